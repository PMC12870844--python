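import numpy as np
import pandas as pd
import pytest

import sexseldiv as sd


@pytest.fixture
def assay_frame() -> pd.DataFrame:
    """Small hand-written assay table (one zero-mating female)."""
    return pd.DataFrame(
        {
            "individual_id": ["m1", "m2", "f1", "f2", "f3"],
            "sex": ["male", "male", "female", "female", "female"],
            "line_id": ["WSS-A", "WSS-B", "WSS-A", "WSS-A", "WSS-B"],
            "regime": ["WSS"] * 5,
            "mating_population_id": ["p1", "p2", "p3", "p3", "p4"],
            "matings": [2, 3, 1, 0, 2],
            "offspring": [50, 80, 30, 0, 55],
        }
    )


@pytest.fixture
def double_mating_frame() -> pd.DataFrame:
    rows = []
    rng = np.random.default_rng(1)
    for regime in ("WSS", "SSS"):
        for f in ("A", "B"):
            for m in ("A", "B"):
                for i in range(4):
                    eggs = int(rng.integers(20, 50))
                    rows.append(
                        {
                            "female_id": f"{regime}-{f}{m}-{i}",
                            "regime": regime,
                            "female_line": f"{regime}-{f}",
                            "male_line": f"{regime}-{m}",
                            "eggs_total": eggs,
                            "hatched": int(rng.integers(1, eggs)),
                            "first_mating_ok": True,
                            "second_mating_ok": True,
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture
def small_expression() -> sd.ExpressionData:
    truth = sd.SyntheticTruth()
    data, _, _ = sd.simulate_expression(truth, n_genes=200, geneset_spec={"SFP": 20}, seed=3)
    return data
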