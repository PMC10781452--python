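import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from drugmr.datatypes import HarmonizedInstrumentSet

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_summary_frame(rows):
    """Build a canonical summary-stats DataFrame from dict rows, filling
    optional fields."""
    defaults = {
        "chrom": "1",
        "pos": 1,
        "eaf": np.nan,
        "n": 100_000.0,
        "n_cases": np.nan,
    }
    full = []
    for i, r in enumerate(rows):
        d = dict(defaults)
        d.setdefault("variant_id", f"rs{i + 1}")
        d["pos"] = 1000 * (i + 1)
        d.update(r)
        full.append(d)
    return pd.DataFrame(full)


def make_hset(b_x, se_x, b_y, se_y, n_exp=100_000.0, n_out=200_000.0):
    """Small harmonized instrument set from effect/SE arrays."""
    k = len(b_x)
    tbl = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(k)],
            "effect_allele": "A",
            "other_allele": "G",
            "beta_exp": np.asarray(b_x, float),
            "se_exp": np.asarray(se_x, float),
            "pvalue_exp": 1e-10,
            "n_exp": float(n_exp),
            "eaf_exp": 0.3,
            "beta_out": np.asarray(b_y, float),
            "se_out": np.asarray(se_y, float),
            "n_out": float(n_out),
            "flipped": False,
            "palindromic_resolution": "not_palindromic",
        }
    )
    return HarmonizedInstrumentSet(gene="GENE", outcome="OUT", table=tbl)


def random_instrument_array(rng, k):
    """Random (k, 4) instrument array with positive SEs and nonzero b_x."""
    b_x = rng.normal(0.05, 0.02, k)
    b_x[np.abs(b_x) < 1e-3] = 1e-3
    se_x = rng.uniform(0.002, 0.01, k)
    b_y = rng.normal(0.0, 0.02, k)
    se_y = rng.uniform(0.002, 0.01, k)
    return np.column_stack([b_x, se_x, b_y, se_y])


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)
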