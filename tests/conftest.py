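import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from msremip.matrix import CountMatrix
from msremip.simulate import SimConfig, default_sample_sheet, make_panel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    """Fixture-sized panel: 40 CpG + 20 reference + 8 lambda smMIPs."""
    return make_panel(11)


@pytest.fixture(scope="session")
def tiny_panel():
    """Minimal panel for fast count-level simulations."""
    return make_panel(
        12,
        n_cpg_targets=3,
        n_double_tiled=1,
        n_ref_no_site=2,
        n_ref_no_cpg=2,
        n_lambda_cpg=2,
        n_lambda_ref=2,
    )


@pytest.fixture(scope="session")
def small_config():
    samples = default_sample_sheet(13, n_tumor=4, n_normal=4, n_blood=2, n_undigested=2)
    return SimConfig(seed=13, samples=samples, n_molecules_per_target=200)


def manual_count_matrix(counts: dict, categories: dict, sample_meta: dict | None = None):
    """Hand-built CountMatrix: counts maps sample -> {smmip: count}."""
    df = pd.DataFrame(counts).T.fillna(0).astype(np.int64)
    df.index.name = "sample_id"
    smmip_meta = pd.DataFrame(
        {
            "target_id": {k: k for k in categories},
            "tile": {k: "plus" for k in categories},
            "category": categories,
        }
    )
    smmip_meta.index.name = "smmip_id"
    if sample_meta is None:
        sample_meta = {
            sid: {"tissue": "lung", "condition": "normal", "digested": True}
            for sid in df.index
        }
    meta = pd.DataFrame(sample_meta).T.loc[df.index]
    meta["digested"] = meta["digested"].astype(bool)
    return CountMatrix(counts=df, sample_meta=meta, smmip_meta=smmip_meta)


@pytest.fixture
def lambda_counts():
    """Count matrix with lambda controls for digestion-QC arithmetic."""
    categories = {
        "lc1": "lambda_cpg",
        "lr1": "lambda_ref",
        "cpg1": "cpg",
        "ref1": "ref_no_site",
    }
    counts = {
        "dig1": {"lc1": 2, "lr1": 100, "cpg1": 50, "ref1": 100},
        "und1": {"lc1": 50, "lr1": 100, "cpg1": 100, "ref1": 100},
        "und2": {"lc1": 50, "lr1": 100, "cpg1": 100, "ref1": 100},
    }
    sample_meta = {
        "dig1": {"tissue": "lung", "condition": "tumor", "digested": True},
        "und1": {"tissue": "control", "condition": "normal", "digested": False},
        "und2": {"tissue": "control", "condition": "normal", "digested": False},
    }
    return manual_count_matrix(counts, categories, sample_meta)
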