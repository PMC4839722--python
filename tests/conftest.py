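import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from coexpair import (SimulationConfig, build_null, classify_pairs,
                      correlation_table, derive_thresholds, preprocess_pair,
                      simulate_expression)
from coexpair.types import ExpressionMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_matrix(values, level="bulk", state="raw_rpkm", genes=None, samples=None):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"G{i+1}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j+1}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples),
                            level=level, state=state)


@pytest.fixture(scope="session")
def default_sim():
    """One default-sized simulation shared by read-only tests."""
    cfg = SimulationConfig(seed=7)
    sc, bulk, truth = simulate_expression(cfg)
    return cfg, sc, bulk, truth


@pytest.fixture(scope="session")
def default_classified(default_sim):
    """Preprocessed matrices, correlation table and classification for the
    default simulation (null of 100 shuffles per level)."""
    cfg, sc_raw, bulk_raw, truth = default_sim
    sc, bulk = preprocess_pair(sc_raw, bulk_raw)
    table = correlation_table(sc, bulk)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null_sc = build_null(sc, n_reps=100, seed=71)
        null_bulk = build_null(bulk, n_reps=100, seed=72)
        thresholds = derive_thresholds(null_sc, null_bulk)
    class_table = classify_pairs(table, thresholds)
    return {"config": cfg, "truth": truth, "sc": sc, "bulk": bulk,
            "table": table, "thresholds": thresholds,
            "class_table": class_table}
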