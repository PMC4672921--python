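import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import septikit as sk

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_matrix():
    """4 genes x 6 samples, log2 scale, hand-set values."""
    genes = list(sk.PANEL_GENES)
    samples = [f"s{i}" for i in range(1, 7)]
    data = pd.DataFrame(
        [[12.0, 11.0, 10.0, 12.5, 11.5, 10.5],   # PLAC8
         [10.0, 10.0, 10.0, 10.0, 10.0, 10.0],   # PLA2G7
         [11.0, 10.5, 10.0, 11.5, 11.0, 10.0],   # LAMP1
         [9.0, 9.5, 10.0, 9.0, 9.5, 10.0]],      # CEACAM4
        index=genes, columns=samples,
    )
    return sk.ExpressionMatrix(data)


@pytest.fixture
def tiny_labels():
    idx = pd.Index([f"s{i}" for i in range(1, 7)], name="sample_id")
    return sk.CohortLabels(pd.DataFrame(
        {"class_label": ["case", "case", "control", "case", "control", "control"]},
        index=idx,
    ))


@pytest.fixture
def discovery_cohort():
    """Seeded synthetic discovery cohort with the default planted signature."""
    spec = sk.SimSpec(seed=7)
    matrix, labels = sk.generate_expression_cohort(spec)
    return spec, matrix, labels


def brute_force_auc(cases, controls):
    """Independent oracle: exhaustive concordant/tied pair counting."""
    cases = np.asarray(cases, float)
    controls = np.asarray(controls, float)
    wins = sum((c > k) + 0.5 * (c == k) for c in cases for k in controls)
    return wins / (cases.size * controls.size)
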