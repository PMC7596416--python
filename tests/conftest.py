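import numpy as np
import pandas as pd
import pytest

from rbprofiler import (
    ExpressionMatrix,
    GroupDesign,
    SimulationConfig,
    detection_filter,
    generate_dataset,
    median_normalize,
    run_comparison,
)


def make_matrix(intensities, detection_p=None, annotation=None,
                probes=None, samples=None):
    """Small helper to build a validated ExpressionMatrix from raw arrays."""
    arr = np.asarray(intensities, dtype=float)
    probes = probes or [f"p{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    inten = pd.DataFrame(arr, index=probes, columns=samples)
    if detection_p is None:
        det = pd.DataFrame(0.01, index=probes, columns=samples)
    else:
        det = pd.DataFrame(np.asarray(detection_p, dtype=float),
                           index=probes, columns=samples)
    ann = pd.Series(annotation or {}, dtype=object)
    return ExpressionMatrix(intensities=inten, detection_p=det, annotation=ann)


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the default study conditions."""
    matrix, design, truth = generate_dataset(SimulationConfig(seed=11))
    return matrix, design, truth


@pytest.fixture(scope="session")
def default_normalized(default_cohort):
    matrix, design, _ = default_cohort
    kept = detection_filter(matrix, design)
    return median_normalize(matrix.subset_probes(kept)), design


@pytest.fixture(scope="session")
def default_comparison(default_cohort, default_normalized):
    """Disease-vs-non-smoker comparison, census-restricted."""
    _, _, truth = default_cohort
    norm, design = default_normalized
    res = run_comparison(
        norm, design, ("COPD", "NS"), census=truth.census(),
        prefiltered_normalized=True,
    )
    return res, truth
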