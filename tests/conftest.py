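import numpy as np
import pytest

from rppi.curves import compute_knees
from rppi.matrix import ScoreMatrix, ProteinSet, threshold_at_specificity
from rppi.simulate import SyntheticConfig, generate_interactome


def make_intra_matrix(values: np.ndarray, ids=None) -> ScoreMatrix:
    """Square symmetric matrix from an upper-triangle-specified array."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    full = np.triu(values, k=1)
    full = full + full.T
    np.fill_diagonal(full, np.nan)
    if ids is None:
        ids = tuple(f"p{i:02d}" for i in range(n))
    ps = ProteinSet(tuple(ids))
    return ScoreMatrix(ps, ps, full, intra_species=True)


def random_intra_matrix(n: int, seed: int) -> ScoreMatrix:
    rng = np.random.default_rng(seed)
    return make_intra_matrix(rng.uniform(1.0, 100.0, size=(n, n)))


@pytest.fixture(scope="session")
def small_interactome():
    """A 60-protein synthetic interactome with knees and a global threshold."""
    cfg = SyntheticConfig(n_proteins=60, prevalence=0.05, seed=17)
    matrix, truth = generate_interactome(cfg)
    knees = compute_knees(matrix)
    neg = [s for a, b, s in matrix.iter_pairs() if (a, b) not in truth.positives]
    gt = threshold_at_specificity(neg, 0.9995)
    return matrix, truth, knees, gt


@pytest.fixture(scope="session")
def study_interactome():
    """The default-condition synthetic interactome (n=300) used end to end."""
    cfg = SyntheticConfig(seed=11)
    matrix, truth = generate_interactome(cfg)
    knees = compute_knees(matrix)
    neg = [s for a, b, s in matrix.iter_pairs() if (a, b) not in truth.positives]
    gt = threshold_at_specificity(neg, 0.9995)
    return matrix, truth, knees, gt
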