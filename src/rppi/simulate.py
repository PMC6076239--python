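"""Seeded synthetic interactomes with the structure the RP framework assumes.

The generator emulates the pathologies a per-protein local baseline is meant
to fix: every protein carries a log-normal baseline bias (some proteins are
systematically over-scored by the base predictor), a pair's background score
couples both partners' baselines through their geometric mean, true
interactions are rare (~1:100) and lifted above the pair's own baseline, and
a small fraction of hub proteins have several-fold more true partners than
the rest (negative-binomial degrees, Chung-Lu edge placement).

Under these conditions the raw score is an unreliable discriminator — a true
pair of two low-baseline proteins can score below the background of two
high-baseline ones — while rank-order context recovers it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .matrix import LabelSet, OneToAllCurve, ProteinSet, ScoreMatrix

#: Baseline score scale (roughly the magnitude of similarity-weighted scores
#: produced by sequence-based PPI predictors).
BASE_SCORE = 50.0
#: Negative-binomial dispersion (size) for per-protein true-partner counts.
DEGREE_DISPERSION = 2.0


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic interactome.

    prevalence is the marginal fraction of pairs that truly interact;
    baseline_bias_sd is the SD of per-protein log-scale score bias;
    head_effect is the mean lift of a true pair's score above its own
    baseline, in units of that baseline; noise_sd is the multiplicative
    score noise SD.
    """

    n_proteins: int = 300
    prevalence: float = 0.01
    hub_fraction: float = 0.05
    hub_degree_multiplier: float = 4.0
    baseline_bias_sd: float = 0.5
    head_effect: float = 2.0
    noise_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 10:
            raise ValueError("need at least 10 proteins")
        if not (0.0 < self.prevalence < 0.5):
            raise ValueError("prevalence must be in (0, 0.5)")
        if not (0.0 <= self.hub_fraction <= 1.0):
            raise ValueError("hub_fraction must be in [0, 1]")
        if self.hub_degree_multiplier < 1.0:
            raise ValueError("hub_degree_multiplier must be >= 1")
        for name in ("baseline_bias_sd", "head_effect", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated matrix."""

    positives: LabelSet
    baselines: dict[str, float]
    planted_knees: dict[str, int] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#protein\tbaseline\ttrue_partners\n")
            for pid in sorted(self.baselines):
                fh.write(
                    f"{pid}\t{self.baselines[pid]:.10g}\t{self.planted_knees[pid]}\n"
                )


def _protein_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"P{i:0{width}d}" for i in range(n)]


def generate_interactome(config: SyntheticConfig) -> tuple[ScoreMatrix, SyntheticTruth]:
    """Complete symmetric score matrix plus ground-truth labels.

    Per-protein baselines b_x are log-normal around BASE_SCORE; the pair
    background is sqrt(b_x * b_y); true pairs add head_effect times that
    background; multiplicative Gaussian noise is applied and scores are
    clipped at zero.  Deterministic under config.seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    ids = _protein_ids(n)

    b = BASE_SCORE * np.exp(rng.normal(0.0, config.baseline_bias_sd, size=n))

    # expected true-partner counts: negative binomial, hubs scaled up
    n_hubs = int(round(config.hub_fraction * n))
    hubs = rng.choice(n, size=n_hubs, replace=False)
    mean_degree = config.prevalence * (n - 1)
    base_mean = mean_degree / (
        1.0 + config.hub_fraction * (config.hub_degree_multiplier - 1.0)
    )
    means = np.full(n, base_mean)
    means[hubs] *= config.hub_degree_multiplier
    p_nb = DEGREE_DISPERSION / (DEGREE_DISPERSION + means)
    w = rng.negative_binomial(DEGREE_DISPERSION, p_nb).astype(float)

    # Chung-Lu edge placement: P(i~j) = min(1, w_i w_j / sum(w))
    total_w = w.sum()
    iu, ju = np.triu_indices(n, k=1)
    if total_w > 0:
        p_edge = np.minimum(1.0, w[iu] * w[ju] / total_w)
    else:
        p_edge = np.zeros(iu.size)
    edge = rng.random(iu.size) < p_edge

    background = np.sqrt(np.outer(b, b))
    lift = np.zeros((n, n))
    lift[iu[edge], ju[edge]] = config.head_effect
    lift = lift + lift.T
    noise = rng.normal(0.0, config.noise_sd, size=(n, n))
    noise = np.triu(noise, k=1)
    noise = noise + noise.T
    scores = background * (1.0 + lift + noise)
    scores = np.clip(scores, 0.0, None)
    np.fill_diagonal(scores, np.nan)  # self-pairs excluded

    ps = ProteinSet(tuple(ids))
    matrix = ScoreMatrix(ps, ps, scores, intra_species=True)
    positives = LabelSet(
        (ids[i], ids[j]) for i, j in zip(iu[edge], ju[edge])
    )
    degree = np.zeros(n, dtype=int)
    np.add.at(degree, iu[edge], 1)
    np.add.at(degree, ju[edge], 1)
    truth = SyntheticTruth(
        positives=positives,
        baselines={pid: float(b[i]) for i, pid in enumerate(ids)},
        planted_knees={pid: int(degree[i]) for i, pid in enumerate(ids)},
    )
    return matrix, truth


def generate_curve(
    m: int,
    knee_rank: int,
    head_height: float,
    baseline: float,
    noise_sd: float = 0.0,
    shape: str = "L",
    seed: int = 0,
) -> OneToAllCurve:
    """One synthetic one-to-all curve with a planted knee.

    The noiseless core is a linear head descending from
    baseline + head_height at rank 1 to the baseline just past
    ``knee_rank``, followed by a flat baseline; an "S" shape additionally
    drops the final 5% of ranks linearly below the baseline.  Additive
    Gaussian noise is applied and the scores re-sorted descending.
    """
    if not (1 <= knee_rank < m):
        raise ValueError("knee_rank must satisfy 1 <= knee_rank < m")
    if shape not in ("S", "L"):
        raise ValueError("shape must be 'S' or 'L'")
    rng = np.random.default_rng(seed)
    ranks = np.arange(1, m + 1)
    scores = np.full(m, float(baseline))
    head = ranks <= knee_rank
    scores[head] = baseline + head_height * (knee_rank - ranks[head] + 1) / knee_rank
    if shape == "S":
        tail_len = max(1, int(round(0.05 * m)))
        tail = np.arange(tail_len)
        scores[m - tail_len :] = baseline - head_height * 0.3 * (tail + 1) / tail_len
    if noise_sd > 0:
        scores = scores + rng.normal(0.0, noise_sd, size=m)
    scores = np.sort(scores)[::-1]
    width = len(str(m))
    partners = tuple(f"T{i:0{width}d}" for i in range(m))
    return OneToAllCurve(query="Q", partners=partners, scores=scores, ranks=ranks)
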