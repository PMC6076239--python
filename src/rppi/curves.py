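"""Smooth modeling of one-to-all rank-order curves and knee detection.

A one-to-all score curve has a characteristic S (or L) shape: a short
high-scoring head, a long baseline plateau, and sometimes a low-scoring
tail.  The baseline is the predictor's typical score for non-interactors of
that protein and thus a per-protein bias proxy.  We fit a locally weighted
quadratic regression (LOESS, tricube weights, no robustness iterations) to
score vs. ordinal rank and take the maximum of the second derivative of the
fit — the point of greatest upward concavity — as the knee: the rank/score
where the baseline begins.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .matrix import OneToAllCurve, RPError, ScoreMatrix

#: Curves shorter than this go straight to the degenerate fallback.
MIN_CURVE_LENGTH = 10
#: Grid points excluded at each end of the knee search (finite-difference
#: curvature is undefined/unstable there).
EDGE_EXCLUSION = 2


class DegenerateCurveError(RPError):
    """The curve is too short or ill-conditioned for a LOESS fit."""


@dataclass
class FittedCurve:
    """A LOESS fit evaluated on the integer rank grid of the source curve."""

    fitted_scores: np.ndarray
    span: float
    degree: int


@dataclass
class KneeEstimate:
    """Per-protein local baseline: the rank and fitted score at the knee.

    ``degenerate`` marks curves where the fallback rule was applied (short
    curve, failed fit, or no upward concavity anywhere in the interior).
    """

    r_tau: int
    s_tau: float
    second_derivative: np.ndarray | None
    degenerate: bool


def _tricube(d: np.ndarray, dmax: float) -> np.ndarray:
    if dmax <= 0:
        return np.ones_like(d)
    u = np.clip(np.abs(d) / dmax, 0.0, 1.0)
    return (1.0 - u**3) ** 3


def _window_size(m: int, span: float, degree: int) -> int:
    # at least degree+3 points so >= degree+1 carry nonzero tricube weight
    return min(m, max(int(math.ceil(span * m)), degree + 3))


def fit_loess(curve: OneToAllCurve, span: float = 0.10, degree: int = 2) -> FittedCurve:
    """Locally weighted polynomial regression of score on rank.

    At each rank a symmetric window of halfwidth ceil(span*m)/2 ranks is
    tricube-weighted and a degree-``degree`` polynomial is fit; the fitted
    value is its value at that rank.  No robustness reweighting iterations
    are performed.  At the curve boundaries the window is truncated (not
    shifted): shifting nearest-neighbor windows, as classic LOESS does,
    creates a spurious curvature maximum a half-window into the curve that
    masks exactly the high-rank knees this model exists to find.  Interior
    fits agree with the classic nearest-neighbor formulation and reduce to
    a fixed linear filter applied via a sliding window.
    """
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    if degree < 0:
        raise ValueError("degree must be non-negative")
    y = np.asarray(curve.scores, dtype=float)
    m = y.size
    if m < degree + 3:
        raise DegenerateCurveError(f"curve of length {m} too short for degree {degree}")
    if not np.all(np.isfinite(y)):
        raise ValueError("curve scores must be finite")
    q = _window_size(m, span, degree)
    half = max((q - 1) // 2, 1)
    width = 2 * half + 1  # symmetric odd window
    fitted = np.empty(m)

    # interior: identical centered windows -> one precomputed filter
    offsets = np.arange(-half, half + 1, dtype=float)
    c = _local_fit_coefficients(offsets, float(half), degree)
    if m >= width:
        windows = np.lib.stride_tricks.sliding_window_view(y, width)
        fitted[half : m - half] = windows @ c

    # boundaries: symmetric window truncated at the grid edge, same halfwidth
    for i in list(range(0, min(half, m))) + list(range(max(m - half, 0), m)):
        lo, hi = max(0, i - half), min(m - 1, i + half)
        off = np.arange(lo, hi + 1, dtype=float) - i
        w = _tricube(off, float(half))
        if int((w > 0).sum()) < degree + 2:
            # too few usable points: widen to the nearest-neighbor window
            lo = min(max(i - half, 0), max(m - width, 0))
            hi = min(lo + width - 1, m - 1)
            off = np.arange(lo, hi + 1, dtype=float) - i
            w = _tricube(off, float(np.max(np.abs(off))))
        ci = _local_fit_coefficients(off, None, degree, weights=w)
        fitted[i] = ci @ y[lo : hi + 1]

    if not np.all(np.isfinite(fitted)):
        raise DegenerateCurveError("LOESS fit produced non-finite values")
    return FittedCurve(fitted_scores=fitted, span=span, degree=degree)


def _local_fit_coefficients(
    offsets: np.ndarray,
    dmax: float | None,
    degree: int,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Row of the hat matrix for a weighted polynomial fit evaluated at 0."""
    w = weights if weights is not None else _tricube(offsets, dmax)
    X = np.vander(offsets, degree + 1, increasing=True)
    XtW = X.T * w
    try:
        beta_map = np.linalg.solve(XtW @ X, XtW)
    except np.linalg.LinAlgError:
        raise DegenerateCurveError("singular local regression window") from None
    return beta_map[0]


def second_derivative(fit: FittedCurve) -> np.ndarray:
    """Central second finite differences on the unit rank grid.

    Endpoints carry NaN; they are excluded from the knee search.
    """
    f = np.asarray(fit.fitted_scores, dtype=float)
    if f.size < 5:
        raise ValueError("fit too short for a second derivative (need >= 5 points)")
    d2 = np.full(f.size, np.nan)
    d2[1:-1] = f[2:] - 2.0 * f[1:-1] + f[:-2]
    return d2


def _fallback(curve: OneToAllCurve, d2: np.ndarray | None = None) -> KneeEstimate:
    m = len(curve)
    return KneeEstimate(
        r_tau=int(math.ceil(m / 2)),
        s_tau=float(np.median(curve.scores)),
        second_derivative=d2,
        degenerate=True,
    )


def find_knee(
    curve: OneToAllCurve,
    span: float = 0.10,
    degree: int = 2,
    min_length: int = MIN_CURVE_LENGTH,
) -> KneeEstimate:
    """Locate the knee: argmax of the fitted curve's second derivative.

    The search excludes ``EDGE_EXCLUSION`` grid points at each end; ties go
    to the smallest rank (the most conservative baseline start).  Degenerate
    curves (shorter than ``min_length``, failed fits, or no strictly positive
    interior curvature) fall back to r_tau = ceil(m/2) with s_tau = median
    raw score, flagged via ``degenerate``.
    """
    m = len(curve)
    if m < max(min_length, 5):
        return _fallback(curve)
    try:
        fit = fit_loess(curve, span=span, degree=degree)
    except DegenerateCurveError:
        return _fallback(curve)
    d2 = second_derivative(fit)
    interior = slice(EDGE_EXCLUSION, m - EDGE_EXCLUSION)
    seg = d2[interior]
    if seg.size == 0 or not np.any(np.isfinite(seg)) or np.nanmax(seg) <= 0:
        return _fallback(curve, d2)
    idx = int(np.nanargmax(seg)) + EDGE_EXCLUSION  # first max -> smallest rank
    return KneeEstimate(
        r_tau=idx + 1,
        s_tau=float(fit.fitted_scores[idx]),
        second_derivative=d2,
        degenerate=False,
    )


def compute_knees(
    matrix: ScoreMatrix,
    span: float = 0.10,
    degree: int = 2,
    side: str = "a",
) -> dict[str, KneeEstimate]:
    """Knee estimates for every protein on one side of the matrix."""
    ids = matrix.proteome_a.ids if side == "a" else matrix.proteome_b.ids
    return {
        pid: find_knee(matrix.one_to_all(pid, side=side), span=span, degree=degree)
        for pid in ids
    }


def write_knee_table(knees: dict[str, KneeEstimate], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#protein\tr_tau\ts_tau\tdegenerate\n")
        for pid in sorted(knees):
            k = knees[pid]
            fh.write(f"{pid}\t{k.r_tau}\t{k.s_tau:.10g}\t{int(k.degenerate)}\n")


def stratified_curve_sample(
    matrix: ScoreMatrix,
    fraction: float = 0.01,
    stratum_size: int = 100,
    seed: int = 0,
) -> list[OneToAllCurve]:
    """QC sample of one-to-all curves stratified by maximum score.

    All curves are sorted by their maximum score, partitioned into
    consecutive strata of ``stratum_size``, and one uniformly random
    representative is drawn per stratum (cycling over strata) until
    ceil(fraction * n) curves are collected.  Deterministic under ``seed``.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    ids = list(matrix.proteome_a.ids)
    curves = {pid: matrix.one_to_all(pid, side="a") for pid in ids}
    order = sorted(ids, key=lambda p: (float(np.max(curves[p].scores)), p))
    strata = [order[i : i + stratum_size] for i in range(0, len(order), stratum_size)]
    needed = math.ceil(fraction * len(ids))
    sample: list[OneToAllCurve] = []
    s = 0
    while len(sample) < needed:
        stratum = strata[s % len(strata)]
        sample.append(curves[stratum[int(rng.integers(len(stratum)))]])
        s += 1
    return sample


def plot_curve_fit(curve: OneToAllCurve, knee: KneeEstimate, path, span: float = 0.10,
                   degree: int = 2) -> None:
    """QC plot: raw curve, LOESS overlay, and knee marker."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.ranks, curve.scores, ".", ms=2, color="0.6", label="scores")
    try:
        fit = fit_loess(curve, span=span, degree=degree)
        ax.plot(curve.ranks, fit.fitted_scores, "-", color="C0", label="LOESS")
    except DegenerateCurveError:
        pass
    ax.axvline(knee.r_tau, color="C3", ls="--", lw=1,
               label=f"knee r={knee.r_tau}" + (" (degenerate)" if knee.degenerate else ""))
    ax.set_xlabel("rank")
    ax.set_ylabel("score")
    ax.set_title(f"one-to-all curve: {curve.query}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
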