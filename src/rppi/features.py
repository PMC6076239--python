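"""Reciprocal Perspective features for candidate protein pairs.

A candidate interaction x-y is characterized jointly from both partners'
one-to-all contexts: the rank each partner assigns the other, the reciprocal
rank-order combinations (NaRRO, NoRRO, ARRO), each partner's local baseline
cutoff (knee rank and score), indicators for sitting above the local and
global cutoffs, and the fold differences from each baseline.

Notation: for pair x_i y_j, rank_xy is the ordinal rank of y_j among all
predictions for x_i and rank_yx the rank of x_i among predictions for y_j;
s_tau / r_tau are the knee score/rank of each partner's curve.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .curves import KneeEstimate
from .matrix import GlobalThreshold, RPError, ScoreMatrix, UnknownProteinError

DEFAULT_EPSILON = 1e-8

# Table layout: canonical (oriented) feature columns grouped by feature type.
RANK_FEATURES = (
    "Rank-XY",
    "Rank-YX",
    "NaRRO",
    "NoRRO_A",
    "NoRRO_B",
    "ARRO",
    "Rank-Local-Cutoff-X",
    "Rank-Local-Cutoff-Y",
    "Interaction-XY-Above-Local-X",
    "Interaction-YX-Above-Local-Y",
)
SCORE_FEATURES = (
    "Score-Local-Cutoff-X",
    "Score-Local-Cutoff-Y",
    "Above-Global-Threshold",
)
FOLD_FEATURES = (
    "Fold-Difference-From-Local-X",
    "Fold-Difference-From-Local-Y",
)
ALL_RP_FEATURES = RANK_FEATURES + SCORE_FEATURES + FOLD_FEATURES
ORIGINAL_COLUMN = "original_score"

# Complementary (X/Y) column pairs collapsed to mean + |difference| in
# symmetric mode; the replacement names keep the feature-type prefix.
SYMMETRIC_PAIRS: tuple[tuple[str, str, str], ...] = (
    ("Rank-XY", "Rank-YX", "Rank-Pair"),
    ("NoRRO_A", "NoRRO_B", "NoRRO"),
    ("Rank-Local-Cutoff-X", "Rank-Local-Cutoff-Y", "Rank-Local-Cutoff"),
    ("Score-Local-Cutoff-X", "Score-Local-Cutoff-Y", "Score-Local-Cutoff"),
    (
        "Interaction-XY-Above-Local-X",
        "Interaction-YX-Above-Local-Y",
        "Interaction-Above-Local",
    ),
    ("Fold-Difference-From-Local-X", "Fold-Difference-From-Local-Y", "Fold-Difference"),
)

FEATURE_TYPE_OF: dict[str, str] = {}
for _c in RANK_FEATURES:
    FEATURE_TYPE_OF[_c] = "Rank"
for _c in SCORE_FEATURES:
    FEATURE_TYPE_OF[_c] = "Score"
for _c in FOLD_FEATURES:
    FEATURE_TYPE_OF[_c] = "Fold"
for _x, _y, _base in SYMMETRIC_PAIRS:
    for _suffix in ("Mean", "AbsDiff"):
        FEATURE_TYPE_OF[f"{_base}-{_suffix}"] = FEATURE_TYPE_OF[_x]
FEATURE_TYPE_OF[ORIGINAL_COLUMN] = "Original"


class SchemaError(RPError):
    """A feature table does not match the expected column schema."""


# ---------------------------------------------------------------------------
# elementary metrics
# ---------------------------------------------------------------------------

def fold_difference(s: float, s_tau: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """Fold difference of a score from a baseline: (s - s_tau) / s_tau.

    A zero baseline (flat curve) is guarded by ``epsilon`` in the
    denominator.
    """
    if s < 0 or s_tau < 0:
        raise ValueError("scores and baselines are non-negative")
    return (s - s_tau) / max(s_tau, epsilon)


def narro(rank_xy: int, rank_yx: int) -> float:
    """Naive Reciprocal Rank Order: 1 / (rank_xy * rank_yx), in [1/(nm), 1]."""
    _check_ranks(rank_xy, rank_yx)
    return 1.0 / (rank_xy * rank_yx)


def arro(rank_xy: int, rank_yx: int, n: int, m: int) -> float:
    """Adjusted Reciprocal Rank Order: ((rank_xy/n) * (rank_yx/m))^-1.

    Proteome-size normalization for inter-species comparisons; values lie in
    [1, nm].
    """
    _check_ranks(rank_xy, rank_yx)
    if n < 1 or m < 1:
        raise ValueError("proteome sizes must be >= 1")
    return (n * m) / (rank_xy * rank_yx)


def norro(rank_xy: int, rank_yx: int, p: int) -> float:
    """Normalized Reciprocal Rank Order: (rank_xy * rank_yx / p)^-1.

    Intra-species form (p = proteome size); values lie in [p/(nm), p].
    """
    _check_ranks(rank_xy, rank_yx)
    if p < 1:
        raise ValueError("proteome size must be >= 1")
    return p / (rank_xy * rank_yx)


def _check_ranks(rank_xy: int, rank_yx: int) -> None:
    if rank_xy < 1 or rank_yx < 1:
        raise ValueError("ordinal ranks are >= 1")


# ---------------------------------------------------------------------------
# per-pair feature vector
# ---------------------------------------------------------------------------

@dataclass
class RPFeatureVector:
    """The 15 RP features plus the original score for one oriented pair."""

    original_score: float
    rank_xy: int
    rank_yx: int
    narro: float
    norro_a: float
    norro_b: float
    arro: float
    rank_local_cutoff_x: int
    rank_local_cutoff_y: int
    score_local_cutoff_x: float
    score_local_cutoff_y: float
    above_local_x: int
    above_local_y: int
    above_global: int
    fd_x: float
    fd_y: float

    def as_dict(self) -> dict[str, float]:
        """Map to Table-style column names."""
        return {
            ORIGINAL_COLUMN: self.original_score,
            "Rank-XY": self.rank_xy,
            "Rank-YX": self.rank_yx,
            "NaRRO": self.narro,
            "NoRRO_A": self.norro_a,
            "NoRRO_B": self.norro_b,
            "ARRO": self.arro,
            "Rank-Local-Cutoff-X": self.rank_local_cutoff_x,
            "Rank-Local-Cutoff-Y": self.rank_local_cutoff_y,
            "Score-Local-Cutoff-X": self.score_local_cutoff_x,
            "Score-Local-Cutoff-Y": self.score_local_cutoff_y,
            "Interaction-XY-Above-Local-X": self.above_local_x,
            "Interaction-YX-Above-Local-Y": self.above_local_y,
            "Above-Global-Threshold": self.above_global,
            "Fold-Difference-From-Local-X": self.fd_x,
            "Fold-Difference-From-Local-Y": self.fd_y,
        }


class RankIndex:
    """Cache of per-protein one-to-all rank lookups for a matrix."""

    def __init__(self, matrix: ScoreMatrix):
        self.matrix = matrix
        self._curves: dict[tuple[str, str], dict[str, int]] = {}

    def rank(self, query: str, partner: str, side: str) -> int:
        key = (side, query)
        table = self._curves.get(key)
        if table is None:
            curve = self.matrix.one_to_all(query, side=side)
            table = {p: int(r) for p, r in zip(curve.partners, curve.ranks)}
            self._curves[key] = table
        try:
            return table[partner]
        except KeyError:
            raise UnknownProteinError(
                f"{partner!r} not in the one-to-all curve of {query!r}"
            ) from None


def compute_pair_features(
    x: str,
    y: str,
    matrix: ScoreMatrix,
    knees: Mapping[str, KneeEstimate],
    global_t: GlobalThreshold,
    epsilon: float = DEFAULT_EPSILON,
    rank_index: RankIndex | None = None,
) -> RPFeatureVector:
    """Assemble the full RP feature vector for the oriented pair (x, y).

    ``x`` is taken from proteome A and ``y`` from proteome B (for
    intra-species matrices both sides coincide).  The above-local indicators
    use strict ``>`` (the knee itself starts the baseline); the global
    indicator uses ``>=``.
    """
    for pid in (x, y):
        if pid not in knees:
            raise UnknownProteinError(f"no knee estimate for protein {pid!r}")
    if rank_index is None:
        rank_index = RankIndex(matrix)
    s = matrix.score(x, y)
    rank_xy = rank_index.rank(x, y, side="a")
    rank_yx = rank_index.rank(y, x, side="b" if not matrix.intra_species else "a")
    n, m = matrix.n, matrix.m
    kx, ky = knees[x], knees[y]
    return RPFeatureVector(
        original_score=s,
        rank_xy=rank_xy,
        rank_yx=rank_yx,
        narro=narro(rank_xy, rank_yx),
        norro_a=norro(rank_xy, rank_yx, n),
        norro_b=norro(rank_xy, rank_yx, m),
        arro=arro(rank_xy, rank_yx, n, m),
        rank_local_cutoff_x=kx.r_tau,
        rank_local_cutoff_y=ky.r_tau,
        score_local_cutoff_x=kx.s_tau,
        score_local_cutoff_y=ky.s_tau,
        above_local_x=int(s > kx.s_tau),
        above_local_y=int(s > ky.s_tau),
        above_global=int(s >= global_t.value),
        fd_x=fold_difference(s, kx.s_tau, epsilon),
        fd_y=fold_difference(s, ky.s_tau, epsilon),
    )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def symmetrize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse complementary X/Y columns to mean + |difference| columns.

    The result is invariant under pair-orientation swap while keeping both
    the location and spread of each complementary feature pair.
    """
    out = table.copy()
    for col_x, col_y, base in SYMMETRIC_PAIRS:
        a, b = out[col_x].to_numpy(float), out[col_y].to_numpy(float)
        out[f"{base}-Mean"] = (a + b) / 2.0
        out[f"{base}-AbsDiff"] = np.abs(a - b)
        out = out.drop(columns=[col_x, col_y])
    return out


def canonical_pair(x: str, y: str) -> tuple[str, str]:
    """Fix pair orientation by lexicographic id order."""
    return (x, y) if x <= y else (y, x)


def build_feature_table(
    pairs: Iterable[tuple[str, str]],
    matrix: ScoreMatrix,
    knees: Mapping[str, KneeEstimate],
    global_t: GlobalThreshold,
    symmetric_mode: bool = False,
    labels: Sequence[int] | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Feature table with one row per pair, indexed by (id_a, id_b).

    Intra-species pairs are canonically oriented (lexicographic) unless
    ``symmetric_mode`` is set, in which case complementary features are
    collapsed so rows are swap-invariant.  Duplicate pairs are dropped with
    a warning.
    """
    pair_list = list(pairs)
    label_map: dict[tuple[str, str], int] | None = None
    if labels is not None:
        if len(labels) != len(pair_list):
            raise ValueError("labels length must match pairs length")
        label_map = {}
    rank_index = RankIndex(matrix)
    rows, index, seen = [], [], set()
    dupes = 0
    for k, (x, y) in enumerate(pair_list):
        if matrix.intra_species:
            x, y = canonical_pair(x, y)
        key = (x, y)
        if key in seen:
            dupes += 1
            continue
        seen.add(key)
        rows.append(
            compute_pair_features(
                x, y, matrix, knees, global_t, epsilon=epsilon, rank_index=rank_index
            ).as_dict()
        )
        index.append(key)
        if label_map is not None:
            label_map[key] = int(labels[k])
    if dupes:
        warnings.warn(f"dropped {dupes} duplicate pairs", stacklevel=2)
    table = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["id_a", "id_b"])
    )
    if symmetric_mode:
        table = symmetrize_table(table)
    if label_map is not None:
        table["label"] = [label_map[k] for k in index]
    return table


def full_pair_table(
    matrix: ScoreMatrix,
    knees: Mapping[str, KneeEstimate],
    global_t: GlobalThreshold,
    symmetric_mode: bool = False,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Vectorized feature table over every scored pair of an intra matrix.

    Equivalent to :func:`build_feature_table` over all pairs (asserted in
    the test suite) but computed with array operations so genome-wide
    rescoring stays fast.
    """
    if not matrix.intra_species:
        raise ValueError("full_pair_table supports intra-species matrices")
    ids = np.asarray(matrix.proteome_a.ids, dtype=object)
    n = matrix.n
    V = matrix.values
    # ordinal rank of column j within row i (descending score, id tie-break)
    id_rank = np.argsort(np.argsort(ids, kind="stable"), kind="stable")
    R = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        row = V[i]
        keep = np.flatnonzero(np.isfinite(row))
        order = keep[np.lexsort((id_rank[keep], -row[keep]))]
        R[i, order] = np.arange(1, keep.size + 1)
    r_tau = np.array([knees[p].r_tau for p in ids])
    s_tau = np.array([knees[p].s_tau for p in ids])

    iu, ju = np.triu_indices(n, k=1)
    finite = np.isfinite(V[iu, ju])
    iu, ju = iu[finite], ju[finite]
    # canonical orientation by id comparison
    flip = ids[iu] > ids[ju]
    i_x = np.where(flip, ju, iu)
    j_y = np.where(flip, iu, ju)
    s = V[i_x, j_y]
    rank_xy = R[i_x, j_y].astype(float)
    rank_yx = R[j_y, i_x].astype(float)
    prod = rank_xy * rank_yx
    stx, sty = s_tau[i_x], s_tau[j_y]
    table = pd.DataFrame(
        {
            ORIGINAL_COLUMN: s,
            "Rank-XY": rank_xy,
            "Rank-YX": rank_yx,
            "NaRRO": 1.0 / prod,
            "NoRRO_A": n / prod,
            "NoRRO_B": n / prod,
            "ARRO": (n * n) / prod,
            "Rank-Local-Cutoff-X": r_tau[i_x].astype(float),
            "Rank-Local-Cutoff-Y": r_tau[j_y].astype(float),
            "Score-Local-Cutoff-X": stx,
            "Score-Local-Cutoff-Y": sty,
            "Interaction-XY-Above-Local-X": (s > stx).astype(float),
            "Interaction-YX-Above-Local-Y": (s > sty).astype(float),
            "Above-Global-Threshold": (s >= global_t.value).astype(float),
            "Fold-Difference-From-Local-X": (s - stx) / np.maximum(stx, epsilon),
            "Fold-Difference-From-Local-Y": (s - sty) / np.maximum(sty, epsilon),
        },
        index=pd.MultiIndex.from_arrays([ids[i_x], ids[j_y]], names=["id_a", "id_b"]),
    )
    if symmetric_mode:
        table = symmetrize_table(table)
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label=["id_a", "id_b"], float_format="%.10g")
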