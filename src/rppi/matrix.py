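"""All-to-all PPI score matrices, positive-pair labels, and global thresholds.

A comprehensive ("all-to-all") prediction run scores every protein pair of a
proteome (or every inter-species pair between two proteomes).  This module
holds the dense score matrix, the set of known positive pairs used for
training, and the derivation of a single global decision threshold from a
negative-score sample at a target specificity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class RPError(Exception):
    """Base class for errors raised by this package."""


class ScoreParseError(RPError):
    """A score or pair file line could not be parsed."""


class IntegrityError(RPError):
    """Conflicting duplicate entries or violated matrix invariants."""


class CompletenessError(RPError):
    """The matrix is missing required pair scores."""


class UnknownProteinError(RPError, KeyError):
    """A protein id is not present in the proteome."""


@dataclass(frozen=True)
class ProteinSet:
    """An ordered set of unique protein identifiers (one proteome)."""

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) < 2:
            raise IntegrityError("a proteome needs at least 2 proteins")
        if len(set(self.ids)) != len(self.ids):
            raise IntegrityError("protein ids must be unique")

    @property
    def size(self) -> int:
        return len(self.ids)

    def index(self, pid: str) -> int:
        try:
            return self._lookup[pid]
        except KeyError:
            raise UnknownProteinError(f"unknown protein id: {pid!r}") from None

    def __contains__(self, pid: str) -> bool:
        return pid in self._lookup

    @property
    def _lookup(self) -> dict[str, int]:
        # cached on first use; frozen dataclass so stash via __dict__
        cached = self.__dict__.get("_lookup_cache")
        if cached is None:
            cached = {pid: i for i, pid in enumerate(self.ids)}
            self.__dict__["_lookup_cache"] = cached
        return cached


@dataclass(frozen=True)
class GlobalThreshold:
    """A single proteome-wide decision cutoff (score >= value is positive)."""

    value: float
    target_specificity: float


class LabelSet:
    """A set of known positive pairs, compared without orientation."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        seen: set[tuple[str, str]] = set()
        for a, b in pairs:
            seen.add((a, b) if a <= b else (b, a))
        self.positives: frozenset[tuple[str, str]] = frozenset(seen)

    def __len__(self) -> int:
        return len(self.positives)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return ((a, b) if a <= b else (b, a)) in self.positives

    def __iter__(self):
        return iter(sorted(self.positives))

    def validate_against(self, matrix: "ScoreMatrix") -> None:
        for a, b in self.positives:
            if a not in matrix.proteome_a and a not in matrix.proteome_b:
                raise UnknownProteinError(f"positive pair references unknown id {a!r}")
            if b not in matrix.proteome_a and b not in matrix.proteome_b:
                raise UnknownProteinError(f"positive pair references unknown id {b!r}")


@dataclass
class OneToAllCurve:
    """One query protein's partners sorted by descending score.

    Ordinal ranks are 1..m; ties in score are broken by partner id so the
    ordering (hence every rank-derived feature) is reproducible.
    """

    query: str
    partners: tuple[str, ...]
    scores: np.ndarray
    ranks: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.ranks is None:
            self.ranks = np.arange(1, len(self.partners) + 1)
        if not (len(self.partners) == len(self.scores) == len(self.ranks)):
            raise IntegrityError("curve fields must have equal length")
        if np.any(np.diff(self.scores) > 0):
            raise IntegrityError("curve scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.partners)

    def rank_of(self, partner: str) -> int:
        cached = self.__dict__.get("_rank_cache")
        if cached is None:
            cached = {p: r for p, r in zip(self.partners, self.ranks)}
            self.__dict__["_rank_cache"] = cached
        try:
            return int(cached[partner])
        except KeyError:
            raise UnknownProteinError(
                f"{partner!r} is not a partner of {self.query!r}"
            ) from None


class ScoreMatrix:
    """Dense all-to-all score matrix over proteomes A (rows) and B (columns).

    Intra-species matrices are square and symmetric; the diagonal holds
    self-pair scores only when the input provided them (NaN marks absent
    pairs).  Scores are non-negative reals.
    """

    def __init__(
        self,
        proteome_a: ProteinSet,
        proteome_b: ProteinSet,
        values: np.ndarray,
        intra_species: bool,
    ):
        values = np.asarray(values, dtype=float)
        if values.shape != (proteome_a.size, proteome_b.size):
            raise IntegrityError(
                f"values shape {values.shape} does not match proteome sizes "
                f"({proteome_a.size}, {proteome_b.size})"
            )
        if intra_species:
            if proteome_a.ids != proteome_b.ids:
                raise IntegrityError("intra-species matrix requires identical proteomes")
            off = ~np.eye(values.shape[0], dtype=bool)
            a, b = values[off], values.T[off]
            both = np.isfinite(a) & np.isfinite(b)
            if not np.allclose(a[both], b[both], rtol=0, atol=0):
                raise IntegrityError("intra-species matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.any(values < 0):
                raise IntegrityError("scores must be non-negative")
        self.proteome_a = proteome_a
        self.proteome_b = proteome_b
        self.values = values
        self.intra_species = intra_species

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        """Size of proteome A."""
        return self.proteome_a.size

    @property
    def m(self) -> int:
        """Size of proteome B."""
        return self.proteome_b.size

    def score(self, x: str, y: str) -> float:
        """Score of the pair (x in A, y in B); intra matrices accept either order."""
        if self.intra_species and x not in self.proteome_a:
            x, y = y, x
        s = self.values[self.proteome_a.index(x), self.proteome_b.index(y)]
        if not np.isfinite(s):
            raise CompletenessError(f"pair ({x!r}, {y!r}) has no score")
        return float(s)

    def has_pair(self, x: str, y: str) -> bool:
        try:
            self.score(x, y)
            return True
        except (CompletenessError, UnknownProteinError):
            return False

    def missing_count(self, include_self: bool = False) -> int:
        miss = ~np.isfinite(self.values)
        if self.intra_species and not include_self:
            miss = miss & ~np.eye(self.n, dtype=bool)
            return int(miss[np.triu_indices(self.n, k=1)].sum())
        return int(miss.sum())

    def require_complete(self, include_self: bool = False) -> None:
        k = self.missing_count(include_self=include_self)
        if k:
            raise CompletenessError(f"matrix is missing {k} pair scores")

    def iter_pairs(self) -> Iterable[tuple[str, str, float]]:
        """Yield every scored pair once (upper triangle + diagonal for intra)."""
        A, B, V = self.proteome_a.ids, self.proteome_b.ids, self.values
        if self.intra_species:
            for i in range(self.n):
                for j in range(i, self.n):
                    if np.isfinite(V[i, j]):
                        yield A[i], B[j], float(V[i, j])
        else:
            for i in range(self.n):
                for j in range(self.m):
                    if np.isfinite(V[i, j]):
                        yield A[i], B[j], float(V[i, j])

    # -- one-to-all curves -------------------------------------------------
    def one_to_all(self, query: str, side: str = "a") -> OneToAllCurve:
        """Rank-order distribution of one protein's scores against all partners.

        Partners are sorted by strictly non-increasing score with ties broken
        by partner id (lexicographic).  NaN entries (absent pairs, e.g. the
        diagonal when self-pairs were not supplied) are excluded.
        """
        if side not in ("a", "b"):
            raise ValueError("side must be 'a' or 'b'")
        if side == "a":
            row = self.values[self.proteome_a.index(query), :]
            partners = self.proteome_b.ids
        else:
            row = self.values[:, self.proteome_b.index(query)]
            partners = self.proteome_a.ids
        keep = np.isfinite(row)
        ids = np.asarray(partners, dtype=object)[keep]
        sc = row[keep]
        # stable sort on (-score, id): lexsort's last key is primary
        id_order = np.argsort(np.argsort(ids, kind="stable"), kind="stable")
        order = np.lexsort((id_order, -sc))
        return OneToAllCurve(
            query=query,
            partners=tuple(ids[order]),
            scores=sc[order],
            ranks=np.arange(1, keep.sum() + 1),
        )


# ---------------------------------------------------------------------------
# construction / I/O
# ---------------------------------------------------------------------------

def _parse_score_lines(path: Path) -> Iterable[tuple[int, str, str, float]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ScoreParseError(
                    f"{path}:{lineno}: expected 3 columns (id_a id_b score), "
                    f"got {len(parts)}"
                )
            try:
                s = float(parts[2])
            except ValueError:
                raise ScoreParseError(
                    f"{path}:{lineno}: score {parts[2]!r} is not a number"
                ) from None
            if not math.isfinite(s):
                raise ScoreParseError(f"{path}:{lineno}: non-finite score")
            if s < 0:
                raise ScoreParseError(
                    f"{path}:{lineno}: negative score {s} (scores are non-negative)"
                )
            yield lineno, parts[0], parts[1], s


def matrix_from_pairs(
    entries: Iterable[tuple[str, str, float]],
    intra_species: bool = True,
    source: str = "<pairs>",
) -> ScoreMatrix:
    """Build a ScoreMatrix from (id_a, id_b, score) triples.

    Intra-species duplicate orientations are averaged (directed -> undirected
    rule); inter-species duplicates with conflicting scores raise.
    """
    triples = [(str(a), str(b), float(s)) for a, b, s in entries]
    if intra_species:
        ids = sorted({i for a, b, _ in triples for i in (a, b)})
        ps = ProteinSet(tuple(ids))
        idx = {p: i for i, p in enumerate(ids)}
        n = len(ids)
        total = np.zeros((n, n))
        count = np.zeros((n, n), dtype=int)
        for a, b, s in triples:
            i, j = idx[a], idx[b]
            total[i, j] += s
            count[i, j] += 1
        # average over both listed orientations (and repeated lines)
        sym_total = total + np.triu(total.T, k=1) + np.tril(total.T, k=-1)
        sym_count = count + np.triu(count.T, k=1) + np.tril(count.T, k=-1)
        with np.errstate(invalid="ignore"):
            values = np.where(sym_count > 0, sym_total / np.maximum(sym_count, 1), np.nan)
        return ScoreMatrix(ps, ps, values, intra_species=True)
    ids_a = sorted({a for a, _, _ in triples})
    ids_b = sorted({b for _, b, _ in triples})
    pa, pb = ProteinSet(tuple(ids_a)), ProteinSet(tuple(ids_b))
    values = np.full((pa.size, pb.size), np.nan)
    for a, b, s in triples:
        i, j = pa.index(a), pb.index(b)
        if np.isfinite(values[i, j]) and values[i, j] != s:
            raise IntegrityError(
                f"{source}: conflicting duplicate entry for pair ({a!r}, {b!r})"
            )
        values[i, j] = s
    return ScoreMatrix(pa, pb, values, intra_species=False)


def read_scores(
    path: str | Path,
    intra_species: bool = True,
    require_complete: bool = False,
) -> ScoreMatrix:
    """Read a 3-column score table (id_a, id_b, score; '#' comments)."""
    path = Path(path)
    triples = [(a, b, s) for _, a, b, s in _parse_score_lines(path)]
    if not triples:
        raise ScoreParseError(f"{path}: no score entries")
    mat = matrix_from_pairs(triples, intra_species=intra_species, source=str(path))
    if require_complete:
        mat.require_complete()
    return mat


def write_scores(matrix: ScoreMatrix, path: str | Path) -> None:
    """Write the matrix as TSV, one line per scored pair, round-trip exact."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#id_a\tid_b\tscore\n")
        for a, b, s in matrix.iter_pairs():
            fh.write(f"{a}\t{b}\t{s!r}\n")


def read_pairs(path: str | Path) -> LabelSet:
    """Read a 2-column positive-pair table ('#' comments allowed)."""
    path = Path(path)
    pairs = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ScoreParseError(f"{path}:{lineno}: expected 2 columns")
            pairs.append((parts[0], parts[1]))
    return LabelSet(pairs)


def write_pairs(labels: LabelSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#id_a\tid_b\n")
        for a, b in labels:
            fh.write(f"{a}\t{b}\n")


def symmetrize_directed(matrix: ScoreMatrix) -> ScoreMatrix:
    """Average directed edge scores: s'(x,y) = s'(y,x) = (s(x,y)+s(y,x))/2.

    Converts a directed complete-graph scoring into the undirected relation
    the RP framework assumes.  Rectangular inter-species matrices have no
    reverse orientation and are rejected.
    """
    if not matrix.intra_species and matrix.proteome_a.ids != matrix.proteome_b.ids:
        raise IntegrityError("cannot symmetrize a rectangular inter-species matrix")
    V = matrix.values
    both = np.isfinite(V) & np.isfinite(V.T)
    sym = np.where(both, (V + V.T) / 2.0, np.where(np.isfinite(V), V, V.T))
    return ScoreMatrix(matrix.proteome_a, matrix.proteome_a, sym, intra_species=True)


def threshold_at_specificity(
    negative_scores: Sequence[float], specificity: float
) -> GlobalThreshold:
    """Smallest score T with P(negative >= T) <= 1 - specificity.

    This is the empirical specificity-quantile convention for the global
    cutoff: with the "score >= T is positive" rule, at most a (1-specificity)
    fraction of the supplied negative sample is called positive.  When no
    finite score satisfies this (specificity = 1 with ties at the maximum),
    T is the next float above the maximum so that no negative passes.
    """
    scores = np.asarray(list(negative_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("negative score sample is empty")
    if not (0.0 < specificity <= 1.0):
        raise ValueError("specificity must be in (0, 1]")
    s = np.sort(scores)
    n = s.size
    allowed = 1.0 - specificity
    for t in np.unique(s):
        frac_ge = (n - np.searchsorted(s, t, side="left")) / n
        if frac_ge <= allowed:
            return GlobalThreshold(value=float(t), target_specificity=specificity)
    return GlobalThreshold(
        value=float(np.nextafter(s[-1], np.inf)), target_specificity=specificity
    )
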