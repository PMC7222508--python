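"""Per-generation allele-frequency trajectories, the monotone trajectory
filter, and classical MDS of genotype Hamming distances.

The central object is the per-locus trajectory of alternate-allele
frequencies across the five serial passages g1..g5.  With three diploid
mice per passage each frequency is a count over at most six chromosomes;
missing genotypes are excluded from both numerator and denominator, so
frequencies are exact rationals with denominator <= 6.

The trajectory filter keeps loci whose frequency sweeps monotonically
across the cohort: non-decreasing from g1 <= 1/3 up to g5 >= 2/3
(an allele rising toward fixation under treatment), or the mirrored
non-increasing rule (g1 >= 2/3 down to g5 <= 1/3).  Monotonicity is
non-strict: internal ties are allowed.  Thresholds are compared as exact
fractions so that boundary cases like 2/6 == 1/3 are never lost to
floating-point rounding.

Note on naming: the tracked quantity is the alternate-allele frequency,
which may exceed 0.5; it is *not* folded to the minor allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .io import GenotypeMatrix, SampleSheet

__all__ = [
    "MafTrajectory",
    "TrajectoryVerdict",
    "DistanceMatrix",
    "MdsEmbedding",
    "per_generation_maf",
    "trajectory_filter",
    "hamming_distance",
    "classical_mds",
    "separation_score",
]


@dataclass(frozen=True)
class MafTrajectory:
    """Per-generation alternate-allele frequency of one locus.

    ``alt_counts[g]`` and ``callable_chromosomes[g]`` give the exact
    numerator and denominator for generation g+1; ``defined`` is False
    when some generation has no callable chromosome at all, in which
    case the locus is excluded from filtering.
    """

    locus_id: str
    alt_counts: tuple[int, ...]
    callable_chromosomes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.alt_counts) != len(self.callable_chromosomes):
            raise ValueError("count vectors must be equal length")
        for a, c in zip(self.alt_counts, self.callable_chromosomes):
            if not 0 <= a <= c:
                raise ValueError(f"alt count {a} outside [0, {c}]")

    @property
    def defined(self) -> bool:
        return all(c > 0 for c in self.callable_chromosomes)

    @property
    def fractions(self) -> tuple[Fraction, ...]:
        """Exact per-generation frequencies; requires ``defined``."""
        if not self.defined:
            raise ValueError(f"locus {self.locus_id}: undefined frequency")
        return tuple(
            Fraction(a, c)
            for a, c in zip(self.alt_counts, self.callable_chromosomes)
        )

    @property
    def freqs(self) -> tuple[float, ...]:
        return tuple(float(f) for f in self.fractions)


@dataclass(frozen=True)
class TrajectoryVerdict:
    locus_id: str
    passes: bool
    direction: str  # "increasing", "decreasing" or "none"

    def __post_init__(self) -> None:
        if self.passes and self.direction == "none":
            raise ValueError("a passing locus must have a direction")


def per_generation_maf(g: GenotypeMatrix) -> list[MafTrajectory]:
    """Alternate-allele frequency per locus per generation.

    freq(g) = sum of dosages over non-missing samples of generation g
    divided by 2 x (number of non-missing samples); a generation with
    all samples missing leaves the trajectory undefined.
    """
    gens = sorted(set(g.sample_sheet.generations))
    gen_idx = g.sample_sheet.generation_index()
    out = []
    masks = [gen_idx == gg for gg in gens]
    for i, locus_id in enumerate(g.locus_ids):
        row = g.dosages[i]
        alt, chroms = [], []
        for m in masks:
            vals = row[m]
            ok = ~np.isnan(vals)
            alt.append(int(vals[ok].sum()))
            chroms.append(2 * int(ok.sum()))
        out.append(MafTrajectory(locus_id, tuple(alt), tuple(chroms)))
    return out


_LOW = Fraction(1, 3)
_HIGH = Fraction(2, 3)


def trajectory_filter(
    t: MafTrajectory,
    low: Fraction | float = _LOW,
    high: Fraction | float = _HIGH,
) -> TrajectoryVerdict:
    """Apply the monotone sweep filter to one trajectory.

    Increasing pass: frequencies non-decreasing g1..g5 with
    f(g1) <= ``low`` and f(g5) >= ``high``.  Decreasing pass: mirrored.
    Comparisons use exact rational arithmetic.
    """
    if not t.defined:
        raise ValueError(
            f"locus {t.locus_id}: trajectory undefined (uncallable generation)"
        )
    low = Fraction(low).limit_denominator(10**6) if not isinstance(low, Fraction) else low
    high = Fraction(high).limit_denominator(10**6) if not isinstance(high, Fraction) else high
    f = t.fractions
    nondecr = all(f[i] <= f[i + 1] for i in range(len(f) - 1))
    nonincr = all(f[i] >= f[i + 1] for i in range(len(f) - 1))
    if nondecr and f[0] <= low and f[-1] >= high:
        return TrajectoryVerdict(t.locus_id, True, "increasing")
    if nonincr and f[0] >= high and f[-1] <= low:
        return TrajectoryVerdict(t.locus_id, True, "decreasing")
    return TrajectoryVerdict(t.locus_id, False, "none")


@dataclass(frozen=True)
class DistanceMatrix:
    sample_ids: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")


def hamming_distance(
    g: GenotypeMatrix, scope_locus_ids: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pairwise Hamming proportion between sample genotype columns.

    d[i, j] = (# loci where both samples are callable and dosages
    differ) / (# mutually callable loci); loci missing in either sample
    of a pair are skipped pairwise.  Restrict to a locus subset (e.g.
    the filter-passing loci) via ``scope_locus_ids``.
    """
    if scope_locus_ids is not None:
        g = g.subset_loci(scope_locus_ids)
    n = len(g.sample_sheet)
    if n < 2:
        raise ValueError("need at least two samples")
    X = g.dosages
    callable_ = ~np.isnan(X)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = callable_[:, i] & callable_[:, j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    "no mutually callable loci for pair "
                    f"({g.sample_sheet.sample_ids[i]}, {g.sample_sheet.sample_ids[j]})"
                )
            diff = int((X[both, i] != X[both, j]).sum())
            d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(tuple(g.sample_sheet.sample_ids), d)


@dataclass(frozen=True)
class MdsEmbedding:
    sample_ids: tuple[str, ...]
    coords: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # all n eigenvalues, descending


def classical_mds(d: DistanceMatrix, k: int = 4) -> MdsEmbedding:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distance matrix, eigendecomposes, and
    scales the top-k eigenvectors by the square roots of their
    (non-negative) eigenvalues.  Axes with non-positive eigenvalues get
    zero coordinates.  Sign convention: the largest-magnitude entry of
    each coordinate is made positive, so the embedding is deterministic.
    """
    n = len(d.sample_ids)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in 1..{n - 1}")
    D2 = d.d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = np.zeros((n, k))
    for a in range(k):
        if eigvals[a] > 1e-12:
            v = eigvecs[:, a] * np.sqrt(eigvals[a])
            pivot = np.argmax(np.abs(v))
            if v[pivot] < 0:
                v = -v
            coords[:, a] = v
    return MdsEmbedding(d.sample_ids, coords, eigvals)


def separation_score(
    emb: MdsEmbedding, sheet: SampleSheet, group_generations: set[int]
) -> float:
    """Silhouette score of a declared generation split on coordinates 1-2.

    Measures how well the samples of ``group_generations`` (e.g. {5},
    the resistant passage) separate from the rest in the leading MDS
    plane; 0 for coincident points, approaching 1 for a clean split.
    """
    from sklearn.metrics import silhouette_score

    labels = np.array(
        [1 if sheet.generation_of(s) in group_generations else 0 for s in emb.sample_ids]
    )
    if labels.min() == labels.max():
        raise ValueError("both sides of the split must be non-empty")
    xy = emb.coords[:, : min(2, emb.coords.shape[1])]
    if np.allclose(xy, xy[0]):
        return 0.0
    if min(np.bincount(labels)) == 1:
        import warnings

        warnings.warn("singleton group in separation score", stacklevel=2)
    return float(silhouette_score(xy, labels))
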