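"""Contact matrices: I/O, coarsening, ICE balancing, distance decay.

The genome-wide contact map is held dense and symmetric (float64, N x N over
the layout's bin grid); at the problem sizes this package targets, a dense
array is simpler and faster than sparse bookkeeping.  Balanced matrices carry
a per-bin bias vector and use NaN for masked bins, so every downstream
statistic can treat missing data uniformly with nan-aware reductions.

ICE (iterative correction) rescales the matrix so that every usable bin has
the same total visibility.  The implementation iterates marginal division with
unit-mean rescaling and finally recomputes the balanced matrix from the raw
counts and the accumulated biases, so that

    balanced[i, j] * bias[i] * bias[j] == raw[i, j]

holds exactly (not just to iteration tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import GenomeLayout

__all__ = [
    "ContactMatrix",
    "DecayProfile",
    "read_matrix",
    "write_matrix",
    "coarsen",
    "ice_normalize",
    "decay_profile",
]


class MatrixFormatError(ValueError):
    """Malformed sparse-triplet input."""


@dataclass
class ContactMatrix:
    """Symmetric binned contact map over a :class:`GenomeLayout` grid."""

    layout: GenomeLayout
    data: np.ndarray  # (N, N) float64, symmetric; NaN on masked bins iff balanced
    balanced: bool = False
    bias: np.ndarray | None = None  # per-bin; NaN where masked

    def __post_init__(self) -> None:
        n = self.layout.n_bins
        if self.data.shape != (n, n):
            raise ValueError(f"data shape {self.data.shape} != layout bins ({n})")

    @property
    def bins(self) -> pd.DataFrame:
        return self.layout.bins

    @property
    def n_bins(self) -> int:
        return self.layout.n_bins

    def chrom_slices(self) -> dict[str, slice]:
        return self.layout.chrom_slices()

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.layout,
            self.data.copy(),
            self.balanced,
            None if self.bias is None else self.bias.copy(),
        )

    def mask(self) -> np.ndarray:
        """Boolean vector, True where the bin is usable."""
        if self.bias is None:
            return np.ones(self.n_bins, dtype=bool)
        return np.isfinite(self.bias)

    def total(self) -> float:
        """Sum over unordered bin pairs (each off-diagonal pair counted once)."""
        d = np.nan_to_num(self.data)
        return float((d.sum() + np.trace(d)) / 2.0)


# ---------------------------------------------------------------------------
# sparse-triplet TSV I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["chrom1", "start1", "chrom2", "start2", "count"]


def write_matrix(matrix: ContactMatrix, path) -> None:
    """Write non-zero upper-triangle entries as a 5-column TSV.

    Columns: chrom1, start1, chrom2, start2, count; 0-based half-open bin
    starts; each unordered pair appears exactly once (lower global index
    first).  NaN entries of balanced matrices are omitted.
    """
    bins = matrix.bins
    iu, ju = np.triu_indices(matrix.n_bins)
    vals = matrix.data[iu, ju]
    keep = np.isfinite(vals) & (vals != 0)
    df = pd.DataFrame(
        {
            "chrom1": bins["chrom"].to_numpy()[iu[keep]],
            "start1": bins["start"].to_numpy()[iu[keep]],
            "chrom2": bins["chrom"].to_numpy()[ju[keep]],
            "start2": bins["start"].to_numpy()[ju[keep]],
            "count": vals[keep],
        }
    )
    df.to_csv(path, sep="\t", index=False, header=True, float_format="%.17g")


def read_matrix(path, layout: GenomeLayout) -> ContactMatrix:
    """Read a sparse-triplet TSV written by :func:`write_matrix`.

    Raises :class:`MatrixFormatError` naming the offending line for unknown
    chromosomes, starts off the bin grid, or duplicate unordered pairs
    (including a pair listed in both orientations).
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise MatrixFormatError(f"{path}: missing columns {missing}")
    slices = layout.chrom_slices()
    bs = layout.bin_size
    n = layout.n_bins
    data = np.zeros((n, n))
    seen: set[tuple[int, int]] = set()
    lengths = {c.name: c.length for c in layout.chromosomes}
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        idx = []
        for chrom, start in ((row.chrom1, row.start1), (row.chrom2, row.start2)):
            if chrom not in slices:
                raise MatrixFormatError(f"{path}:{line_no}: unknown chromosome {chrom!r}")
            if start % bs != 0 or not 0 <= start < lengths[chrom]:
                raise MatrixFormatError(
                    f"{path}:{line_no}: start {start} not on the {bs}-bp bin grid"
                )
            idx.append(slices[chrom].start + start // bs)
        i, j = min(idx), max(idx)
        if (i, j) in seen:
            raise MatrixFormatError(
                f"{path}:{line_no}: duplicate unordered bin pair "
                f"({row.chrom1}:{row.start1}, {row.chrom2}:{row.start2})"
            )
        seen.add((i, j))
        data[i, j] = data[j, i] = row.count
    return ContactMatrix(layout, data)


# ---------------------------------------------------------------------------
# coarsening
# ---------------------------------------------------------------------------


def coarsen(matrix: ContactMatrix, factor: int) -> ContactMatrix:
    """Merge ``factor`` consecutive bins (never across chromosome boundaries).

    Counts are summed within merged bins; total matrix mass is conserved.
    Operates on raw values; the result is unbalanced.
    """
    if factor < 1:
        raise ValueError(f"coarsening factor must be >= 1, got {factor}")
    if factor == 1:
        return matrix.copy()
    new_layout = matrix.layout.with_bin_size(matrix.layout.bin_size * factor)
    # map old global bin -> new global bin
    mapping = np.empty(matrix.n_bins, dtype=int)
    new_lo = 0
    for c in matrix.layout.chromosomes:
        sl = matrix.chrom_slices()[c.name]
        old_local = np.arange(sl.stop - sl.start)
        mapping[sl] = new_lo + old_local // factor
        new_lo += new_layout.n_bins_of(c)
    m = new_layout.n_bins
    # two-sided aggregation via indicator matrix
    ind = np.zeros((m, matrix.n_bins))
    ind[mapping, np.arange(matrix.n_bins)] = 1.0
    data = ind @ np.nan_to_num(matrix.data) @ ind.T
    data = (data + data.T) / 2.0  # exact symmetry against fp drift
    return ContactMatrix(new_layout, data)


# ---------------------------------------------------------------------------
# ICE balancing
# ---------------------------------------------------------------------------


def ice_normalize(
    matrix: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    mask_fraction: float = 0.02,
) -> ContactMatrix:
    """Iteratively correct a raw matrix to uniform bin visibility.

    Bins with zero coverage, plus the lowest ``mask_fraction`` of positive-
    coverage bins, are masked (bias NaN, rows/columns NaN in the output).
    Iteration stops when the coefficient of variation of the usable marginals
    drops below ``tol``.  The returned matrix satisfies
    ``balanced[i,j] * bias[i] * bias[j] == raw[i,j]`` exactly on usable pairs.
    """
    if matrix.balanced:
        raise ValueError("matrix is already balanced")
    raw = np.nan_to_num(matrix.data)
    n = matrix.n_bins
    coverage = raw.sum(axis=1)
    usable = coverage > 0
    if usable.any() and mask_fraction > 0:
        cutoff = np.quantile(coverage[usable], mask_fraction)
        usable &= coverage > cutoff
        if not usable.any():  # tiny matrices: keep the top-coverage bins
            usable = coverage >= coverage.max()
    if not usable.any():
        raise ValueError("all bins masked: matrix has no coverage")

    work = raw[np.ix_(usable, usable)].astype(float)
    bias_u = np.ones(work.shape[0])
    for _ in range(max_iter):
        marg = work.sum(axis=1)
        mean = marg.mean()
        if mean == 0:
            raise ValueError("degenerate input: usable sub-matrix sums to zero")
        cv = marg.std() / mean
        if cv < tol:
            break
        s = marg / mean
        work /= np.outer(s, s)
        bias_u *= s

    bias = np.full(n, np.nan)
    bias[usable] = bias_u
    data = np.full((n, n), np.nan)
    data[np.ix_(usable, usable)] = raw[np.ix_(usable, usable)] / np.outer(bias_u, bias_u)
    return ContactMatrix(matrix.layout, data, balanced=True, bias=bias)


def ice_marginal_cv(matrix: ContactMatrix) -> float:
    """Coefficient of variation of the usable-bin marginals (diagnostic)."""
    usable = matrix.mask()
    d = np.nan_to_num(matrix.data)[np.ix_(usable, usable)]
    marg = d.sum(axis=1)
    return float(marg.std() / marg.mean())


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------


@dataclass
class DecayProfile:
    """Per-separation mean/sd/n of intra-chromosomal contact values.

    Distances are in bins (d = 1..D); separations with no defined pair are
    omitted.  ``mean_at`` interpolates nothing: missing distances raise.
    """

    distances: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    _index: dict[int, int] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self._index = {int(d): k for k, d in enumerate(self.distances)}

    def mean_at(self, d: int) -> float:
        return float(self.mean[self._index[int(d)]])

    def has(self, d: int) -> bool:
        return int(d) in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"distance_bins": self.distances, "mean": self.mean, "sd": self.sd, "n": self.n}
        )


def decay_profile(matrix: ContactMatrix) -> DecayProfile:
    """Mean/sd/count of contact values per intra-chromosomal bin separation.

    Pools all chromosomes; masked (NaN) pairs are excluded.  Raises on layouts
    with no intra-chromosomal off-diagonal pair.
    """
    max_d = max(
        (sl.stop - sl.start - 1 for sl in matrix.chrom_slices().values()), default=0
    )
    if max_d < 1:
        raise ValueError("no intra-chromosomal bin pairs: cannot build a decay profile")
    dists, means, sds, ns = [], [], [], []
    slices = list(matrix.chrom_slices().values())
    for d in range(1, max_d + 1):
        vals = []
        for sl in slices:
            sub = matrix.data[sl, sl]
            if sub.shape[0] > d:
                vals.append(np.diagonal(sub, offset=d))
        v = np.concatenate(vals) if vals else np.array([])
        v = v[np.isfinite(v)]
        if v.size == 0:
            continue
        dists.append(d)
        means.append(v.mean())
        sds.append(v.std())
        ns.append(v.size)
    return DecayProfile(
        np.asarray(dists), np.asarray(means), np.asarray(sds), np.asarray(ns, dtype=int)
    )
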