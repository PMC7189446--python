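"""Genome-territory statistics: class-wise interaction distributions.

Contacts are aggregated into large super-bins (10 Mb in the wheat analysis),
scaled to counts-per-million of the matrix total, and every unordered
super-bin pair is classified as intra-chromosomal, interchromosomal within a
subgenome, or interchromosomal between two subgenomes; inter-subgenome
chromosome pairs additionally carry a homeolog flag (same homeolog group,
different subgenome).  Class medians quantify the territory hierarchy; the
homeolog vs non-homeolog contrast is tested with a Mann-Whitney U and a
Cliff's Delta effect size.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ContactMatrix

__all__ = [
    "classify_and_aggregate",
    "median_by_class",
    "mann_whitney_u",
    "cliffs_delta",
    "compare_samples",
    "homeolog_contrast",
    "TwoSampleResult",
]

INTRA = "intra_chromosome"
SAME_SUB = "inter_same_subgenome"
CROSS_SUB = "inter_subgenome"


@dataclass(frozen=True)
class TwoSampleResult:
    """Mann-Whitney U with two-sided p, plus Cliff's Delta in [-1, 1]."""

    u: float
    p: float
    cliffs_delta: float
    n1: int
    n2: int


def classify_and_aggregate(matrix: ContactMatrix, super_bin: int = 10_000_000) -> pd.DataFrame:
    """Aggregate into super-bins and classify every unordered pair.

    Returns one row per unordered super-bin pair with columns ``chrom1``,
    ``start1``, ``chrom2``, ``start2``, ``cls``, ``subgenome_pair``,
    ``homeolog`` (None for non-inter-subgenome pairs), ``cpm`` (balanced
    counts per million of the matrix total; sums to 1e6 over all pairs),
    ``n_pairs`` (distinct bin pairs in the block) and ``freq`` = cpm /
    n_pairs, the per-bin-pair normalized frequency used for medians (the
    diagonal block of a super-bin holds fewer distinct pairs than an
    off-diagonal block, so raw mass alone is not comparable across classes).
    Super-bins never span chromosomes; the last super-bin may be short.
    """
    bs = matrix.layout.bin_size
    if super_bin % bs != 0:
        raise ValueError(f"super_bin {super_bin} is not a multiple of bin_size {bs}")
    layout = matrix.layout
    # super-bin index per genome bin
    sb_of = np.empty(matrix.n_bins, dtype=int)
    sb_meta = []  # (chrom, start)
    nxt = 0
    for c in layout.chromosomes:
        sl = layout.chrom_slices()[c.name]
        local = layout.bins["start"].to_numpy()[sl] // super_bin
        for s in np.unique(local):
            sb_of[sl.start + np.flatnonzero(local == s)] = nxt
            sb_meta.append((c.name, int(s) * super_bin))
            nxt += 1
    m = nxt
    sb_sizes = np.bincount(sb_of, minlength=m)
    ind = np.zeros((m, matrix.n_bins))
    ind[sb_of, np.arange(matrix.n_bins)] = 1.0
    dense = np.nan_to_num(matrix.data)
    agg = ind @ dense @ ind.T
    diag_sb = ind @ np.diagonal(dense)  # bin-level self pairs per super-bin
    # unordered-pair mass: off-diagonal blocks stored once, within-block pairs once
    total = (agg.sum() + diag_sb.sum()) / 2.0
    if total <= 0:
        raise ValueError("matrix has no usable contacts")

    chrom_info = {c.name: c for c in layout.chromosomes}
    rows = []
    for a in range(m):
        for b in range(a, m):
            ca, sa = sb_meta[a]
            cb, sb_ = sb_meta[b]
            ia, ib = chrom_info[ca], chrom_info[cb]
            if ca == cb:
                cls, pair, hom = INTRA, ia.subgenome + ia.subgenome, None
            elif ia.subgenome == ib.subgenome:
                cls, pair, hom = SAME_SUB, ia.subgenome + ib.subgenome, None
            else:
                cls = CROSS_SUB
                pair = "".join(sorted((ia.subgenome, ib.subgenome)))
                hom = ia.homeolog_group == ib.homeolog_group
            na, nb = sb_sizes[a], sb_sizes[b]
            if a != b:
                value, n_pairs = agg[a, b], na * nb
            else:
                value = (agg[a, a] + diag_sb[a]) / 2.0
                n_pairs = na * (na + 1) // 2
            cpm = value / total * 1e6
            rows.append(
                {
                    "chrom1": ca,
                    "start1": sa,
                    "chrom2": cb,
                    "start2": sb_,
                    "cls": cls,
                    "subgenome_pair": pair,
                    "homeolog": hom,
                    "cpm": cpm,
                    "n_pairs": n_pairs,
                    "freq": cpm / n_pairs,
                }
            )
    return pd.DataFrame(rows)


def median_by_class(table: pd.DataFrame) -> dict:
    """Per-class and per-subgenome-pair medians of ``freq``, plus the hierarchy flag.

    ``hierarchy_ok`` is True when median(intra) >= median(same-subgenome) >=
    median(cross-subgenome); absent classes are skipped, not errors.
    """
    if table.empty:
        raise ValueError("empty pair-class table")
    cls_medians = table.groupby("cls")["freq"].median().to_dict()
    pair_medians = table.groupby("subgenome_pair")["freq"].median().to_dict()
    chain = [cls_medians.get(k) for k in (INTRA, SAME_SUB, CROSS_SUB)]
    present = [v for v in chain if v is not None]
    ok = all(x >= y for x, y in zip(present, present[1:]))
    return {
        "class_medians": cls_medians,
        "subgenome_pair_medians": pair_medians,
        "hierarchy_ok": ok,
    }


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p).

    U counts pairs with x > y plus half the ties.  For n1 + n2 <= 12 the
    p-value is computed by exact enumeration of all label assignments
    (tie-safe); larger samples use the normal approximation with tie
    correction (scipy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    u = _u_statistic(x, y)
    n1, n2 = x.size, y.size
    if n1 + n2 <= 12:
        pooled = np.concatenate([x, y])
        centre = n1 * n2 / 2.0
        dev = abs(u - centre)
        hits = total = 0
        for pick in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(pick)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - centre) >= dev - 1e-12:
                hits += 1
        return u, hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


def cliffs_delta(x, y) -> float:
    """Cliff's Delta: (#{x_i > y_j} - #{x_i < y_j}) / (n1*n2); ties count 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    gt = (x[:, None] > y[None, :]).sum()
    lt = (x[:, None] < y[None, :]).sum()
    return float(gt - lt) / (x.size * y.size)


def compare_samples(x, y) -> TwoSampleResult:
    """Mann-Whitney U + Cliff's Delta in one record."""
    u, p = mann_whitney_u(x, y)
    return TwoSampleResult(u=u, p=p, cliffs_delta=cliffs_delta(x, y), n1=len(x), n2=len(y))


def homeolog_contrast(table: pd.DataFrame) -> TwoSampleResult:
    """Homeolog vs non-homeolog super-bin pairs among inter-subgenome pairs."""
    inter = table[table["cls"] == CROSS_SUB]
    hom = inter.loc[inter["homeolog"] == True, "freq"].to_numpy()  # noqa: E712
    non = inter.loc[inter["homeolog"] == False, "freq"].to_numpy()  # noqa: E712
    return compare_samples(hom, non)
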