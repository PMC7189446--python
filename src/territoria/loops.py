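"""Significance-based chromatin-loop calling.

Intra-chromosomal expected counts follow a coverage-scaled distance-decay
model, expected(i, j) = decay_mean(d_ij) * cov_i * cov_j / mean_cov^2;
interchromosomal expected counts follow a coverage-product model,
expected(i, j) = 2 * T * (cov_i / T) * (cov_j / T) with T the unordered-pair
total.  Each tested pair gets a Z-score (obs - exp) / sqrt(exp), an
upper-tail Poisson p-value, and a Benjamini-Hochberg q-value over the tested
pool (per resolution and per kind).  Loops are pairs passing all three
filters simultaneously: p < p_max, Z > z_min, q < q_max — defaults match the
published calling parameters (p < 0.05, Z > 1.5, FDR < 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ContactMatrix, decay_profile

__all__ = [
    "LoopSet",
    "call_loops_intra",
    "call_interactions_inter",
    "bh_fdr",
    "conserved_loops",
    "write_bedpe",
    "read_bedpe",
]

_LOOP_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "bin1", "bin2", "observed", "expected", "z", "p", "q", "kind",
]


@dataclass
class LoopSet:
    """Loops passing thresholds, plus the calling provenance."""

    loops: pd.DataFrame
    resolution: int
    p_max: float
    z_min: float
    q_max: float
    kind: str  # "intra" | "inter"
    n_tested: int = 0
    condition: str = ""

    def __len__(self) -> int:
        return len(self.loops)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Standard step-up: q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1;
    monotone in sorted order and q >= p elementwise.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _coverage(matrix: ContactMatrix) -> np.ndarray:
    return np.nan_to_num(matrix.data).sum(axis=1)


def _assemble(matrix, i, j, obs, exp, z, p, q, keep, kind) -> pd.DataFrame:
    bins = matrix.bins
    return pd.DataFrame(
        {
            "chrom1": bins["chrom"].to_numpy()[i[keep]],
            "start1": bins["start"].to_numpy()[i[keep]],
            "end1": bins["end"].to_numpy()[i[keep]],
            "chrom2": bins["chrom"].to_numpy()[j[keep]],
            "start2": bins["start"].to_numpy()[j[keep]],
            "end2": bins["end"].to_numpy()[j[keep]],
            "bin1": i[keep],
            "bin2": j[keep],
            "observed": obs[keep],
            "expected": exp[keep],
            "z": z[keep],
            "p": p[keep],
            "q": q[keep],
            "kind": kind,
        }
    )


def call_loops_intra(
    matrix: ContactMatrix,
    p_max: float = 0.05,
    z_min: float = 1.5,
    q_max: float = 0.1,
    min_distance_bins: int = 2,
    max_distance: int | None = None,
    condition: str = "",
) -> LoopSet:
    """Call significant intra-chromosomal bin-pair interactions.

    The matrix must already be at the calling resolution (coarsen first).
    Pairs closer than ``min_distance_bins`` are excluded (diagonal and
    adjacent bins); pairs with zero/undefined expected are skipped.
    """
    decay = decay_profile(matrix)
    cov = _coverage(matrix)
    usable = cov > 0
    mean_cov = cov[usable].mean()
    max_d_bins = (
        None if max_distance is None else max(max_distance // matrix.layout.bin_size, 1)
    )

    ii, jj, obs, exp = [], [], [], []
    for sl in matrix.chrom_slices().values():
        n_c = sl.stop - sl.start
        li, lj = np.triu_indices(n_c, k=min_distance_bins)
        d = lj - li
        if max_d_bins is not None:
            keep = d <= max_d_bins
            li, lj, d = li[keep], lj[keep], d[keep]
        gi, gj = li + sl.start, lj + sl.start
        dmean = np.array([decay.mean_at(x) if decay.has(x) else np.nan for x in d])
        e = dmean * cov[gi] * cov[gj] / mean_cov**2
        o = np.nan_to_num(matrix.data)[gi, gj]
        good = usable[gi] & usable[gj] & np.isfinite(e) & (e > 0)
        ii.append(gi[good]); jj.append(gj[good])
        obs.append(o[good]); exp.append(e[good])
    i = np.concatenate(ii); j = np.concatenate(jj)
    obs = np.concatenate(obs); exp = np.concatenate(exp)

    z = (obs - exp) / np.sqrt(exp)
    p = stats.poisson.sf(obs - 1, exp)  # upper tail: P(X >= obs)
    q = bh_fdr(p)
    keep = (p < p_max) & (z > z_min) & (q < q_max)
    loops = _assemble(matrix, i, j, obs, exp, z, p, q, keep, "intra")
    return LoopSet(
        loops, matrix.layout.bin_size, p_max, z_min, q_max, "intra",
        n_tested=int(p.size), condition=condition,
    )


def call_interactions_inter(
    matrix: ContactMatrix,
    p_max: float = 0.05,
    z_min: float = 1.5,
    q_max: float = 0.1,
    condition: str = "",
) -> LoopSet:
    """Call significant interchromosomal bin-pair interactions."""
    import warnings

    if len(matrix.layout.chromosomes) < 2:
        warnings.warn("single-chromosome layout: no interchromosomal pairs")
        return LoopSet(
            pd.DataFrame(columns=_LOOP_COLUMNS), matrix.layout.bin_size,
            p_max, z_min, q_max, "inter", n_tested=0, condition=condition,
        )
    cov = _coverage(matrix)
    total = matrix.total()
    slices = list(matrix.chrom_slices().values())
    ii, jj = [], []
    for a in range(len(slices)):
        for b in range(a + 1, len(slices)):
            gi, gj = np.meshgrid(
                np.arange(slices[a].start, slices[a].stop),
                np.arange(slices[b].start, slices[b].stop),
                indexing="ij",
            )
            ii.append(gi.ravel()); jj.append(gj.ravel())
    i = np.concatenate(ii); j = np.concatenate(jj)
    exp = 2.0 * total * (cov[i] / total) * (cov[j] / total)
    obs = np.nan_to_num(matrix.data)[i, j]
    good = exp > 0
    i, j, obs, exp = i[good], j[good], obs[good], exp[good]
    z = (obs - exp) / np.sqrt(exp)
    p = stats.poisson.sf(obs - 1, exp)
    q = bh_fdr(p)
    keep = (p < p_max) & (z > z_min) & (q < q_max)
    loops = _assemble(matrix, i, j, obs, exp, z, p, q, keep, "inter")
    return LoopSet(
        loops, matrix.layout.bin_size, p_max, z_min, q_max, "inter",
        n_tested=int(p.size), condition=condition,
    )


def conserved_loops(set_a: LoopSet, set_b: LoopSet) -> LoopSet:
    """Loops of A whose both anchors overlap (>= 1 bp) anchors of a B loop.

    Sets at different resolutions are matched on the coarser grid.  The
    result carries A's statistics plus ``z_other`` (the best-matching B
    loop's Z; the match maximizing z_other is kept).
    """
    a, b = set_a.loops, set_b.loops
    out = a.copy()
    out["z_other"] = np.nan
    if a.empty or b.empty:
        return LoopSet(
            out.iloc[0:0], set_a.resolution, set_a.p_max, set_a.z_min, set_a.q_max,
            set_a.kind, condition=f"{set_a.condition}&{set_b.condition}",
        )
    grid = max(set_a.resolution, set_b.resolution)

    def keys(df):
        # anchor pair on the coarse grid, canonically ordered
        k1 = list(zip(df["chrom1"], df["start1"] // grid))
        k2 = list(zip(df["chrom2"], df["start2"] // grid))
        return [tuple(sorted([x, y])) for x, y in zip(k1, k2)]

    best: dict[tuple, float] = {}
    for key, zb in zip(keys(b), b["z"]):
        if key not in best or zb > best[key]:
            best[key] = zb
    z_other = np.array([best.get(key, np.nan) for key in keys(a)])
    out["z_other"] = z_other
    out = out[np.isfinite(z_other)].reset_index(drop=True)
    return LoopSet(
        out, set_a.resolution, set_a.p_max, set_a.z_min, set_a.q_max, set_a.kind,
        n_tested=set_a.n_tested, condition=f"{set_a.condition}&{set_b.condition}",
    )


def write_bedpe(loop_set: LoopSet, path) -> None:
    """BEDPE with name, score = Z, and obs/exp/p/q extra columns."""
    df = loop_set.loops
    out = df[["chrom1", "start1", "end1", "chrom2", "start2", "end2"]].copy()
    out["name"] = [f"loop_{k}" for k in range(len(df))]
    out["score"] = df["z"].to_numpy()
    for col in ("observed", "expected", "p", "q"):
        out[col] = df[col].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bedpe(path, kind: str = "intra") -> LoopSet:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"score": "z", "observed": "observed", "expected": "expected"})
    resolution = int((df["end1"] - df["start1"]).max()) if len(df) else 0
    return LoopSet(df, resolution, np.nan, np.nan, np.nan, kind)
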