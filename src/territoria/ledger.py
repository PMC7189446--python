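"""Gene-pair ledger: anchor annotation, feature associations, concordance.

Loop anchors are annotated with overlapping genes (any overlap, >= 1 bp);
every gene-in-anchor1 x gene-in-anchor2 combination becomes a pair record
carrying both genes' epigenetic flags, expression and loop strength — the
analog of the study's deposited pair table.  On that table the module
computes 2x2 feature-association statistics (odds ratio with a
Haldane-Anscombe correction for zero cells, chi-square without continuity
correction, Cramer's V = sqrt(chi2 / n)), the full feature x feature
association ledger, expression-quantile concordance matrices, and per-gene
partner-count distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .loops import LoopSet

__all__ = [
    "annotate_anchors",
    "feature_association",
    "association_matrix",
    "expression_concordance",
    "partner_counts",
    "read_pair_table",
    "ContingencyResult",
]

#: gene columns copied onto each pair record (when present)
PAIR_FEATURES = ["H3K9ac", "H3K36me3", "H3K27me3", "RNAPII", "ATAC", "expressed"]
_GENE_COLS = ["gene_id", "chrom", "start", "end"]


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 association: counts, odds ratio, chi2, p, Cramer's V."""

    a: int  # feature1 & feature2
    b: int  # feature1 & ~feature2
    c: int  # ~feature1 & feature2
    d: int  # neither
    odds_ratio: float
    log2_or: float
    chi2: float
    p: float
    cramers_v: float
    haldane_applied: bool

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def _gene_trees(genes: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in genes.groupby("chrom", sort=False):
        tree = IntervalTree()
        for idx, r in grp.iterrows():
            if r["end"] > r["start"]:
                tree[r["start"] : r["end"]] = idx
        trees[chrom] = tree
    return trees


def annotate_anchors(loop_set: LoopSet, genes: pd.DataFrame) -> pd.DataFrame:
    """Emit one pair record per (gene in anchor1) x (gene in anchor2).

    Any-overlap rule (>= 1 bp); loops with a gene-less anchor are dropped, as
    are pairs mapping both anchors to the same gene.  Intra-chromosomal pairs
    are ordered genomically (gene1 upstream); interchromosomal pairs by
    chromosome name.  Loop z (and z_other, if present) are copied onto the
    record, along with the genes' feature flags, TPM, log2FC and DE p-value.
    """
    trees = _gene_trees(genes)
    extra = [c for c in PAIR_FEATURES + ["tpm_shoot", "tpm_root", "log2fc", "de_pvalue"]
             if c in genes.columns]
    rows = []
    for loop_id, lp in enumerate(loop_set.loops.itertuples()):
        t1 = trees.get(lp.chrom1)
        t2 = trees.get(lp.chrom2)
        g1 = sorted(iv.data for iv in t1[lp.start1 : lp.end1]) if t1 else []
        g2 = sorted(iv.data for iv in t2[lp.start2 : lp.end2]) if t2 else []
        if not g1 or not g2:
            continue
        for i1 in g1:
            for i2 in g2:
                if i1 == i2:
                    continue  # same gene overlapping both anchors
                ga, gb = genes.loc[i1], genes.loc[i2]
                # canonical orientation
                if (ga["chrom"], ga["start"]) > (gb["chrom"], gb["start"]):
                    ga, gb = gb, ga
                rec = {"loop_id": loop_id, "kind": lp.kind, "z": lp.z}
                if hasattr(lp, "z_other"):
                    rec["z_other"] = lp.z_other
                if ga["chrom"] == gb["chrom"]:
                    mid_a = (ga["start"] + ga["end"]) / 2
                    mid_b = (gb["start"] + gb["end"]) / 2
                    rec["distance"] = abs(mid_b - mid_a)
                else:
                    rec["distance"] = np.nan
                for tag, g in (("1", ga), ("2", gb)):
                    rec[f"gene{tag}"] = g["gene_id"]
                    for col in extra:
                        rec[f"{col}{tag}"] = g[col]
                rows.append(rec)
    pairs = pd.DataFrame(rows)
    if not pairs.empty:
        pairs = pairs[pairs["gene1"] != pairs["gene2"]].reset_index(drop=True)
    return pairs


def _contingency(a: int, b: int, c: int, d: int) -> ContingencyResult:
    n = a + b + c + d
    if n < 1:
        raise ValueError("empty contingency table")
    haldane = 0 in (a, b, c, d)
    aa, bb, cc, dd = (v + 0.5 for v in (a, b, c, d)) if haldane else (a, b, c, d)
    odds = (aa * dd) / (bb * cc)
    table = np.array([[a, b], [c, d]], dtype=float)
    rows_ok = table.sum(axis=1).min() > 0
    cols_ok = table.sum(axis=0).min() > 0
    if rows_ok and cols_ok:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    else:  # degenerate margin: no association measurable
        chi2, p = 0.0, 1.0
    return ContingencyResult(
        a=a, b=b, c=c, d=d,
        odds_ratio=float(odds),
        log2_or=float(np.log2(odds)),
        chi2=float(chi2),
        p=float(p),
        cramers_v=float(np.sqrt(chi2 / n)),
        haldane_applied=haldane,
    )


def feature_association(
    pairs: pd.DataFrame, feature1: str, feature2: str
) -> ContingencyResult:
    """2x2 association between feature1 on gene1 and feature2 on gene2."""
    if pairs.empty:
        raise ValueError("empty pair table")
    f1 = pairs[f"{feature1}1"].astype(bool).to_numpy()
    f2 = pairs[f"{feature2}2"].astype(bool).to_numpy()
    a = int((f1 & f2).sum())
    b = int((f1 & ~f2).sum())
    c = int((~f1 & f2).sum())
    d = int((~f1 & ~f2).sum())
    return _contingency(a, b, c, d)


def association_matrix(
    pairs: pd.DataFrame, features: list[str], symmetrize: bool = True
) -> pd.DataFrame:
    """Association ledger over all ordered feature combinations.

    With ``symmetrize`` (default) each unordered pair contributes both
    orientations (genes swapped and pooled), making the ledger invariant to
    which gene the annotation listed first.  Returns one row per
    (feature1, feature2) with the contingency statistics.
    """
    for f in features:
        if f"{f}1" not in pairs.columns or f"{f}2" not in pairs.columns:
            raise ValueError(f"unknown feature {f!r}")
    work = pairs
    if symmetrize:
        swapped = pairs.copy()
        for f in set(features) | {
            c[:-1] for c in pairs.columns if c.endswith("1") and c != "gene1"
        }:
            c1, c2 = f"{f}1", f"{f}2"
            if c1 in pairs.columns and c2 in pairs.columns:
                swapped[c1], swapped[c2] = pairs[c2], pairs[c1]
        work = pd.concat([pairs, swapped], ignore_index=True)
    rows = []
    for f1 in features:
        for f2 in features:
            r = feature_association(work, f1, f2)
            rows.append(
                {
                    "feature1": f1, "feature2": f2,
                    "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                    "odds_ratio": r.odds_ratio, "log2_or": r.log2_or,
                    "chi2": r.chi2, "p": r.p, "cramers_v": r.cramers_v,
                    "haldane_applied": r.haldane_applied,
                }
            )
    return pd.DataFrame(rows)


def _quantile_labels(x: np.ndarray, n_quantiles: int) -> np.ndarray:
    """Left-closed quantile labels 0..n-1; values at a break go to the lower bin."""
    breaks = np.quantile(x, np.arange(1, n_quantiles) / n_quantiles)
    if np.unique(breaks).size < breaks.size or (x == x[0]).all():
        raise ValueError("degenerate quantiles: too many tied values")
    return np.searchsorted(breaks, x, side="left")


def expression_concordance(
    pairs: pd.DataFrame,
    n_quantiles: int = 4,
    tpm_col: str = "tpm_shoot",
) -> pd.DataFrame:
    """Quantile x quantile count matrix of partner expression levels.

    Restricted to pairs with TPM > 0 on both genes; quantile breaks computed
    independently for the two sides.  The returned matrix is indexed by
    gene1 quantile (rows) and gene2 quantile (columns); the diagonal-mass
    fraction is stored in ``matrix.attrs["diagonal_fraction"]``.
    """
    t1 = pairs[f"{tpm_col}1"].to_numpy(dtype=float)
    t2 = pairs[f"{tpm_col}2"].to_numpy(dtype=float)
    keep = (t1 > 0) & (t2 > 0)
    if keep.sum() < n_quantiles:
        raise ValueError(f"need >= {n_quantiles} expressed pairs, have {int(keep.sum())}")
    q1 = _quantile_labels(t1[keep], n_quantiles)
    q2 = _quantile_labels(t2[keep], n_quantiles)
    counts = np.zeros((n_quantiles, n_quantiles), dtype=int)
    np.add.at(counts, (q1, q2), 1)
    out = pd.DataFrame(
        counts,
        index=[f"q{k + 1}" for k in range(n_quantiles)],
        columns=[f"q{k + 1}" for k in range(n_quantiles)],
    )
    out.attrs["diagonal_fraction"] = float(np.trace(counts)) / counts.sum()
    return out


def partner_counts(pairs: pd.DataFrame) -> tuple[pd.Series, dict[str, float]]:
    """Distinct-partner count per gene, plus fractions with >= 4 / >= 10.

    Duplicate pairs count once; returns (per-gene Series, summary dict).
    """
    if pairs.empty:
        raise ValueError("empty pair table")
    edges = pd.concat(
        [
            pairs[["gene1", "gene2"]],
            pairs[["gene2", "gene1"]].rename(columns={"gene2": "gene1", "gene1": "gene2"}),
        ],
        ignore_index=True,
    ).drop_duplicates()
    counts = edges.groupby("gene1")["gene2"].nunique().sort_index()
    counts.name = "n_partners"
    summary = {
        "fraction_ge_4": float((counts >= 4).mean()),
        "fraction_ge_10": float((counts >= 10).mean()),
    }
    return counts, summary


#: default column mapping for ingesting a deposited pair table
DEFAULT_PAIR_COLUMNS = {
    "gene1": "gene1",
    "gene2": "gene2",
    "expressed1": "expressed1",
    "expressed2": "expressed2",
}


def read_pair_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a deposited gene-pair table (TSV) onto the pair-record schema.

    ``column_map`` maps our canonical column names to the file's column
    names; unmapped canonical columns that are absent are left out.  Columns
    holding "expressed"/"non-expressed" style labels or 0/1 flags are coerced
    to booleans.
    """
    cmap = dict(DEFAULT_PAIR_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t")
    out = pd.DataFrame(index=df.index)
    for canon, src in cmap.items():
        if src not in df.columns:
            continue
        col = df[src]
        if canon.startswith(tuple(PAIR_FEATURES)):
            if col.dtype == object:
                col = col.astype(str).str.strip().str.lower().isin(
                    ["1", "true", "yes", "expressed"]
                )
            else:
                col = col.astype(float) > 0
        out[canon] = col
    missing = [c for c in ("gene1", "gene2") if c not in out.columns]
    if missing:
        raise ValueError(f"{path}: pair table lacks mapped columns {missing}")
    return out
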