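"""Plain-text I/O for gene tables and related tracks.

Genes travel as BED6 plus a sidecar TSV keyed by gene_id (marks as a
semicolon list, per-condition TPM replicates, log2FC, DE p-value), so both
halves stay greppable and diffable.
"""

from __future__ import annotations

import pandas as pd

from .simulate import MARKS

__all__ = ["write_genes", "read_genes"]

_SIDECAR_COLS = [
    "gene_id", "marks",
    "tpm_shoot_1", "tpm_shoot_2", "tpm_shoot_3",
    "tpm_root_1", "tpm_root_2", "tpm_root_3",
    "log2fc", "de_pvalue",
]


def write_genes(genes: pd.DataFrame, bed_path, sidecar_path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes.get("strand", "+"),
        }
    )
    bed.to_csv(bed_path, sep="\t", index=False, header=False)
    cols = [c for c in _SIDECAR_COLS if c in genes.columns]
    genes[cols].to_csv(sidecar_path, sep="\t", index=False, float_format="%.6g")


def read_genes(bed_path, sidecar_path) -> pd.DataFrame:
    bed = pd.read_csv(
        bed_path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    side = pd.read_csv(sidecar_path, sep="\t")
    genes = bed.drop(columns=["score"]).merge(side, on="gene_id", how="left")
    marks = genes["marks"].fillna("")
    for m in MARKS:
        genes[m] = marks.str.split(";").apply(lambda parts: m in parts)
    for cond in ("shoot", "root"):
        reps = [f"tpm_{cond}_{r}" for r in (1, 2, 3) if f"tpm_{cond}_{r}" in genes.columns]
        if reps:
            genes[f"tpm_{cond}"] = genes[reps].median(axis=1)
    if "tpm_shoot" in genes.columns:
        genes["expressed"] = genes["tpm_shoot"] > 0
    return genes
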