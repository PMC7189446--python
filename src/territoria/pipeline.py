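"""End-to-end orchestration from one structured configuration.

Stages run in dependency order — simulate -> balance -> (territories,
insulation, loops) -> ledger -> coregulation — writing plain-text artifacts
into a write-once output directory and recording every file with a SHA-256
checksum in ``manifest.json``.  A rerun with the same configuration and seed
reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .coregulation import regress_pair_logfc, select_de_pairs, stratified_regression
from .insulation import call_domains, insulation_index, partition_deciles
from .layout import make_layout
from .ledger import (
    annotate_anchors,
    association_matrix,
    expression_concordance,
    partner_counts,
)
from .loops import call_interactions_inter, call_loops_intra, conserved_loops, write_bedpe
from .matrix import coarsen, ice_normalize, write_matrix
from .simulate import (
    SimParams,
    resample_contacts,
    simulate_contacts,
    simulate_genes_and_expression,
    simulate_hichip,
)
from .territories import classify_and_aggregate, homeolog_contrast, median_by_class

log = logging.getLogger("territoria")

_STAGES = ["simulate", "balance", "territories", "insulation", "loops", "ledger", "coregulation"]
_DEPS = {
    "balance": ["simulate"],
    "territories": ["balance"],
    "insulation": ["balance"],
    "loops": ["simulate"],
    "ledger": ["loops"],
    "coregulation": ["ledger"],
}


@dataclass
class PipelineConfig:
    """Fixture-sized defaults: 3 subgenomes x 2 chromosomes x 4.2 Mb at 25 kb."""

    seed: int = 0
    # layout
    n_subgenomes: int = 3
    chroms_per_subgenome: int = 2
    chrom_length: int = 4_200_000
    bin_size: int = 25_000
    # simulation overrides (merged into SimParams)
    sim: dict = field(default_factory=dict)
    # thresholds / resolutions
    super_bin: int = 1_000_000
    insulation_window: int = 100_000
    insulation_threshold: float = 0.4
    loop_coarsen_factor: int = 1
    p_max: float = 0.05
    z_min: float = 1.5
    q_max: float = 0.1
    de_p_max: float = 0.01
    hichip_boost: float = 5.0
    # control
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    outdir: str = "territoria_run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        enabled = [s for s in _STAGES if s in self.stages]
        for s in enabled:
            for dep in _DEPS.get(s, []):
                if dep not in enabled:
                    raise ValueError(f"stage {s!r} requires stage {dep!r} to be enabled")
        if self.super_bin % self.bin_size:
            raise ValueError("super_bin must be a multiple of bin_size")
        for name in ("p_max", "q_max", "de_p_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the manifest (also written to disk)."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "log_level"
        },
        "stages": {},
        "files": {},
    }
    artifacts: list[Path] = []

    def emit(name: str) -> Path:
        p = out / name
        artifacts.append(p)
        return p

    enabled = [s for s in _STAGES if s in config.stages]
    state: dict = {}

    # -- simulate -----------------------------------------------------------
    if "simulate" in enabled:
        layout = make_layout(
            config.n_subgenomes, config.chroms_per_subgenome,
            config.chrom_length, config.bin_size,
        )
        params = SimParams(seed=config.seed, **config.sim)
        shoot, truth = simulate_contacts(layout, params)
        genes = simulate_genes_and_expression(layout, truth, params)
        root = resample_contacts(truth)
        hichip = simulate_hichip(shoot, genes, config.hichip_boost, rng=truth.rng)
        layout.to_tsv(emit("layout.tsv"))
        write_matrix(shoot, emit("matrix_shoot.tsv"))
        write_matrix(root, emit("matrix_root.tsv"))
        write_matrix(hichip, emit("matrix_hichip.tsv"))
        gio.write_genes(genes, emit("genes.bed"), emit("genes.tsv"))
        for p in truth.write(out / "truth"):
            artifacts.append(Path(p))
        state.update(layout=layout, truth=truth, genes=genes,
                     shoot=shoot, root=root, hichip=hichip)
        manifest["stages"]["simulate"] = {
            "n_bins": layout.n_bins, "n_genes": len(genes),
            "planted_loops": len(truth.planted_loops),
            "planted_domains": len(truth.planted_domains),
        }
        log.info("simulate: %d bins, %d genes", layout.n_bins, len(genes))

    # -- balance ------------------------------------------------------------
    if "balance" in enabled:
        balanced = ice_normalize(state["shoot"])
        bias = state["layout"].bins.copy()
        bias["bias"] = balanced.bias
        bias.to_csv(emit("bias.tsv"), sep="\t", index=False, float_format="%.10g")
        write_matrix(balanced, emit("matrix_shoot.ice.tsv"))
        state["balanced"] = balanced
        manifest["stages"]["balance"] = {
            "masked_bins": int((~balanced.mask()).sum()),
        }

    # -- territories --------------------------------------------------------
    if "territories" in enabled:
        table = classify_and_aggregate(state["balanced"], config.super_bin)
        med = median_by_class(table)
        contrast = homeolog_contrast(table)
        table.to_csv(emit("territory_pairs.tsv"), sep="\t", index=False, float_format="%.6g")
        report = pd.DataFrame(
            [
                {"statistic": f"median_{k}", "value": v}
                for k, v in sorted(med["class_medians"].items())
            ]
            + [
                {"statistic": f"median_pair_{k}", "value": v}
                for k, v in sorted(med["subgenome_pair_medians"].items())
            ]
            + [
                {"statistic": "hierarchy_ok", "value": float(med["hierarchy_ok"])},
                {"statistic": "homeolog_u", "value": contrast.u},
                {"statistic": "homeolog_p", "value": contrast.p},
                {"statistic": "homeolog_cliffs_delta", "value": contrast.cliffs_delta},
            ]
        )
        report.to_csv(emit("territory_report.tsv"), sep="\t", index=False, float_format="%.6g")
        manifest["stages"]["territories"] = {
            "hierarchy_ok": bool(med["hierarchy_ok"]),
            "homeolog_cliffs_delta": contrast.cliffs_delta,
        }

    # -- insulation ---------------------------------------------------------
    if "insulation" in enabled:
        track = insulation_index(state["balanced"], config.insulation_window)
        domains = call_domains(track, config.insulation_threshold)
        deciles = partition_deciles(track)
        track.to_bedgraph(emit("insulation.bedgraph"))
        domains.to_bed(emit("domains.bed"))
        dec = track.bins[["chrom", "start", "end"]].copy()
        dec["decile"] = deciles
        dec.dropna(subset=["decile"]).astype({"decile": int}).to_csv(
            emit("deciles.bed"), sep="\t", index=False, header=False
        )
        state["track"], state["domains"] = track, domains
        manifest["stages"]["insulation"] = {
            "domains": domains.count,
            "coverage_fraction": domains.coverage_fraction,
            "mean_size_bp": domains.mean_size,
        }

    # -- loops --------------------------------------------------------------
    if "loops" in enabled:
        kw = dict(p_max=config.p_max, z_min=config.z_min, q_max=config.q_max)
        mats = {"shoot": state["shoot"], "root": state["root"]}
        sets = {}
        for cond, mat in mats.items():
            m = coarsen(mat, config.loop_coarsen_factor)
            sets[cond] = call_loops_intra(m, condition=cond, **kw)
            write_bedpe(sets[cond], emit(f"loops_{cond}.bedpe"))
        conserved = conserved_loops(sets["shoot"], sets["root"])
        write_bedpe(conserved, emit("loops_conserved.bedpe"))
        inter = call_interactions_inter(
            coarsen(state["hichip"], config.loop_coarsen_factor), condition="hichip", **kw
        )
        write_bedpe(inter, emit("interactions_inter.bedpe"))
        state.update(loop_sets=sets, conserved=conserved, inter=inter)
        manifest["stages"]["loops"] = {
            "shoot": len(sets["shoot"]), "root": len(sets["root"]),
            "conserved": len(conserved), "inter": len(inter),
        }
        log.info("loops: shoot=%d root=%d conserved=%d inter=%d",
                 len(sets["shoot"]), len(sets["root"]), len(conserved), len(inter))

    # -- ledger -------------------------------------------------------------
    if "ledger" in enabled:
        genes = state["genes"]
        pairs = annotate_anchors(state["conserved"], genes)
        pairs.to_csv(emit("gene_pairs.tsv"), sep="\t", index=False, float_format="%.6g")
        stats: dict = {"pairs": len(pairs)}
        if len(pairs):
            ledger = association_matrix(
                pairs, ["expressed", "H3K9ac", "H3K36me3", "H3K27me3", "RNAPII"]
            )
            ledger.to_csv(emit("association_ledger.tsv"), sep="\t", index=False,
                          float_format="%.6g")
            try:
                conc = expression_concordance(pairs, n_quantiles=4)
                conc.to_csv(emit("expression_concordance.tsv"), sep="\t",
                            float_format="%.6g")
                stats["diagonal_fraction"] = conc.attrs["diagonal_fraction"]
            except ValueError:
                log.warning("ledger: too few expressed pairs for concordance")
            counts, frac = partner_counts(pairs)
            counts.to_csv(emit("partner_counts.tsv"), sep="\t")
            stats.update(frac)
        state["pairs"] = pairs
        manifest["stages"]["ledger"] = stats

    # -- coregulation -------------------------------------------------------
    if "coregulation" in enabled:
        pairs = state["pairs"]
        stats = {}
        if len(pairs):
            de_pairs = select_de_pairs(pairs, p_max=config.de_p_max)
            de_pairs.to_csv(emit("de_pairs.tsv"), sep="\t", index=False, float_format="%.6g")
            if len(de_pairs) >= 3:
                fit = regress_pair_logfc(de_pairs)
                strat = stratified_regression(de_pairs, "strength", z_cols=("z", "z_other"))
                pooled = pd.DataFrame(
                    [{"stratum": "pooled", "n": fit.n_pairs, "slope": fit.slope,
                      "intercept": fit.intercept, "r_squared": fit.r_squared,
                      "f_pvalue": fit.f_pvalue}]
                )
                pd.concat([pooled, strat], ignore_index=True).to_csv(
                    emit("coregulation.tsv"), sep="\t", index=False, float_format="%.6g"
                )
                stats = {"n_de_pairs": len(de_pairs), "slope": fit.slope,
                         "r_squared": fit.r_squared}
        manifest["stages"]["coregulation"] = stats

    for p in artifacts:
        manifest["files"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return manifest
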