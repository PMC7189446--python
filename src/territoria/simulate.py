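"""Synthetic allopolyploid Hi-C / Hi-ChIP generator with planted structure.

The generator emulates, at desk scale, the statistical structure of a
hexaploid (wheat-like) genome:

* power-law distance decay of intra-chromosomal contacts,
  mu(d) = base_rate * f_intra * (1 + d)^(-alpha);
* a hierarchy of interchromosomal contact rates — chromosomes of the same
  subgenome interact more than chromosomes of different subgenomes
  (f_intra >= f_subgenome >= f_inter), with a multiplicative bonus on
  homeolog pairs (1A-1B etc.);
* a Rabl configuration: an anti-diagonal band of enriched contacts between
  mirrored positions of chromosome pairs (telomere-to-telomere /
  centromere-to-centromere alignment);
* condensed, gene-poor folding domains (ICONS analogs): contacts whose two
  ends fall inside the same planted domain keep the full decay rate while
  every other intra-chromosomal pair is thinned by ``domain_depletion`` < 1,
  so domain interiors are contact-rich relative to their surroundings and
  domain flanks are insulation minima;
* gene-to-gene loops between domain-boundary bins, multiplied by
  ``loop_fold`` over the background expectation;
* genes hosted at domain boundaries, carrying histone marks / RNAPII / ATAC
  flags with active-repressive anti-correlation, lognormal TPM, and a
  two-condition expression model in which loop partners' log2 fold changes
  are coupled with a configurable slope.

Counts are Poisson around the expected rates; a single integer seed drives
one generator that is threaded through the contact, gene and Hi-ChIP stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import GenomeLayout
from .matrix import ContactMatrix

__all__ = [
    "SimParams",
    "SimTruth",
    "simulate_contacts",
    "resample_contacts",
    "simulate_genes_and_expression",
    "simulate_hichip",
    "simulate_coupled_pairs",
    "noise_sd_for_r2",
]

MARKS = ["H3K9ac", "H3K36me3", "H3K27me3", "RNAPII", "ATAC"]

#: per-mark probability given the gene's chromatin state (active / repressed)
_MARK_PROBS = {
    "H3K9ac": (0.90, 0.05),
    "H3K36me3": (0.90, 0.05),
    "H3K27me3": (0.05, 0.90),
    "RNAPII": (0.90, 0.05),
    "ATAC": (0.80, 0.10),
}


def noise_sd_for_r2(slope: float, x_sd: float, r2: float) -> float:
    """Residual sd that yields expected R^2 = ``r2`` for y = slope*x + eps."""
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    return abs(slope) * x_sd * math.sqrt(1.0 / r2 - 1.0)


@dataclass
class SimParams:
    """Generator parameters.  Defaults are the package's study conditions.

    Contact model: ``decay_exponent`` (alpha > 0) and ``base_rate`` set the
    intra-chromosomal expectation base_rate*f_intra*(1+d)^(-alpha);
    ``f_intra >= f_subgenome >= f_inter`` set the territory hierarchy;
    ``homeolog_factor`` and ``rabl_strength`` are multiplicative (>= 1).
    Domains/loops: ``n_domains`` per chromosome of ``domain_bins`` bins
    separated by ``gap_bins``; ``loop_rate`` intra + ``inter_loop_rate`` inter
    loops at fold ``loop_fold`` between boundary bins.  Genes/expression:
    boundary bins host one gene each, other bins with prob
    ``interior_gene_prob``; TPM ~ lognormal(``tpm_mu``, ``tpm_sigma``);
    loop partners couple log2FC with slope ``pair_logfc_slope`` and residual
    ``pair_logfc_noise_sd`` (default gives R^2 ~ 0.23 at the default slope).
    """

    seed: int = 0
    # contact decay + territories
    decay_exponent: float = 1.0
    base_rate: float = 100.0
    f_intra: float = 8.0
    f_subgenome: float = 0.02
    f_inter: float = 0.005
    homeolog_factor: float = 2.0
    rabl_strength: float = 3.0
    # planted domains
    n_domains: int = 10
    domain_bins: int = 10
    gap_bins: int = 6
    domain_depletion: float = 0.3
    # planted loops
    loop_rate: int = 60
    inter_loop_rate: int = 30
    loop_fold: float = 5.0
    min_loop_distance_bins: int = 2
    strata_slopes: tuple[float, ...] | None = None  # per loop-strength stratum
    strength_fold_base: float = 1.0  # fold multiplier ratio between strata
    # genes, marks, expression
    interior_gene_prob: float = 0.10
    p_active: float = 0.6
    mark_concordance: float = 0.9
    tpm_mu: float = 3.0
    tpm_sigma: float = 1.2
    tpm_partner_rho: float = 0.8
    logfc_sd: float = 2.0
    pair_logfc_slope: float = 0.483
    pair_logfc_noise_sd: float = field(default=None)  # type: ignore[assignment]
    coupled_de_pvalue: float = 1e-4

    def __post_init__(self) -> None:
        if self.pair_logfc_noise_sd is None:
            self.pair_logfc_noise_sd = noise_sd_for_r2(
                self.pair_logfc_slope, self.logfc_sd, 0.23
            )
        if not self.f_intra >= self.f_subgenome >= self.f_inter > 0:
            raise ValueError("require f_intra >= f_subgenome >= f_inter > 0")
        if self.decay_exponent <= 0 or self.base_rate <= 0:
            raise ValueError("decay_exponent and base_rate must be positive")
        for name in ("homeolog_factor", "rabl_strength", "loop_fold"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.domain_depletion <= 1:
            raise ValueError("domain_depletion must be in (0, 1]")
        for name in ("interior_gene_prob", "p_active", "mark_concordance"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")


@dataclass
class SimTruth:
    """Everything planted by the generator, for recovery tests.

    ``planted_domains``: per-chromosome intervals (bp + global bin indices);
    ``boundary_bins``: global indices of the gene-rich bins flanking each
    domain; ``planted_loops``: bin pairs with their fold and strength stratum;
    ``gene_pair_couplings``: filled by the gene stage; ``rng``: the single
    generator, carried across stages.
    """

    layout: GenomeLayout
    params: SimParams
    planted_domains: pd.DataFrame
    boundary_bins: np.ndarray
    planted_loops: pd.DataFrame
    homeolog_pairs: list[tuple[str, str]]
    gene_pair_couplings: pd.DataFrame | None = None
    rng: np.random.Generator | None = field(default=None, repr=False)

    def write(self, prefix) -> list[str]:
        """Write planted structure as documented TSV files; returns paths."""
        paths = []
        for name, df in [
            ("planted_domains", self.planted_domains),
            ("planted_loops", self.planted_loops),
            ("gene_pair_couplings", self.gene_pair_couplings),
        ]:
            if df is None:
                continue
            path = f"{prefix}.{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            paths.append(path)
        return paths


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def _plant_domains(layout: GenomeLayout, params: SimParams) -> tuple[pd.DataFrame, np.ndarray]:
    """Evenly place ``n_domains`` per chromosome; returns (domains, boundary bins)."""
    rows, boundary = [], []
    slices = layout.chrom_slices()
    for c in layout.chromosomes:
        n_c = layout.n_bins_of(c)
        if params.n_domains == 0:
            continue
        span = params.domain_bins + params.gap_bins
        needed = params.gap_bins + params.n_domains * span
        if needed > n_c:
            raise ValueError(
                f"chromosome {c.name}: {params.n_domains} domains of "
                f"{params.domain_bins} bins + {params.gap_bins}-bin gaps need "
                f"{needed} bins, have {n_c}"
            )
        lo = slices[c.name].start
        for k in range(params.n_domains):
            b0 = params.gap_bins + k * span
            b1 = b0 + params.domain_bins
            rows.append(
                {
                    "chrom": c.name,
                    "start": b0 * layout.bin_size,
                    "end": min(b1 * layout.bin_size, c.length),
                    "start_bin": lo + b0,
                    "end_bin": lo + b1,
                }
            )
            boundary += [lo + b0 - 1, lo + b1]
    domains = pd.DataFrame(rows, columns=["chrom", "start", "end", "start_bin", "end_bin"])
    return domains, np.unique(np.asarray(boundary, dtype=int))


def _plant_loops(
    layout: GenomeLayout,
    params: SimParams,
    boundary_bins: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample loop anchor pairs among boundary bins (intra + inter)."""
    bins = layout.bins
    chrom_of = bins["chrom"].to_numpy()
    rows = []
    intra_cand = []
    inter_cand = []
    for a in range(len(boundary_bins)):
        for b in range(a + 1, len(boundary_bins)):
            i, j = int(boundary_bins[a]), int(boundary_bins[b])
            if chrom_of[i] == chrom_of[j]:
                if j - i >= params.min_loop_distance_bins:
                    intra_cand.append((i, j))
            else:
                inter_cand.append((i, j))
    for kind, cand, n_req in [
        ("intra", intra_cand, params.loop_rate),
        ("inter", inter_cand, params.inter_loop_rate),
    ]:
        if n_req == 0:
            continue
        if n_req > len(cand):
            raise ValueError(f"cannot plant {n_req} {kind} loops: only {len(cand)} candidates")
        pick = rng.choice(len(cand), size=n_req, replace=False)
        n_strata = len(params.strata_slopes) if params.strata_slopes else 1
        for m, pidx in enumerate(sorted(pick)):
            i, j = cand[pidx]
            stratum = int(rng.integers(n_strata))
            fold = params.loop_fold * params.strength_fold_base**stratum
            rows.append(
                {
                    "chrom1": chrom_of[i],
                    "bin1": i,
                    "chrom2": chrom_of[j],
                    "bin2": j,
                    "fold": fold,
                    "stratum": stratum,
                    "kind": kind,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom1", "bin1", "chrom2", "bin2", "fold", "stratum", "kind"]
    )


def _expected_matrix(
    layout: GenomeLayout,
    params: SimParams,
    domains: pd.DataFrame,
    loops: pd.DataFrame,
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Deterministic expected-count matrix for a planted structure."""
    n = layout.n_bins
    expected = np.zeros((n, n))
    slices = layout.chrom_slices()

    # intra-chromosomal: decay x domain contrast
    domain_id = np.full(n, -1)
    for k, d in enumerate(domains.itertuples()):
        domain_id[d.start_bin : d.end_bin] = k
    for c in layout.chromosomes:
        sl = slices[c.name]
        n_c = sl.stop - sl.start
        d = np.abs(np.subtract.outer(np.arange(n_c), np.arange(n_c)))
        mu = params.base_rate * params.f_intra * (1.0 + d) ** (-params.decay_exponent)
        if params.domain_depletion < 1 and len(domains):
            dom = domain_id[sl]
            same_domain = (dom[:, None] == dom[None, :]) & (dom[:, None] >= 0)
            mu = np.where(same_domain, mu, mu * params.domain_depletion)
        expected[sl, sl] = mu

    # interchromosomal: territory hierarchy, homeolog bonus, Rabl anti-diagonal
    homeolog_pairs = []
    chrom_list = layout.chromosomes
    for a in range(len(chrom_list)):
        for b in range(a + 1, len(chrom_list)):
            ca, cb = chrom_list[a], chrom_list[b]
            sa, sb = slices[ca.name], slices[cb.name]
            f = params.f_subgenome if ca.subgenome == cb.subgenome else params.f_inter
            hom = 1.0
            if layout.is_homeolog_pair(ca.name, cb.name):
                hom = params.homeolog_factor
                homeolog_pairs.append((ca.name, cb.name))
            block = np.full((sa.stop - sa.start, sb.stop - sb.start), params.base_rate * f * hom)
            if params.rabl_strength > 1:
                n1, n2 = block.shape
                i = np.arange(n1)
                mirror = np.rint((n1 - 1 - i) * (n2 - 1) / max(n1 - 1, 1)).astype(int)
                block[i, mirror] *= params.rabl_strength
            expected[sa, sb] = block
            expected[sb, sa] = block.T

    for lp in loops.itertuples():
        expected[lp.bin1, lp.bin2] *= lp.fold
        expected[lp.bin2, lp.bin1] = expected[lp.bin1, lp.bin2]
    return expected, homeolog_pairs


def _draw_counts(expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = expected.shape[0]
    iu, ju = np.triu_indices(n)
    counts = np.zeros((n, n))
    counts[iu, ju] = rng.poisson(expected[iu, ju])
    return counts + np.triu(counts, 1).T


def simulate_contacts(
    layout: GenomeLayout, params: SimParams
) -> tuple[ContactMatrix, SimTruth]:
    """Draw a symmetric Poisson contact matrix with planted structure."""
    rng = np.random.default_rng(params.seed)
    domains, boundary_bins = _plant_domains(layout, params)
    loops = _plant_loops(layout, params, boundary_bins, rng)
    expected, homeolog_pairs = _expected_matrix(layout, params, domains, loops)
    counts = _draw_counts(expected, rng)
    truth = SimTruth(
        layout=layout,
        params=params,
        planted_domains=domains,
        boundary_bins=boundary_bins,
        planted_loops=loops,
        homeolog_pairs=homeolog_pairs,
        rng=rng,
    )
    return ContactMatrix(layout, counts), truth


def resample_contacts(
    truth: SimTruth, rng: np.random.Generator | int | None = None
) -> ContactMatrix:
    """Draw an independent replicate matrix from the same planted structure.

    Used to emulate a second condition/organ sharing the planted loops and
    domains; by default the truth's own generator stream continues.
    """
    if rng is None:
        rng = truth.rng if truth.rng is not None else np.random.default_rng(truth.params.seed)
    elif isinstance(rng, int):
        rng = np.random.default_rng(rng)
    expected, _ = _expected_matrix(
        truth.layout, truth.params, truth.planted_domains, truth.planted_loops
    )
    return ContactMatrix(truth.layout, _draw_counts(expected, rng))


# ---------------------------------------------------------------------------
# genes, marks, expression
# ---------------------------------------------------------------------------


def _draw_marks(active: bool, rng: np.random.Generator) -> dict[str, bool]:
    return {
        m: bool(rng.random() < (pa if active else pr))
        for m, (pa, pr) in _MARK_PROBS.items()
    }


def simulate_genes_and_expression(
    layout: GenomeLayout, truth: SimTruth, params: SimParams | None = None
) -> pd.DataFrame:
    """Place genes, assign marks/TPM/log2FC, couple loop partners.

    Boundary bins each host one gene; every other bin hosts a gene with
    probability ``interior_gene_prob`` (gene depletion inside domains is a
    consequence of boundary enrichment plus the low interior rate).  For each
    planted intra/inter loop joining two gene bins the partner gene's marks
    are copied with probability ``mark_concordance``, expressed partners get
    rank-correlated TPM, and log2FC2 = beta * log2FC1 + eps with beta from the
    loop's stratum.  Coupled genes get DE p-values of ``coupled_de_pvalue``;
    all others p = 1.
    """
    params = params or truth.params
    rng = truth.rng if truth.rng is not None else np.random.default_rng(params.seed)
    bins = layout.bins
    bs = layout.bin_size

    boundary = set(int(b) for b in truth.boundary_bins)
    gene_bins = sorted(
        boundary | {int(b) for b in np.flatnonzero(rng.random(layout.n_bins) < params.interior_gene_prob)}
    )

    rows = []
    for k, b in enumerate(gene_bins):
        chrom, start, end = bins.loc[b, ["chrom", "start", "end"]]
        width = end - start
        g_start = start + int(0.3 * width)
        g_end = g_start + max(int(0.4 * width), 1)
        active = bool(rng.random() < params.p_active)
        marks = _draw_marks(active, rng)
        rows.append(
            {
                "gene_id": f"G{k:05d}",
                "chrom": chrom,
                "start": g_start,
                "end": min(g_end, end),
                "strand": "+" if rng.random() < 0.5 else "-",
                "bin": b,
                "active": active,
                **marks,
            }
        )
    genes = pd.DataFrame(rows)
    if genes.empty:
        raise ValueError("no genes generated: zero boundary bins and zero interior rate")
    by_bin = {int(r.bin): i for i, r in enumerate(genes.itertuples())}

    # expression baseline (log-TPM); expressed <=> active chromatin state
    log_tpm = rng.normal(params.tpm_mu, params.tpm_sigma, size=len(genes))

    # concordant loop edges merge partners into components sharing state/marks
    parent = list(range(len(genes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    loop_gene_idx = []
    for lp in truth.planted_loops.itertuples():
        i1, i2 = by_bin.get(int(lp.bin1)), by_bin.get(int(lp.bin2))
        loop_gene_idx.append((i1, i2))
        if i1 is None or i2 is None:
            continue
        if rng.random() < params.mark_concordance:
            parent[find(i2)] = find(i1)
    for i in range(len(genes)):
        rep = find(i)
        if rep == i:
            continue
        genes.loc[i, "active"] = genes.loc[rep, "active"]
        for m in MARKS:
            genes.loc[i, m] = genes.loc[rep, m]
        if genes.loc[rep, "active"]:
            rho = params.tpm_partner_rho
            log_tpm[i] = (
                params.tpm_mu
                + rho * (log_tpm[rep] - params.tpm_mu)
                + params.tpm_sigma * math.sqrt(max(1 - rho**2, 0.0)) * rng.normal()
            )

    # couple loop partners' fold changes
    logfc = rng.normal(0.0, 0.05, size=len(genes))
    de_p = np.ones(len(genes))
    coupled: set[int] = set()
    couplings = []
    for lp, (i1, i2) in zip(truth.planted_loops.itertuples(), loop_gene_idx):
        if i1 is None or i2 is None:
            continue
        beta = (
            params.strata_slopes[int(lp.stratum)]
            if params.strata_slopes
            else params.pair_logfc_slope
        )
        de_p[i1] = de_p[i2] = params.coupled_de_pvalue
        if i1 in coupled or i2 in coupled:
            continue  # a gene couples to one partner only; extra loops are DE but uncoupled
        logfc[i1] = rng.normal(0.0, params.logfc_sd)
        logfc[i2] = beta * logfc[i1] + rng.normal(0.0, params.pair_logfc_noise_sd)
        coupled.update((i1, i2))
        couplings.append(
            {
                "gene1": genes.loc[i1, "gene_id"],
                "gene2": genes.loc[i2, "gene_id"],
                "beta": beta,
                "stratum": int(lp.stratum),
            }
        )

    active_arr = genes["active"].to_numpy(dtype=bool)
    tpm = np.where(active_arr, np.exp(log_tpm), 0.0)
    shoot = tpm
    # root condition: shoot shifted by -log2fc (log2fc is shoot/root)
    root = np.where(active_arr, tpm / np.exp2(logfc), 0.0)
    for cond, base in [("shoot", shoot), ("root", root)]:
        for rep in (1, 2, 3):
            jitter = np.exp(rng.normal(0.0, 0.1, size=len(genes)))
            genes[f"tpm_{cond}_{rep}"] = base * jitter
    for cond in ("shoot", "root"):
        genes[f"tpm_{cond}"] = genes[[f"tpm_{cond}_{r}" for r in (1, 2, 3)]].median(axis=1)
    genes["expressed"] = genes["tpm_shoot"] > 0
    genes["log2fc"] = logfc
    genes["de_pvalue"] = de_p
    genes["marks"] = [
        ";".join(m for m in MARKS if r[m]) for _, r in genes.iterrows()
    ]
    truth.gene_pair_couplings = pd.DataFrame(
        couplings, columns=["gene1", "gene2", "beta", "stratum"]
    )
    return genes


# ---------------------------------------------------------------------------
# Hi-ChIP
# ---------------------------------------------------------------------------


def simulate_hichip(
    matrix: ContactMatrix,
    genes: pd.DataFrame,
    occupancy_boost: float,
    thinning: float = 0.25,
    rng: np.random.Generator | int | None = None,
) -> ContactMatrix:
    """Protein-centric (RNAPII) resampling of a contact matrix.

    Pairs whose both bins contain an RNAPII-marked gene are multiplied by
    ``occupancy_boost``; all other pairs by ``thinning``; counts are then
    re-drawn from a Poisson with those means.  Symmetry is preserved.
    """
    if occupancy_boost < 1:
        raise ValueError("occupancy_boost must be >= 1")
    if not 0 < thinning <= 1:
        raise ValueError("thinning must be in (0, 1]")
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    n = matrix.n_bins
    rnapii = np.zeros(n, dtype=bool)
    marked = genes[genes["RNAPII"].astype(bool)]
    if "bin" in marked.columns:
        rnapii[marked["bin"].to_numpy(dtype=int)] = True
    factor = np.where(np.outer(rnapii, rnapii), occupancy_boost, thinning)
    iu, ju = np.triu_indices(n)
    mean = np.nan_to_num(matrix.data)[iu, ju] * factor[iu, ju]
    counts = np.zeros((n, n))
    counts[iu, ju] = rng.poisson(mean)
    counts = counts + np.triu(counts, 1).T
    return ContactMatrix(matrix.layout, counts)


# ---------------------------------------------------------------------------
# stand-alone coupled-pair generator (coregulation experiments)
# ---------------------------------------------------------------------------


def simulate_coupled_pairs(
    n_pairs: int,
    slope: float = 0.483,
    noise_sd: float | None = None,
    logfc_sd: float = 2.0,
    r2: float | None = None,
    slope_grid: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw differentially expressed gene pairs with coupled log2 fold changes.

    With ``slope_grid`` (q x q), each pair is assigned a loop-strength
    quantile in each of two conditions (columns ``z_shoot``/``z_root`` carry
    strengths whose empirical quantiles recover the assignment) and the cell's
    slope couples the pair.  Otherwise a single ``slope`` applies; ``noise_sd``
    defaults to the value giving expected R^2 = ``r2`` (or 0.23).
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if noise_sd is None:
        noise_sd = noise_sd_for_r2(slope, logfc_sd, 0.23 if r2 is None else r2)
    x = rng.normal(0.0, logfc_sd, size=n_pairs)
    if slope_grid is not None:
        grid = np.asarray(slope_grid, dtype=float)
        q = grid.shape[0]
        qa = rng.integers(q, size=n_pairs)
        qb = rng.integers(q, size=n_pairs)
        betas = grid[qa, qb]
        z_shoot = 2.0 + qa + rng.random(n_pairs)  # quantile bands, non-overlapping
        z_root = 2.0 + qb + rng.random(n_pairs)
    else:
        betas = np.full(n_pairs, slope)
        z_shoot = 2.0 + 4.0 * rng.random(n_pairs)
        z_root = 2.0 + 4.0 * rng.random(n_pairs)
    y = betas * x + rng.normal(0.0, noise_sd, size=n_pairs)
    return pd.DataFrame(
        {
            "gene1": [f"P{k}_a" for k in range(n_pairs)],
            "gene2": [f"P{k}_b" for k in range(n_pairs)],
            "log2fc1": x,
            "log2fc2": y,
            "de_pvalue1": 1e-4,
            "de_pvalue2": 1e-4,
            "z_shoot": z_shoot,
            "z_root": z_root,
            "distance": rng.integers(40_000, 400_000, size=n_pairs),
        }
    )
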