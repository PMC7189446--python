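# Methods

This note documents the models, parameter choices and numerical conventions
behind `territoria`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Coordinates and containers

All coordinates are 0-based half-open. Contact maps are dense symmetric
float64 arrays over a fixed bin grid (`GenomeLayout`); the last bin of a
chromosome may be short. Balanced matrices carry a per-bin bias vector and
use NaN for masked bins, so all downstream statistics handle missing data
with nan-aware reductions. Dense storage is a deliberate choice: the package
targets desk-scale maps (≤ a few thousand bins), where dense algebra is
simpler and faster than sparse bookkeeping; the sparse-triplet TSV interchange
format is independent of the in-memory representation.

## ICE balancing

Iterative correction divides the matrix by the outer product of its usable
marginals, rescaled to mean 1 each iteration, until the coefficient of
variation of the usable marginals falls below `tol` (default 1e-5, max 200
iterations). Bins with zero coverage plus the lowest `mask_fraction`
(default 0.02) of positive-coverage bins are masked before iterating —
published wheat workflows cite iterative correction without printing
filtering percentages, so these defaults are documented package choices, not
inferred values. After convergence the balanced matrix is recomputed in one step as
`raw[i,j] / (bias_i * bias_j)`, which makes that identity hold bit-exactly
rather than only to iteration tolerance. Unit-mean marginal rescaling keeps
the matrix total approximately preserved; the balancing target is uniform
visibility, not a particular scale.

## Distance decay

The decay profile pools all intra-chromosomal pairs at separations d = 1..D
(mean, sd, count per d; masked pairs excluded; empty separations omitted).
It is computed on whatever values the matrix carries: balanced values for the
analysis path, raw counts when it feeds the loop caller's expected model.

## Territory statistics

Counts are aggregated into super-bins (10 Mb on wheat; scaled down in the
fixtures) that never span chromosomes. Each unordered super-bin pair gets
`cpm` (block mass per million of the matrix total, conserving mass) and
`freq` = cpm / (distinct bin pairs in the block). Medians and the homeolog
contrast use `freq`: a diagonal block holds n(n+1)/2 distinct pairs versus
n·m for an off-diagonal block, so raw mass is not comparable across classes —
on a constant matrix, `freq` is flat while mass is not. "Interaction
frequency" is thus defined as balanced counts per million per bin pair, a
documented and monotone-equivalent stand-in for tool-specific normalized
values. The Mann-Whitney U uses exact enumeration of all label assignments
for n₁+n₂ ≤ 12 (tie-safe) and the tie-corrected normal approximation above
that; Cliff's Delta is computed exactly with ties contributing zero.

## Insulation and domain calling

The insulation score of bin i with window w (bins) is the mean balanced value
over the square {u ∈ [i−w, i−1]} × {v ∈ [i+1, i+w]} (intra-chromosomal only),
normalized as log₂(window mean / chromosome mean of defined window means).
A score is defined only where the full square fits inside the chromosome and
at least half its entries are unmasked (missing-data rule; published workflows do not
state one). A zero window mean maps to −inf (fully insulated), kept
rather than clipped so that rank-based deciles remain well defined. By
construction the chromosome average maps to score 0; negative scores mark
insulated bins, and condensed (contact-rich, gene-poor) regions score high.
Domains are maximal runs of ≥ `min_bins` (2) consecutive bins with score ≥
the calling threshold (0.4 at 25-kb bins / 100-kb window — the published
parameters); boundaries are the flanking low-score bins. A square window
cannot localize a boundary more sharply than a plateau of width 2w−1, so the
boundary-recovery benchmark scores the matrix at w = 1 (25-kb window), where
recovery of planted edges to ±1 bin is achievable; the 100-kb default remains
the analysis condition.

Deciles: defined bins are stably sorted by score (ties broken by genomic
order) and split into 10 equal groups, the remainder going to the lowest
(most insulated) groups. Genes take the label of the bin covering ≥ 50 % of
them, a 50/50 split going to the left bin. Meta-profiles rescale each region
body to a fixed number of meta-bins by midpoint sampling, bin flanks at fixed
width, reverse minus-strand regions, and aggregate per meta-bin with the
median (the published plotting convention).

## Loop calling

Intra-chromosomal expected counts: exp(i,j) = decay_mean(d_ij) · cov_i ·
cov_j / mean_cov², computed from the same matrix (HOMER-style background);
interchromosomal: exp(i,j) = 2T·(cov_i/T)(cov_j/T) with T the unordered-pair
total (the factor 2 reflects unordered-pair counting and is fixed so results
are bit-reproducible). Each tested pair gets Z = (obs − exp)/√exp, an
upper-tail Poisson p-value P(X ≥ obs), and a Benjamini–Hochberg q computed
per resolution and per kind (intra vs inter pools are separate, matching the
separate published calls); loops must pass p < 0.05, Z > 1.5, q < 0.1
simultaneously — thresholds and the 20/25/50-kb resolutions are the published
calling parameters. Pairs closer than 2 bins are excluded (diagonal and
adjacent bins; avoids trivial self-interaction calls). Conserved loops match
anchors by ≥ 1-bp overlap on the coarser of the two grids and carry both
conditions' Z values.

Known miscalibration: the coverage term corrects visibility differences that
real maps have, but on a synthetic null with *uniform* per-distance rates it
injects variance (chromosome-end bins have lower coverage), so the caller
makes a small excess of calls near chromosome ends on structured fixtures.
The null error-control benchmarks use homogeneous simulations where the
false-call count stays well inside the BH budget; on the structured fixture
most "extra" calls sit inside planted condensed domains, which genuinely are
contact-enriched.

## Pair ledger

Anchors annotate to genes by any overlap; every gene-in-anchor1 ×
gene-in-anchor2 combination becomes a record (gene-less anchors drop the
loop; a single gene spanning both anchors never pairs with itself).
Intra-chromosomal pairs are ordered genomically, interchromosomal pairs by
chromosome name. The 2×2 association applies the Haldane–Anscombe +0.5 to all
cells iff any cell is zero (odds ratio only; χ² without continuity correction
uses the raw counts), with Cramér's V = √(χ²/n). Because the published
heatmap convention for "first" vs "second" gene is undefined, the ledger is
symmetrized by pooling both orientations of every pair (the unsymmetrized
table is available via `symmetrize=False`). Expression-concordance quantile
breaks are computed independently per side, left-closed with ties assigned to
the lower quantile, so counts are bit-reproducible. A reader
(`read_pair_table`) maps deposited pair tables onto this schema via a
configurable column map.

## Coregulation

Differentially expressed pairs (both genes p < 0.01, loop conserved across
conditions, finite log₂FC on both sides) are fit by OLS with the first gene's
log₂(fold change) as predictor. "First" means genomically upstream (intra)
or lower chromosome name (inter) — fixed for reproducibility; swapping
predictor and response changes the slope but not the F-test p-value (simple
regression identity, asserted in tests). Genes appearing in several loops
contribute each pair as an independent observation, matching pairwise-table
analyses. Strength stratification computes quartiles of Z within each
condition independently and fits each of the 16 cells (cells with n < 3
reported absent); distance stratification uses distance quartiles.

## Synthetic generator: what it emulates

Expected counts: intra μ(d) = base_rate · f_intra · (1+d)^(−α); inter =
base_rate · f_class · homeolog_factor (on homeolog pairs) with f_intra ≥
f_subgenome ≥ f_inter; a Rabl anti-diagonal multiplies mirrored-position bin
pairs by `rabl_strength`; planted loops multiply their pair by `loop_fold`.
`f_intra` deliberately also scales the intra-chromosomal amplitude so the
class hierarchy is a single knob family. Condensed domains: pairs whose both
ends lie inside one planted domain keep the full decay rate, every other
intra-chromosomal pair is thinned by `domain_depletion` < 1 — domains are
thus contact-*rich* (condensed) relative to their surroundings, the flanking
gene-rich bins are insulation minima, and with the depletion at 1 the null
model is exactly μ(d). Counts are independent Poisson per unordered pair
(overdispersion is an explicit non-goal: the downstream significance model is
Poisson, and the benchmarks test that model's own guarantees).

Genes: one per domain-boundary bin, plus other bins at a low rate (0.10) —
gene depletion inside domains follows. Marks (H3K9ac, H3K36me3, H3K27me3,
RNAPII, ATAC) are drawn with active/repressive anti-correlation from a
per-gene chromatin state; concordant loop edges (probability
`mark_concordance`, default 0.9) merge partners into components sharing state
and marks (union-find, so concordance at probability 1 is transitively
exact). Expressed genes get lognormal TPM (μ = 3, σ = 1.2 in log space —
a realistic heavy-tailed expression distribution), with loop partners'
log-TPMs correlated at ρ = 0.8. Each planted loop couples its partners'
fold changes once (a gene couples to one partner; additional loops make genes
DE without re-coupling): log₂FC₂ = β·log₂FC₁ + ε. Coupled genes get DE
p = 1e-4 (below the 0.01 filter, so the filtering logic is exercised); all
others p = 1. The default β = 0.483 with noise giving R² ≈ 0.23 at the
1659-pair scale mirrors the published wheat regression; the strength-stratified
generator plants per-quartile slopes up to 0.90 in the strongest cell, and
the stand-alone coupled-pair generator reproduces the RNAPII-loop (0.77 /
R² 0.61) and interchromosomal (0.60) conditions. One integer seed drives a
single generator threaded through contacts → genes → Hi-ChIP.

Hi-ChIP resampling multiplies pairs whose both bins host an RNAPII-marked
gene by `occupancy_boost`, thins all others (default 0.25), and re-draws
Poisson counts.

Magnitudes the source analyses do not report (territory factors, Rabl
strength, domain depletion, loop fold, TPM parameters) are fixed package
defaults chosen once to be field-realistic: interchromosomal rates are a few
per-mille of the short-range intra rate, the homeolog bonus is 2×, domains
are 250 kb with 150-kb gaps at 25-kb bins, planted loops are 5-fold. They are
study conditions, not tuning knobs.

## Problem sizes

Benchmarks run at desk scale: 6 chromosomes × 4.2 Mb at 25-kb bins
(1008 bins) for the fixture pipeline and recovery experiments, 2 × 60 bins at
100 kb for the loop error-control replicates (20 seeds), and the published
pair counts (1659 / 2000 / 8000) for the regression recoveries. These sizes
make every experiment rerunnable in seconds while keeping ≥ 10³ pairs per
estimated quantity.

## What passing tests do and do not show

The generator draws from the same model family the callers assume (Poisson
counts, power-law decay, step-function domains). Passing recovery tests
therefore demonstrates correctness of the implementations and calibration of
their error control under matched assumptions — not robustness to
overdispersion, copy-number artifacts, restriction-fragment geometry,
mappability structure, or the A/B-compartment signal absent from this model.
The wheat-scale census numbers (loop counts, domain counts, genome-wide
effect sizes) depend on the deposited experimental data and are out of reach
of the synthetic fixtures; the package reproduces the *statistics*, and the
fixture-level analogs (e.g. a positive but attenuated end-to-end coregulation
slope, diluted by incidental gene pairs among called loops) behave the way
the published analysis behaves qualitatively.

## Known limitations

- Poisson-only counts; no negative-binomial overdispersion knob.
- The loop background model inherits the coverage-term miscalibration noted
  above; on real (visibility-structured) data this term is the standard
  correction, but p-values remain model-based, hence the joint p/Z/q filter.
- Insulation near chromosome ends is undefined (full-window rule) — w bins
  are lost at each end.
- The deposited-table worked example requires the external pair table; only
  its ingestion path is covered by unit tests here.
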