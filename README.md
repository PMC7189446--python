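# territoria

Chromatin-architecture analysis for polyploid genomes: genome-territory
statistics, insulation-index folding-domain (ICONS) calling, significance-based
chromatin-loop calling, a gene-pair feature-association ledger, and
loop-conditioned coregulation regressions — with a synthetic allopolyploid
Hi-C/Hi-ChIP generator that plants every structure the analyses are meant to
detect.

## Who this is for

Groups studying 3D genome organization in allopolyploid plants (hexaploid
bread wheat being the motivating system: three subgenomes A/B/D, homeologous
chromosome groups 1–7) who need a transparent, testable re-implementation of
the standard analysis chain over binned contact matrices, rather than a
patchwork of external tools.

## The analyses

Given a binned contact map (sparse-triplet TSV) the package computes:

1. **Territories** — ICE-balance the map, aggregate into large super-bins
   (10 Mb in the wheat analysis), classify every unordered super-bin pair as
   intra-chromosomal / within-subgenome / cross-subgenome, and compare class
   medians. The homeolog vs non-homeolog contrast is tested with a two-sided
   Mann-Whitney U (exact enumeration for n₁+n₂ ≤ 12) and a Cliff's Delta
   effect size δ = (#{xᵢ>yⱼ} − #{xᵢ<yⱼ})/(n₁n₂).
2. **Insulation / ICONS** — per-bin insulation score
   log₂(mean w-window contact straddling the bin / chromosome mean); maximal
   runs of bins with score ≥ 0.4 (25-kb bins, 100-kb window by default) are
   called as condensed folding domains; bins are partitioned into insulation
   deciles and genes assigned by the ≥ 50 % overlap rule; meta-profiles of any
   signal over scaled gene bodies ± flanks.
3. **Loops** — expected counts from a coverage-scaled distance-decay model
   (intra) or a coverage product (inter); per pair Z = (obs−exp)/√exp, an
   upper-tail Poisson p, and Benjamini–Hochberg q over the tested pool; loops
   are pairs with p < 0.05, Z > 1.5, q < 0.1 (the published thresholds).
4. **Pair ledger** — loop anchors annotated with genes (any overlap), all
   anchor-gene combinations emitted as pair records; 2×2 feature associations
   with odds ratios (Haldane–Anscombe +0.5 on zero cells), χ² and Cramér's
   V = √(χ²/n); expression-quantile concordance matrices; partner counts.
5. **Coregulation** — OLS of partner log₂ fold changes over differentially
   expressed pairs of conserved loops, pooled and stratified by distance or by
   loop-strength quartiles in two conditions.

The synthetic generator (`territoria.simulate`) draws Poisson counts around a
fully specified expected model: power-law decay, the territory hierarchy with
a homeolog bonus and a Rabl anti-diagonal, condensed gene-poor domains with
gene-rich boundary bins, planted gene-to-gene loops whose partner genes share
marks and expression, and a two-condition expression model with configurable
log₂FC coupling. Everything planted is recorded in a `SimTruth` for recovery
tests.

## Worked example

```bash
python analysis/01_simulate_genome.py
python analysis/02_territories.py
```

The first script plants the study fixture (3 subgenomes × 2 chromosomes ×
4.2 Mb at 25-kb bins) and prints:

```
Planted a 6-chromosome hexaploid-like genome: 60 condensed domains, 90 loops,
200 genes (70% expressed).
```

The second balances the map, aggregates into 1-Mb super-bins and prints:

```
Territory hierarchy ordered intra > same-subgenome > cross-subgenome;
homeolog chromosome pairs interact more than non-homeologs
(delta = 1.00, p = 1.08e-50).
```

meaning the class medians recover the planted interaction hierarchy and the
homeolog bonus is detected with complete dominance (δ = 1 on this synthetic
map; real wheat data show a weaker but clearly positive effect). The remaining
scripts (`03`–`06`) call domains (100 % of planted boundaries recovered within
one 25-kb bin under strong depletion), call loops in two conditions (100 % of
planted 5-fold loops recovered; false calls within the BH budget on a pure
null), build the association ledger (concordant transcriptional status,
log₂OR ≈ 2.5 on the fixture), and fit the coregulation regressions (recovered
slope 0.46, R² 0.21 at the 1659-pair study scale against a planted
0.483 / 0.23; 0.93 in the strongest strength-quartile cell against a planted
0.90). All tables land in `results/`.

The same stages run from one configuration via the CLI:

```bash
territoria run --config cfg.yaml --seed 7       # or: territoria simulate/balance/...
```

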