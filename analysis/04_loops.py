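#!/usr/bin/env python
"""Call chromatin loops in two conditions and assess sensitivity/error control.

Calls intra-chromosomal loops (p < 0.05, Z > 1.5, FDR < 0.1) on the shoot and
root replicates of the fixture genome, matches conserved loops, measures
recovery of the planted 5-fold loops, and runs a pure-null replicate to check
the false-call budget.

Writes: results/loops_summary.tsv
"""

from pathlib import Path

import numpy as np
import pandas as pd

import territoria as t

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 7


def main() -> None:
    OUT.mkdir(exist_ok=True)
    layout = t.make_layout(3, 2, 4_200_000, 25_000)
    params = t.SimParams(seed=SEED)
    shoot, truth = t.simulate_contacts(layout, params)
    t.simulate_genes_and_expression(layout, truth, params)
    root = t.resample_contacts(truth)

    ls_shoot = t.call_loops_intra(shoot, condition="shoot")
    ls_root = t.call_loops_intra(root, condition="root")
    conserved = t.conserved_loops(ls_shoot, ls_root)

    planted = {
        (int(r.bin1), int(r.bin2))
        for r in truth.planted_loops.query("kind == 'intra'").itertuples()
    }
    called = {(int(r.bin1), int(r.bin2)) for r in ls_shoot.loops.itertuples()}
    sensitivity = len(planted & called) / len(planted)

    null_params = t.SimParams(
        seed=SEED + 5, n_domains=0, loop_rate=0, inter_loop_rate=0,
        domain_depletion=1.0, rabl_strength=1.0,
    )
    ls_null = t.call_loops_intra(t.simulate_contacts(layout, null_params)[0])
    bound = 0.1 * ls_null.n_tested + 3 * np.sqrt(0.1 * ls_null.n_tested)

    report = pd.DataFrame(
        [
            ("loops_shoot", len(ls_shoot)),
            ("loops_root", len(ls_root)),
            ("loops_conserved", len(conserved)),
            ("planted_intra_loops", len(planted)),
            ("planted_sensitivity", round(sensitivity, 4)),
            ("null_tested_pairs", ls_null.n_tested),
            ("null_false_calls", len(ls_null)),
            ("null_bh_budget", round(bound, 1)),
        ],
        columns=["statistic", "value"],
    )
    report.to_csv(OUT / "loops_summary.tsv", sep="\t", index=False)
    print(report.to_string(index=False))
    print(
        f"\n{len(ls_shoot)} shoot / {len(ls_root)} root loops, {len(conserved)} "
        f"conserved; {sensitivity:.0%} of planted 5-fold loops recovered; "
        f"pure-null run produced {len(ls_null)} calls against a BH budget of "
        f"{bound:.0f} (note: the fixture's condensed domains are genuinely "
        "enriched, so most fixture calls reflect planted domain structure)."
    )


if __name__ == "__main__":
    main()
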