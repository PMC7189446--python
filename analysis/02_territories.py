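#!/usr/bin/env python
"""Quantify the genome-territory hierarchy on the study fixture.

Balances the simulated contact map, aggregates into 1-Mb super-bins, and
compares interaction frequencies per class: within chromosomes, between
chromosomes of one subgenome, and across subgenomes — with the homeolog vs
non-homeolog contrast (Mann-Whitney U, Cliff's Delta).

Writes: results/territory_report.tsv
"""

from pathlib import Path

import pandas as pd

import territoria as t
from territoria.territories import homeolog_contrast

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 7


def main() -> None:
    OUT.mkdir(exist_ok=True)
    layout = t.make_layout(3, 2, 4_200_000, 25_000)
    matrix, _ = t.simulate_contacts(layout, t.SimParams(seed=SEED))
    balanced = t.ice_normalize(matrix)
    table = t.classify_and_aggregate(balanced, super_bin=1_000_000)
    med = t.median_by_class(table)
    contrast = homeolog_contrast(table)

    rows = [("median_" + k, v) for k, v in sorted(med["class_medians"].items())]
    rows += [("median_pair_" + k, v) for k, v in sorted(med["subgenome_pair_medians"].items())]
    rows += [
        ("hierarchy_ordered", float(med["hierarchy_ok"])),
        ("homeolog_u", contrast.u),
        ("homeolog_p", contrast.p),
        ("homeolog_cliffs_delta", contrast.cliffs_delta),
    ]
    report = pd.DataFrame(rows, columns=["statistic", "value"])
    report.to_csv(OUT / "territory_report.tsv", sep="\t", index=False, float_format="%.6g")
    print(report.to_string(index=False))
    verdict = "ordered intra > same-subgenome > cross-subgenome" if med["hierarchy_ok"] \
        else "NOT ordered"
    print(
        f"\nTerritory hierarchy {verdict}; homeolog chromosome pairs interact "
        f"more than non-homeologs (delta = {contrast.cliffs_delta:.2f}, "
        f"p = {contrast.p:.2e})."
    )


if __name__ == "__main__":
    main()
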