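"""Anchor annotation, 2x2 association statistics, concordance, partner counts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import territoria as t
from territoria.ledger import _contingency


def _loopset(rows, resolution=100):
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "bin1", "bin2", "observed", "expected", "z", "p", "q", "kind"]
    return t.LoopSet(pd.DataFrame(rows, columns=cols), resolution, 0.05, 1.5, 0.1, "intra")


def _genes(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    df["expressed"] = True
    return df


# ---------------------------------------------------------------------------
# anchor annotation
# ---------------------------------------------------------------------------


def test_one_gene_per_anchor_one_pair():
    loops = _loopset([["1A", 0, 100, "1A", 500, 600, 0, 5, 30, 10, 5.0, 1e-5, 1e-4, "intra"]])
    genes = _genes([["g1", "1A", 10, 90], ["g2", "1A", 510, 590]])
    pairs = t.annotate_anchors(loops, genes)
    assert len(pairs) == 1
    assert (pairs.loc[0, "gene1"], pairs.loc[0, "gene2"]) == ("g1", "g2")
    assert pairs.loc[0, "z"] == 5.0


def test_cross_product_of_anchor_genes():
    loops = _loopset([["1A", 0, 100, "1A", 500, 600, 0, 5, 30, 10, 5.0, 1e-5, 1e-4, "intra"]])
    genes = _genes(
        [["a1", "1A", 0, 50], ["a2", "1A", 50, 100],
         ["b1", "1A", 500, 530], ["b2", "1A", 530, 560], ["b3", "1A", 560, 600]]
    )
    pairs = t.annotate_anchors(loops, genes)
    assert len(pairs) == 2 * 3


def test_geneless_anchor_drops_loop():
    loops = _loopset([["1A", 0, 100, "1A", 500, 600, 0, 5, 30, 10, 5.0, 1e-5, 1e-4, "intra"]])
    genes = _genes([["g1", "1A", 10, 90]])
    assert len(t.annotate_anchors(loops, genes)) == 0


def test_gene_overlapping_both_anchors_self_pair_excluded():
    loops = _loopset([["1A", 0, 100, "1A", 200, 300, 0, 2, 30, 10, 5.0, 1e-5, 1e-4, "intra"]])
    genes = _genes([["big", "1A", 50, 250], ["g2", "1A", 210, 290]])
    pairs = t.annotate_anchors(loops, genes)
    # big x big self pair excluded; big x g2 kept (from either anchor side)
    assert (pairs["gene1"] != pairs["gene2"]).all()
    assert {"big", "g2"} == set(pairs[["gene1", "gene2"]].to_numpy().ravel())


def test_intra_pairs_ordered_genomically():
    loops = _loopset([["1A", 500, 600, "1A", 0, 100, 5, 0, 30, 10, 5.0, 1e-5, 1e-4, "intra"]])
    genes = _genes([["down", "1A", 510, 590], ["up", "1A", 10, 90]])
    pairs = t.annotate_anchors(loops, genes)
    assert pairs.loc[0, "gene1"] == "up"  # upstream gene listed first
    assert pairs.loc[0, "distance"] == pytest.approx(500.0)


# ---------------------------------------------------------------------------
# 2x2 contingency statistics
# ---------------------------------------------------------------------------


def test_independence_table():
    r = _contingency(25, 25, 25, 25)
    assert r.odds_ratio == 1.0 and r.log2_or == 0.0 and r.cramers_v == 0.0


def test_closed_form_example():
    r = _contingency(10, 5, 5, 10)
    assert r.odds_ratio == pytest.approx(4.0)
    assert r.log2_or == pytest.approx(2.0)
    assert r.chi2 == pytest.approx(10 / 3)
    assert r.cramers_v == pytest.approx(1 / 3)
    assert not r.haldane_applied


def test_haldane_correction_on_zero_cell():
    r = _contingency(10, 0, 0, 10)
    assert r.haldane_applied
    assert r.odds_ratio == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))  # 441


def test_cramers_v_phi_identity(rng):
    # V = |ad - bc| / sqrt((a+b)(c+d)(a+c)(b+d)) for 2x2 tables
    for _ in range(20):
        a, b, c, d = rng.integers(1, 50, size=4)
        r = _contingency(int(a), int(b), int(c), int(d))
        phi = abs(a * d - b * c) / np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
        assert r.cramers_v == pytest.approx(phi, rel=1e-12)


def test_table_sums_to_pair_count(structured_sim):
    _, _, matrix, truth, genes = structured_sim
    ls = t.call_loops_intra(matrix)
    pairs = t.annotate_anchors(ls, genes)
    r = t.feature_association(pairs, "expressed", "expressed")
    assert r.n == len(pairs)


# ---------------------------------------------------------------------------
# association matrix
# ---------------------------------------------------------------------------


def _feature_pairs(f1, f2, n=None):
    n = n or len(f1)
    return pd.DataFrame(
        {
            "gene1": [f"a{i}" for i in range(n)],
            "gene2": [f"b{i}" for i in range(n)],
            "H3K9ac1": f1,
            "H3K9ac2": f2,
            "expressed1": f1,
            "expressed2": f2,
        }
    )


def test_concordant_simulation_strong_diagonal(rng):
    f = rng.random(2000) < 0.5
    pairs = _feature_pairs(f, f)
    ledger = t.association_matrix(pairs, ["H3K9ac", "expressed"])
    diag = ledger[(ledger["feature1"] == "H3K9ac") & (ledger["feature2"] == "H3K9ac")]
    assert diag["log2_or"].iloc[0] > 3


def test_independent_features_small_log2_or(rng):
    hits = 0
    for seed in range(10):
        r = np.random.default_rng(900 + seed)
        pairs = _feature_pairs(r.random(5000) < 0.5, r.random(5000) < 0.5)
        ledger = t.association_matrix(pairs, ["H3K9ac"])
        if abs(ledger["log2_or"].iloc[0]) <= 0.3:
            hits += 1
    assert hits >= 9


def test_mirrored_input_identical_ledger(rng):
    f1 = rng.random(500) < 0.4
    f2 = rng.random(500) < 0.6
    pairs = _feature_pairs(f1, f2)
    swapped = _feature_pairs(f2, f1)
    l1 = t.association_matrix(pairs, ["H3K9ac"], symmetrize=True)
    l2 = t.association_matrix(swapped, ["H3K9ac"], symmetrize=True)
    pd.testing.assert_frame_equal(l1, l2)


# ---------------------------------------------------------------------------
# expression concordance
# ---------------------------------------------------------------------------


def _tpm_pairs(t1, t2):
    n = len(t1)
    return pd.DataFrame(
        {
            "gene1": [f"a{i}" for i in range(n)],
            "gene2": [f"b{i}" for i in range(n)],
            "tpm_shoot1": t1,
            "tpm_shoot2": t2,
        }
    )


def test_equal_tpms_all_mass_on_diagonal(rng):
    tpm = rng.lognormal(2, 1, size=400)
    conc = t.expression_concordance(_tpm_pairs(tpm, tpm), n_quantiles=4)
    assert conc.attrs["diagonal_fraction"] == 1.0


def test_independent_tpms_uniform_cells(rng):
    r = np.random.default_rng(77)
    conc = t.expression_concordance(
        _tpm_pairs(r.lognormal(2, 1, 10_000), r.lognormal(2, 1, 10_000)), n_quantiles=4
    )
    counts = conc.to_numpy().ravel()
    _, p = stats.chisquare(counts)
    assert p > 0.01


def test_correlated_tpms_diagonal_exceeds_off(rng):
    r = np.random.default_rng(78)
    z1 = r.normal(size=3000)
    z2 = 0.8 * z1 + np.sqrt(1 - 0.64) * r.normal(size=3000)
    conc = t.expression_concordance(
        _tpm_pairs(np.exp(z1), np.exp(z2)), n_quantiles=4
    )
    m = conc.to_numpy()
    diag_mean = np.diagonal(m).mean()
    off_mean = (m.sum() - np.trace(m)) / (m.size - 4)
    assert diag_mean > off_mean
    # marginals balanced: each side's quantiles hold ~ n/4
    np.testing.assert_allclose(m.sum(axis=0), 750, atol=1)
    np.testing.assert_allclose(m.sum(axis=1), 750, atol=1)


def test_degenerate_tpms_rejected():
    with pytest.raises(ValueError):
        t.expression_concordance(_tpm_pairs(np.ones(50), np.ones(50)))


# ---------------------------------------------------------------------------
# partner counts
# ---------------------------------------------------------------------------


def test_partner_counting_star_and_duplicates():
    pairs = pd.DataFrame(
        {"gene1": ["A", "A", "A", "A"], "gene2": ["B", "C", "D", "B"]}
    )
    counts, summary = t.partner_counts(pairs)
    assert counts["A"] == 3
    assert counts["B"] == 1  # duplicate (A,B) counted once
    assert summary["fraction_ge_4"] == 0.0


def test_partner_fraction_ten_star():
    pairs = pd.DataFrame(
        {"gene1": ["A"] * 10, "gene2": [f"g{k}" for k in range(10)]}
    )
    counts, summary = t.partner_counts(pairs)
    assert counts["A"] == 10
    assert summary["fraction_ge_10"] == pytest.approx(1 / 11)


# ---------------------------------------------------------------------------
# deposited pair-table ingestion
# ---------------------------------------------------------------------------


def test_read_pair_table_synthetic_fixture(tmp_path):
    # synthetic stand-in for a deposited pair table (schema check only)
    path = tmp_path / "synthetic_pairs.tsv"
    pd.DataFrame(
        {
            "first_gene": ["g1", "g2", "g3"],
            "second_gene": ["h1", "h2", "h3"],
            "expr_status_1": ["expressed", "non-expressed", "expressed"],
            "expr_status_2": [1, 0, 1],
        }
    ).to_csv(path, sep="\t", index=False)
    out = t.read_pair_table(
        path,
        column_map={
            "gene1": "first_gene",
            "gene2": "second_gene",
            "expressed1": "expr_status_1",
            "expressed2": "expr_status_2",
        },
    )
    assert out["expressed1"].to_list() == [True, False, True]
    assert out["expressed2"].to_list() == [True, False, True]
    r = t.feature_association(out, "expressed", "expressed")
    assert (r.a, r.b, r.c, r.d) == (2, 0, 0, 1)


def test_read_pair_table_requires_gene_columns(tmp_path):
    path = tmp_path / "bad.tsv"
    pd.DataFrame({"x": [1]}).to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError):
        t.read_pair_table(path, column_map={"gene1": "nope"})
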