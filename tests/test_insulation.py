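"""Insulation scores, domain calling, deciles, gene assignment, meta-profiles."""

import numpy as np
import pandas as pd
import pytest

import territoria as t
from territoria.insulation import InsulationTrack, track_signal


def _track_from_scores(scores, bin_size=25_000, chrom="1A"):
    n = len(scores)
    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * bin_size,
            "end": (np.arange(n) + 1) * bin_size,
            "raw": np.nan,
            "score": np.asarray(scores, dtype=float),
        }
    )
    return InsulationTrack(bins=bins, window=bin_size * 2, bin_size=bin_size)


def _recovery_sim(seed=13):
    """Strong-depletion study conditions for boundary recovery."""
    lay = t.make_layout(3, 2, 4_200_000, 25_000)  # 168 bins per chromosome
    params = t.SimParams(
        seed=seed, base_rate=500.0, domain_depletion=0.05,
        n_domains=10, domain_bins=10, gap_bins=6,
        loop_rate=0, inter_loop_rate=0, rabl_strength=1.0,
    )
    m, truth = t.simulate_contacts(lay, params)
    b = t.ice_normalize(m, mask_fraction=0.0)
    return b, truth


# ---------------------------------------------------------------------------
# insulation index
# ---------------------------------------------------------------------------


def test_constant_matrix_scores_zero():
    lay = t.make_layout(1, 1, 2_000_000, 100_000)
    m = t.ContactMatrix(lay, np.full((20, 20), 3.0))
    track = t.insulation_index(m, window=300_000)
    defined = track.bins["score"].dropna()
    assert len(defined) == 20 - 2 * 3
    np.testing.assert_allclose(defined, 0.0, atol=1e-12)


def test_edges_are_missing():
    lay = t.make_layout(1, 2, 1_000_000, 100_000)
    m = t.ContactMatrix(lay, np.ones((20, 20)))
    track = t.insulation_index(m, window=200_000)
    for sl in lay.chrom_slices().values():
        score = track.bins["score"].to_numpy()[sl]
        assert np.isnan(score[:2]).all() and np.isnan(score[-2:]).all()
        assert np.isfinite(score[2:-2]).all()


def test_matches_brute_force_window_average(rng):
    lay = t.make_layout(1, 1, 2_500_000, 100_000)  # 25 bins
    raw = rng.uniform(1, 20, size=(25, 25))
    raw = (raw + raw.T) / 2
    m = t.ContactMatrix(lay, raw)
    w = 3
    track = t.insulation_index(m, window=300_000)
    raws = np.full(25, np.nan)
    for i in range(w, 25 - w):
        vals = [raw[u, v] for u in range(i - w, i) for v in range(i + 1, i + w + 1)]
        raws[i] = np.mean(vals)
    mean = np.nanmean(raws)
    expected = np.log2(raws / mean)
    np.testing.assert_allclose(
        track.bins["score"].to_numpy(), expected, rtol=1e-12, equal_nan=True
    )


def test_planted_depleted_boundary_is_local_minimum():
    # two condensed domains separated by a contact-depleted boundary bin:
    # the insulation minimum plateau is centred on the boundary
    lay = t.make_layout(1, 1, 3_000_000, 100_000)  # 30 bins
    n, w = 30, 2
    base = np.full((n, n), 2.0)
    for dom in (slice(4, 14), slice(15, 25)):
        sub = base[dom, dom]
        base[dom, dom] = 20.0
    m = t.ContactMatrix(lay, base)
    track = t.insulation_index(m, window=w * 100_000)
    score = track.bins["score"].to_numpy()
    boundary = 14
    interior = np.concatenate([score[6:12], score[17:23]])
    assert score[boundary] < interior.min()
    # minimum within the square-window resolution (plateau of width 2w-1)
    lo = np.flatnonzero(score == np.nanmin(score))
    assert np.abs(lo - boundary).min() <= w - 1
    assert score[boundary] <= score[boundary - w] and score[boundary] <= score[boundary + w]


def test_window_validation():
    lay = t.make_layout(1, 1, 1_000_000, 100_000)
    m = t.ContactMatrix(lay, np.ones((10, 10)))
    with pytest.raises(ValueError):
        t.insulation_index(m, window=50_000)


# ---------------------------------------------------------------------------
# domain calling
# ---------------------------------------------------------------------------


def test_all_scores_below_threshold_empty_set():
    track = _track_from_scores([-1.0, -0.5, 0.0, 0.2])
    assert t.call_domains(track, 0.4).count == 0


def test_run_length_calling_example():
    track = _track_from_scores([-1.0, 0.5, 0.6, -1.0])
    domains = t.call_domains(track, threshold=0.4, min_bins=2)
    assert domains.count == 1
    d = domains.intervals.iloc[0]
    assert (d["start"], d["end"]) == (25_000, 75_000)  # bins 2-3 at 25 kb
    assert domains.mean_size == 50_000


def test_min_bins_respected():
    track = _track_from_scores([0.5, -1.0, 0.5, 0.5])
    domains = t.call_domains(track, threshold=0.4, min_bins=2)
    assert domains.count == 1 and domains.intervals.iloc[0]["n_bins"] == 2


def test_domains_never_overlap_and_summary_consistent(structured_sim):
    _, _, matrix, _, _ = structured_sim
    b = t.ice_normalize(matrix)
    track = t.insulation_index(b, window=100_000)
    domains = t.call_domains(track, 0.4)
    iv = domains.intervals.sort_values(["chrom", "start"])
    for _, grp in iv.groupby("chrom"):
        assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()
    assert (iv["n_bins"] >= 2).all()
    assert domains.coverage_fraction == pytest.approx(
        (iv["end"] - iv["start"]).sum() / (6 * 4_200_000)
    )


def test_planted_boundary_recovery_within_one_bin():
    # >= 90% of planted domain edges recovered within +/- 1 bin
    b, truth = _recovery_sim()
    track = t.insulation_index(b, window=25_000)
    domains = t.call_domains(track, threshold=0.4, min_bins=2)
    called = domains.intervals
    bs = 25_000
    hits = total = 0
    for d in truth.planted_domains.itertuples():
        same = called[called["chrom"] == d.chrom]
        for edge in (d.start, d.end):
            total += 1
            cands = np.concatenate([same["start"].to_numpy(), same["end"].to_numpy()])
            if len(cands) and np.min(np.abs(cands - edge)) <= bs:
                hits += 1
    assert hits / total >= 0.90


def test_score_inside_domains_exceeds_boundaries():
    b, truth = _recovery_sim()
    track = t.insulation_index(b, window=25_000)
    score = track.bins["score"].to_numpy()
    inside, boundary = [], []
    for d in truth.planted_domains.itertuples():
        inside.extend(score[d.start_bin + 1 : d.end_bin - 1])
    boundary = score[truth.boundary_bins]
    inside = np.asarray(inside)
    boundary = boundary[~np.isnan(boundary)]
    assert np.nanmean(inside) > np.nanmean(boundary)


# ---------------------------------------------------------------------------
# deciles
# ---------------------------------------------------------------------------


def test_deciles_equal_counts_and_remainder_rule():
    track = _track_from_scores(np.linspace(-1, 1, 20))
    labels = t.partition_deciles(track)
    assert labels.value_counts().eq(2).all()
    track25 = _track_from_scores(np.linspace(-1, 1, 25))
    sizes = t.partition_deciles(track25).value_counts().sort_index().to_list()
    assert sizes == [3, 3, 3, 3, 3, 2, 2, 2, 2, 2]


def test_decile_one_is_most_negative():
    scores = np.linspace(-2, 2, 30)
    track = _track_from_scores(scores)
    labels = t.partition_deciles(track)
    assert labels.iloc[0] == 1 and labels.iloc[-1] == 10


def test_decile_ties_broken_by_genomic_order():
    track = _track_from_scores([0.0] * 20)
    labels = t.partition_deciles(track)
    # with all scores tied, deciles follow genomic order
    assert labels.to_list() == sorted(labels.to_list())


def test_decile_labels_permutation_invariant(rng):
    scores = rng.normal(size=40)
    track = _track_from_scores(scores)
    labels = t.partition_deciles(track)
    # shuffle bin order, relabel, map back: identical labels per score
    perm = rng.permutation(40)
    shuffled = _track_from_scores(scores[perm])
    back = np.empty(40)
    back[perm] = t.partition_deciles(shuffled).to_numpy()
    np.testing.assert_array_equal(back, labels.to_numpy())


def test_too_few_defined_bins_rejected():
    with pytest.raises(ValueError):
        t.partition_deciles(_track_from_scores([0.1] * 9))


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------


@pytest.fixture()
def labelled_bins():
    bins = pd.DataFrame(
        {"chrom": "1A", "start": [0, 100, 200], "end": [100, 200, 300]}
    )
    labels = pd.Series([1.0, 2.0, 3.0])
    return bins, labels


def _gene(start, end, gid="g1"):
    return pd.DataFrame({"gene_id": [gid], "chrom": "1A", "start": [start], "end": [end]})


def test_gene_fully_inside_one_bin(labelled_bins):
    bins, labels = labelled_bins
    out = t.assign_genes(_gene(110, 150), bins, labels)
    assert out.iloc[0] == 2.0


def test_gene_split_evenly_goes_left(labelled_bins):
    bins, labels = labelled_bins
    out = t.assign_genes(_gene(50, 150), bins, labels)
    assert out.iloc[0] == 1.0


def test_gene_spanning_three_bins_majority_wins(labelled_bins):
    bins, labels = labelled_bins
    # 20% in bin1, 60% in bin2, 20% in bin3
    out = t.assign_genes(_gene(80, 245), bins, labels)
    assert out.iloc[0] == 2.0


def test_gene_below_overlap_fraction_unassigned(labelled_bins):
    bins, labels = labelled_bins
    # spans bins 1-3 with max overlap 100/250 = 40% < 50%
    out = t.assign_genes(_gene(40, 290), bins, labels)
    assert np.isnan(out.iloc[0])


def test_malformed_gene_interval_rejected(labelled_bins):
    bins, labels = labelled_bins
    with pytest.raises(ValueError):
        t.assign_genes(_gene(150, 150), bins, labels)


# ---------------------------------------------------------------------------
# meta-profiles
# ---------------------------------------------------------------------------


def test_metaprofile_constant_signal_flat():
    sig = {"1A": np.full(100, 7.0)}
    regions = pd.DataFrame(
        {"chrom": ["1A"], "start": [3000], "end": [6000], "strand": ["+"]}
    )
    prof = t.metaprofile(sig, 100, regions, body_bins=10, flank=1000, flank_bins=5)
    assert len(prof) == 20
    np.testing.assert_allclose(prof["value"], 7.0)


def test_metaprofile_body_vs_flank_contrast():
    sig = {"1A": np.zeros(100)}
    sig["1A"][30:60] = 1.0  # gene body [3000, 6000)
    regions = pd.DataFrame(
        {"chrom": ["1A"], "start": [3000], "end": [6000], "strand": ["+"]}
    )
    prof = t.metaprofile(sig, 100, regions, body_bins=10, flank=1000, flank_bins=5)
    assert (prof.loc[prof["segment"] == "body", "value"] == 1.0).all()
    assert (prof.loc[prof["segment"] != "body", "value"] == 0.0).all()


def test_metaprofile_minus_strand_reverses():
    sig = {"1A": np.arange(100, dtype=float)}
    plus = pd.DataFrame({"chrom": ["1A"], "start": [2000], "end": [8000], "strand": ["+"]})
    minus = plus.assign(strand="-")
    p_plus = t.metaprofile(sig, 100, plus, body_bins=12, flank=1000, flank_bins=4)
    p_minus = t.metaprofile(sig, 100, minus, body_bins=12, flank=1000, flank_bins=4)
    np.testing.assert_allclose(
        p_minus["value"].to_numpy(), p_plus["value"].to_numpy()[::-1]
    )
    # ascending signal becomes descending on the minus strand
    assert np.all(np.diff(p_minus["value"]) < 0)


def test_insulation_over_genes_classes(structured_sim):
    _, _, matrix, truth, genes = structured_sim
    b = t.ice_normalize(matrix)
    track = t.insulation_index(b, window=100_000)
    profiles = t.insulation_over_genes(track, genes, split_by="expressed", flank=50_000)
    assert set(profiles) <= {"True", "False"}
    for prof in profiles.values():
        assert len(prof) == 30 + 2 * 10


def test_boundary_genes_sit_at_insulation_minima():
    # genes live at domain boundaries: their body insulation is below genome mean
    b, truth = _recovery_sim()
    params = truth.params
    genes = t.simulate_genes_and_expression(b.layout, truth, params)
    track = t.insulation_index(b, window=25_000)
    sig, step = track_signal(track)
    boundary_genes = genes[genes["bin"].isin(truth.boundary_bins)]
    prof = t.metaprofile(sig, step, boundary_genes, body_bins=4, flank=25_000, flank_bins=1)
    body = prof.loc[prof["segment"] == "body", "value"].mean()
    assert body < 0  # below the chromosome average (score 0)
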