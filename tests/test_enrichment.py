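"""Overlap tests, BH correction, pre-ranked GSEA, distance windows, track
summaries, metagene profiles, contact-change ranking and small helpers."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from senhic.bins import GenomeBins
from senhic.compartments import CompartmentSet, TransitionMap
from senhic.enrichment import (
    benjamini_hochberg,
    fraction_downregulated,
    gene_sahf_distances,
    genes_in_distance_windows,
    genes_in_intervals,
    hypergeometric_overlap,
    linear_r2,
    mann_whitney,
    metagene_profile,
    preranked_gsea,
    quantify_nuclear_signal,
    rank_compartment_contact_change,
    summarize_track_by_category,
    window_sweep,
)
from senhic.matrix import ContactMatrix


def exact_upper_tail(N, K, n, k):
    """P(X >= k) for hypergeometric(N, K, n) by exact rational enumeration."""
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x),
                          math.comb(N, n))
    return float(total)


class TestHypergeometric:
    def test_printed_example(self):
        r = hypergeometric_overlap(set(range(4)), {0, 1, 2, 5, 6}, 10)
        assert r.overlap == 3
        assert r.p_value == pytest.approx(66 / 252, rel=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 21))
        s1 = set(rng.choice(N, rng.integers(1, N + 1), replace=False).tolist())
        s2 = set(rng.choice(N, rng.integers(1, N + 1), replace=False).tolist())
        r = hypergeometric_overlap(s1, s2, N)
        want = exact_upper_tail(N, len(s1), len(s2), r.overlap)
        assert r.p_value == pytest.approx(want, rel=1e-12)

    def test_zero_overlap_is_one(self):
        r = hypergeometric_overlap({0, 1}, {5, 6}, 10)
        assert r.p_value == 1.0

    def test_forced_total_overlap_is_one(self):
        s = set(range(10))
        assert hypergeometric_overlap(s, s, 10).p_value == 1.0

    def test_log_tail_finite_and_monotone_at_genome_scale(self):
        N = 75_000
        logs = [hypergeometric_overlap(set(range(5000)),
                                       set(range(k)), N).log10_p
                for k in (1000, 2000, 3000, 4000, 5000)]
        assert all(np.isfinite(logs))
        assert all(b < a for a, b in zip(logs, logs[1:]))
        assert logs[-1] < -1000  # representable far below float underflow

    def test_population_required(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap({0}, {1}, 0)


class TestBenjaminiHochberg:
    def test_step_up_example(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_and_equal_values_unchanged(self):
        assert benjamini_hochberg([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(benjamini_hochberg([0.1, 0.1, 0.1]),
                                   [0.1, 0.1, 0.1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_never_decreases_and_preserves_order(self, ps):
        adj = benjamini_hochberg(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


@pytest.fixture(scope="module")
def null_ranking():
    rng = np.random.default_rng(11)
    return pd.Series(rng.normal(0, 1, 1000),
                     index=[f"g{i}" for i in range(1000)])


class TestGSEA:
    def test_top_genes_hit_the_p_floor(self, null_ranking):
        top = null_ranking.sort_values(ascending=False).index[:50]
        r = preranked_gsea(null_ranking, top, n_perm=500, seed=0)
        assert r.es > 0 and r.nes > 0
        # every same-sign null is milder than the maximal enrichment
        n_pos = round(1 / r.p_value) - 1
        assert r.p_value == pytest.approx(1 / (n_pos + 1))
        assert r.p_value < 0.01

    def test_reversing_ranking_negates_es(self, null_ranking):
        top = null_ranking.sort_values(ascending=False).index[:50]
        fwd = preranked_gsea(null_ranking, top, n_perm=500, seed=0)
        rev = preranked_gsea(-null_ranking, top, n_perm=500, seed=0)
        assert rev.es == pytest.approx(-fwd.es)
        assert rev.nes < 0 < fwd.nes

    def test_result_invariants(self, null_ranking):
        rng = np.random.default_rng(3)
        members = null_ranking.index[rng.choice(1000, 40, replace=False)]
        r = preranked_gsea(null_ranking, members, n_perm=200, seed=5)
        assert np.sign(r.nes) == np.sign(r.es)
        assert 1 / (r.n_perm + 1) <= r.p_value <= 1

    def test_same_seed_reproducible(self, null_ranking):
        members = null_ranking.index[:40:2]
        a = preranked_gsea(null_ranking, members, n_perm=200, seed=9)
        b = preranked_gsea(null_ranking, members, n_perm=200, seed=9)
        assert a == b

    def test_degenerate_sets_rejected(self, null_ranking):
        with pytest.raises(ValueError, match="intersect"):
            preranked_gsea(null_ranking, ["absent"], n_perm=200, seed=0)
        with pytest.raises(ValueError, match="degenerate"):
            preranked_gsea(null_ranking, null_ranking.index, n_perm=200,
                           seed=0)

    def test_type_one_error_calibrated(self, null_ranking):
        rng = np.random.default_rng(17)
        rej = 0
        n_trials = 400
        for t in range(n_trials):
            members = null_ranking.index[rng.choice(1000, 50, replace=False)]
            r = preranked_gsea(null_ranking, members, n_perm=200, seed=t)
            rej += r.p_value <= 0.05
        assert 0.02 <= rej / n_trials <= 0.08

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_enrichment_score_matches_gseapy(self, seed):
        """The weighted-KS running-sum extreme agrees with the independent
        gseapy implementation of the same statistic."""
        import gseapy
        rng = np.random.default_rng(seed)
        s = pd.Series(rng.normal(0, 1, 200),
                      index=[f"g{i}" for i in range(200)])
        s = s.sort_values(ascending=False)
        members = list(s.index[5:65:3])
        rnk = s.reset_index()
        rnk.columns = ["gene", "score"]
        ref = gseapy.prerank(rnk=rnk, gene_sets={"set": members},
                             permutation_num=10, outdir=None, seed=1,
                             weight=1.0, min_size=2, max_size=500,
                             no_plot=True, verbose=False)
        mine = preranked_gsea(s, members, n_perm=100, seed=0)
        assert mine.es == pytest.approx(float(ref.res2d["ES"][0]), rel=1e-9)

    def test_shifted_set_detected(self, null_ranking):
        rng = np.random.default_rng(23)
        idx = rng.choice(1000, 50, replace=False)
        shifted = null_ranking.copy()
        shifted.iloc[idx] += shifted.std()  # 1 SD planted enrichment
        r = preranked_gsea(shifted, shifted.index[idx], n_perm=1000, seed=1)
        assert r.es > 0 and r.p_value <= 0.01


def gene_table():
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(6)],
        "chrom": ["chr1"] * 5 + ["chr2"],
        "start": [0, 550_000, 1_100_000, 2_000_000, 3_000_000, 100_000],
        "end": [30_000, 580_000, 1_130_000, 2_030_000, 3_030_000, 130_000],
        "strand": ["+", "-", "+", "-", "+", "+"],
        "fc": [0.5, 0.8, 1.0, 2.0, 0.9, 1.5],
    })


class TestDistanceWindows:
    # one SAHF region on chr1 at [1.7 Mb, 1.9 Mb)
    SAHF = {"chr1": [(1_700_000, 1_900_000)]}

    def test_distances_from_nearest_edge(self):
        d = gene_sahf_distances(gene_table(), self.SAHF)
        assert d[0] == 1_670_000
        assert d[3] == 100_000          # downstream gap
        assert np.isnan(d[5])           # chromosome without SAHF

    def test_overlapping_gene_distance_zero(self):
        genes = gene_table()
        genes.loc[0, ["start", "end"]] = [1_650_000, 1_750_000]
        d = gene_sahf_distances(genes, self.SAHF)
        assert d[0] == 0
        assert "g0" in genes_in_distance_windows(genes, self.SAHF, 0, 200_000)
        assert "g0" not in genes_in_distance_windows(
            genes, self.SAHF, 200_000, 400_000)

    def test_window_membership(self):
        # gaps to [1.7, 1.9) Mb: g1 ends 580 kb -> 1.12 Mb;
        # g4 starts 3.0 Mb -> 1.10 Mb
        ids = genes_in_distance_windows(gene_table(), self.SAHF,
                                        1_100_000, 1_200_000)
        assert ids == ["g1", "g4"]

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            genes_in_distance_windows(gene_table(), self.SAHF, 100, 100)

    def test_sweep_counts_and_percentages(self):
        sweep = window_sweep(gene_table(), self.SAHF, "fc",
                             window_size=200_000, max_distance=400_000)
        assert list(sweep["window_start"]) == [0, 200_000]
        assert sweep["n_genes"].sum() >= 1

    def test_fraction_downregulated(self):
        genes = gene_table()
        assert fraction_downregulated(["g0", "g1", "g2", "g3"], genes,
                                      "fc") == 50.0
        assert np.isnan(fraction_downregulated([], genes, "fc"))
        # strict inequality: fc == 1 does not count
        assert fraction_downregulated(["g2"], genes, "fc") == 0.0


class TestMannWhitney:
    def test_separated_triples(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_larger_shift_smaller_p(self, rng):
        a = rng.normal(0, 1, 100)
        p1 = mann_whitney(a, a + 0.3)[1]
        p2 = mann_whitney(a, a + 1.0)[1]
        assert p2 < p1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestTrackSummary:
    def tmap(self, cats):
        cats = np.asarray(cats, dtype=object)
        return TransitionMap(GenomeBins("c", 40_000, len(cats)), cats)

    def test_constant_track_degenerate(self):
        tm = self.tmap(["AA"] * 20 + ["BB"] * 20)
        out = summarize_track_by_category(np.ones(40), tm, n_sample=10, seed=0)
        assert np.all(out["samples"]["AA"] == 1.0)
        assert out["pairwise_p"][("AA", "BB")] == 1.0

    def test_same_seed_same_samples(self):
        tm = self.tmap(["AA", "BB"] * 50)
        track = np.arange(100, dtype=float)
        a = summarize_track_by_category(track, tm, n_sample=5, seed=3)
        b = summarize_track_by_category(track, tm, n_sample=5, seed=3)
        np.testing.assert_array_equal(a["samples"]["AA"], b["samples"]["AA"])

    def test_small_category_uses_all_with_warning(self):
        tm = self.tmap(["AA"] * 3 + ["BB"] * 37)
        with pytest.warns(UserWarning, match="only 3 bins"):
            out = summarize_track_by_category(np.ones(40), tm, n_sample=10,
                                              seed=0)
        assert out["samples"]["AA"].size == 3

    def test_condensin_track_elevated_at_ba(self, truth, genes_tracks,
                                            pca_chr1):
        from senhic.compartments import classify_transitions
        _, tracks = genes_tracks
        tm = classify_transitions(pca_chr1["growing"], pca_chr1["senescent"])
        out = summarize_track_by_category(tracks["caph2"]["chr1"], tm,
                                          n_sample=30, seed=0)
        assert (np.median(out["samples"]["BA"])
                > np.median(out["samples"]["AB"]))


class TestMetagene:
    def genes(self, n=40, length=80_000):
        starts = np.arange(n) * 200_000 + 10_000
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "chrom": "chr1",
            "start": starts,
            "end": starts + length,
            "strand": ["+", "-"] * (n // 2),
            "expr": np.arange(n, dtype=float),
        })

    def test_constant_track_flat_everywhere(self):
        track = {"chr1": np.full(250, 2.0)}
        prof = metagene_profile(track, 40_000, self.genes(), "expr",
                                n_groups=4)
        assert np.allclose(prof.to_numpy(), 2.0)

    def test_top_group_sees_its_own_gene_bodies(self):
        genes = self.genes()
        values = np.zeros(250)
        top = genes.sort_values("expr").tail(10)
        for _, g in top.iterrows():
            values[g.start // 40_000: g.end // 40_000 + 1] = 1.0
        prof = metagene_profile({"chr1": values}, 40_000, genes, "expr",
                                n_groups=4, n_points=20, n_flank_points=5)
        body = prof.iloc[:, 5:25]
        assert body.iloc[3].mean() > 0.8
        assert body.iloc[0].mean() < 0.2

    def test_minus_strand_profile_mirrored(self):
        genes = self.genes(n=2)
        genes["strand"] = ["+", "+"]
        values = np.zeros(250)
        values[: genes.loc[0, "end"] // 40_000 + 1] = 1.0  # 5' side of g0
        fwd = metagene_profile({"chr1": values}, 40_000,
                               genes.iloc[[0]], "expr", n_groups=1)
        genes2 = genes.copy()
        genes2.loc[0, "strand"] = "-"
        rev = metagene_profile({"chr1": values}, 40_000,
                               genes2.iloc[[0]], "expr", n_groups=1)
        np.testing.assert_allclose(fwd.iloc[0].to_numpy(),
                                   rev.iloc[0].to_numpy()[::-1])

    def test_sub_bin_genes_skipped(self):
        genes = self.genes()
        genes.loc[0, "end"] = genes.loc[0, "start"] + 100
        prof = metagene_profile({"chr1": np.ones(250)}, 40_000, genes,
                                "expr", n_groups=4)
        assert prof.shape[0] == 4  # still produced, short gene dropped


class TestContactChangeRanking:
    def setup_pair(self, scale_block=None):
        rng = np.random.default_rng(4)
        n = 60
        c = rng.random((n, n)) + 1.0
        c = c + c.T
        bins = GenomeBins("c", 200_000, n)
        m1 = ContactMatrix(bins, c.copy(), normalized=True)
        c2 = c.copy()
        if scale_block is not None:
            s, e = scale_block
            c2[s:e + 1, s:e + 1] *= 0.8
        m2 = ContactMatrix(bins, c2, normalized=True)
        comps = CompartmentSet(
            GenomeBins("c", 40_000, n * 5),
            tuple((i * 50, i * 50 + 49, "A") for i in range(6)))
        return m1, m2, comps

    def test_identical_maps_all_ties(self):
        m1, m2, comps = self.setup_pair()
        df = rank_compartment_contact_change(m1, m1, comps,
                                             fine_bin_size=40_000)
        assert np.allclose(df["relative"], 1.0)
        # ties broken by genomic coordinate
        assert list(df["start_bin"]) == sorted(df["start_bin"])

    def test_scaled_compartment_lands_in_bottom(self):
        m1, m2, comps = self.setup_pair(scale_block=(10, 19))
        # coarse bins 10-19 correspond to the fine-grid compartment 50-99
        df = rank_compartment_contact_change(m2, m1, comps,
                                             bottom_fraction=0.2,
                                             fine_bin_size=40_000)
        sel = df[df["selected"]]
        assert 50 in sel["start_bin"].values

    def test_bottom_fraction_one_selects_all(self):
        m1, _, comps = self.setup_pair()
        df = rank_compartment_contact_change(m1, m1, comps,
                                             bottom_fraction=1.0,
                                             fine_bin_size=40_000)
        assert df["selected"].all()

    def test_genes_in_intervals(self):
        genes = gene_table()
        ids = genes_in_intervals(genes, "chr1", [(0, 600_000)])
        assert ids == ["g0", "g1"]


class TestSmallHelpers:
    def test_perfect_line(self):
        x = np.arange(10.0)
        assert linear_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_independent_noise(self, rng):
        x = rng.normal(0, 1, 1000)
        y = rng.normal(0, 1, 1000)
        assert linear_r2(x, y) < 0.01

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            linear_r2([0, 1], [0, 1])
        with pytest.warns(UserWarning):
            assert np.isnan(linear_r2([1, 1, 1], [0, 1, 2]))

    def test_nuclear_signal_correction(self):
        assert quantify_nuclear_signal(1000, 100, 2.0).signal == 800
        assert quantify_nuclear_signal(1000, 100, 0.0).signal == 1000
        out = quantify_nuclear_signal(100, 100, 2.0)
        assert out.signal == -100 and out.negative
        with pytest.raises(ValueError):
            quantify_nuclear_signal(-1, 1, 1)
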