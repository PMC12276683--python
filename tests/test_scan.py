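"""Window enumeration, Weir-Cockerham components, CLR scan, outliers and
interval annotation."""

import math

import numpy as np
import pytest

from oracles import wc84_components_oracle

from hybridscan.scan import (
    SweepGrid, Window, annotate_windows, estimate_omega, gene_overlap_percent,
    make_windows, outlier_windows, per_site_fst_components, windowed_fst,
    xpclr_window,
)
from hybridscan.variants import GeneModel, VariantRecord, VariantSet


class TestWindows:
    def test_enumeration_100kb(self):
        w = make_windows({"chr1": 100_000}, 50_000, 25_000)
        assert [(x.start, x.end) for x in w] == [
            (0, 50_000), (25_000, 75_000), (50_000, 100_000)]

    def test_trailing_partial_kept_and_enumeration_stops_at_end(self):
        w = make_windows({"chr1": 60_000}, 50_000, 25_000)
        assert [(x.start, x.end) for x in w] == [(0, 50_000), (25_000, 60_000)]

    def test_step_equals_size_tiles(self):
        w = make_windows({"chr1": 100_000}, 25_000, 25_000)
        starts = [x.start for x in w]
        assert starts == [0, 25_000, 50_000, 75_000]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_windows({"chr1": -5})
        with pytest.raises(ValueError):
            make_windows({"chr1": 100}, 10, 20)
        with pytest.raises(ValueError):
            Window("chr1", 10, 10)


class TestWCComponents:
    def test_fixed_difference_is_one(self):
        a, b, c = per_site_fst_components((10, 0, 0), (0, 0, 10))
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_identical_populations_near_zero(self):
        comp = per_site_fst_components((5, 5, 0), (5, 5, 0))
        oracle = wc84_components_oracle((5, 5, 0), (5, 5, 0))
        assert comp == pytest.approx(oracle, abs=1e-12)
        a, b, c = comp
        assert a / (a + b + c) <= 0.05

    def test_focal_site_counts_match_oracle(self):
        comp = per_site_fst_components((40, 0, 0), (21, 15, 1))
        oracle = wc84_components_oracle((40, 0, 0), (21, 15, 1))
        assert comp == pytest.approx(oracle, abs=1e-10)

    def test_random_grid_matches_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            c1 = tuple(int(x) for x in rng.integers(0, 30, 3))
            c2 = tuple(int(x) for x in rng.integers(0, 30, 3))
            if sum(c1) == 0 or sum(c2) == 0 or (sum(c1) + sum(c2)) <= 2:
                continue
            got = per_site_fst_components(c1, c2)
            assert got == pytest.approx(wc84_components_oracle(c1, c2),
                                        abs=1e-10)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            per_site_fst_components((0, 0, 0), (5, 5, 0))


def _vs_from_counts(rows):
    """rows: list of (genotypes for pop1+pop2) arrays"""
    recs = [VariantRecord("chr1", 100 + 10 * i, "A", "T",
                          np.asarray(g, np.int8)) for i, g in enumerate(rows)]
    n = len(rows[0])
    return VariantSet([f"s{i}" for i in range(n)], recs)


class TestWindowedFst:
    def test_single_site_window_equals_site_value(self):
        vs = _vs_from_counts([[0] * 10 + [2] * 10])
        w = [Window("chr1", 0, 1000)]
        scores = windowed_fst(vs, np.arange(10), np.arange(10, 20), w)
        a, b, c = per_site_fst_components((10, 0, 0), (0, 0, 10))
        assert scores[0].score == pytest.approx(a / (a + b + c))

    def test_ratio_of_sums_weighting(self):
        # one fixed-difference site plus one undifferentiated site: the
        # window score is the ratio of summed components, not a mean
        g1 = [0] * 10 + [2] * 10
        g2 = [0, 1] * 5 + [0, 1] * 5
        vs = _vs_from_counts([g1, g2])
        w = [Window("chr1", 0, 1000)]
        s = windowed_fst(vs, np.arange(10), np.arange(10, 20), w)[0]
        a1 = per_site_fst_components((10, 0, 0), (0, 0, 10))
        a2 = per_site_fst_components((5, 5, 0), (5, 5, 0))
        expect = (a1[0] + a2[0]) / (sum(a1) + sum(a2))
        assert s.score == pytest.approx(expect, abs=1e-12)

    def test_all_fixed_differences_score_one(self):
        vs = _vs_from_counts([[0] * 8 + [2] * 8] * 5)
        w = [Window("chr1", 0, 1000)]
        scores = windowed_fst(vs, np.arange(8), np.arange(8, 16), w)
        assert scores[0].score == pytest.approx(1.0)
        assert scores[0].window.n_sites == 5


class TestOmega:
    def test_zero_when_frequencies_match(self):
        p = np.random.default_rng(0).uniform(0.05, 0.95, 200)
        assert estimate_omega(p, p) == 0.0

    def test_moment_recovery(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, 5000)
        q = np.clip(p + rng.normal(0, np.sqrt(0.02 * p * (1 - p))), 0, 1)
        est = estimate_omega(p, q)
        assert abs(est - 0.02) < 0.004

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, 500)
        q = rng.uniform(0.1, 0.9, 500)
        assert estimate_omega(p, q) == pytest.approx(
            estimate_omega(1 - p, 1 - q))

    def test_too_few_sites(self):
        with pytest.raises(ValueError):
            estimate_omega(np.full(10, 0.5), np.full(10, 0.5))


class TestXpclr:
    def test_grid_must_contain_zero(self):
        with pytest.raises(ValueError):
            SweepGrid(s_values=np.array([0.1, 0.2]))

    def test_binomial_null_gives_zero_clr(self):
        rng = np.random.default_rng(3)
        L = 100
        p_ref = rng.uniform(0.05, 0.95, L)
        n = np.full(L, 74.0)
        k = rng.binomial(74, p_ref).astype(float)
        pos = np.sort(rng.integers(0, 50_000, L))
        omega = max(estimate_omega(p_ref, k / n), 1e-6)
        clr, s_hat = xpclr_window(pos, p_ref, k, n, SweepGrid(omega=omega),
                                  25_000.0)
        assert clr <= 1e-6

    def test_full_escape_equals_neutral_likelihood(self):
        """With escape probability 1 the sweep model reduces to the null."""
        from hybridscan.scan import _binom_pmf_nodes, _mixture_loglik

        rng = np.random.default_rng(4)
        p = rng.uniform(0.2, 0.8, 20)
        k = rng.binomial(40, p).astype(float)
        n = np.full(20, 40.0)
        quad_x = (np.arange(512) + 0.5) / 512
        pmf = _binom_pmf_nodes(k, n, quad_x)
        var = np.maximum(0.05 * p * (1 - p), 1e-6)
        l0 = _mixture_loglik(k, n, p[:, None], var[:, None],
                             np.ones((20, 1)), quad_x, 1 / 512, pmf)
        c = np.ones(20)
        lik_s = c * np.exp(l0) + (1 - c) * 0.0
        assert np.allclose(np.log(lik_s), l0, atol=1e-12)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(5)
        L = 60
        p_ref = rng.uniform(0.1, 0.9, L)
        n = np.full(L, 60.0)
        k = rng.binomial(60, np.clip(p_ref + 0.3, 0, 1)).astype(float)
        pos = np.sort(rng.integers(0, 50_000, L))
        grid = SweepGrid(omega=0.05)
        clr1, _ = xpclr_window(pos, p_ref, k, n, grid, 25_000.0)
        clr2, _ = xpclr_window(pos, 1 - p_ref, n - k, n, grid, 25_000.0)
        assert clr1 == pytest.approx(clr2, rel=1e-6, abs=1e-9)

    def test_sweep_configuration_scores_high(self):
        """Near-fixed object frequencies at linked sites yield CLR >> 0."""
        rng = np.random.default_rng(6)
        L = 60
        p_ref = rng.uniform(0.2, 0.8, L)
        n = np.full(L, 74.0)
        k = np.where(rng.random(L) < p_ref, n, 0.0)  # swept to extremes
        pos = np.sort(rng.integers(0, 50_000, L))
        grid = SweepGrid(omega=0.05)
        clr, s_hat = xpclr_window(pos, p_ref, k, n, grid, 25_000.0)
        assert clr > 10 and s_hat > 0


class TestOutliers:
    def test_top_five_percent_of_100(self):
        scores = [type("S", (), {"score": float(i), "window": None})()
                  for i in range(100)]
        out, thr = outlier_windows(scores)
        assert len(out) >= 5

    def test_all_equal_returns_everything(self):
        scores = [type("S", (), {"score": 1.0, "window": None})()
                  for _ in range(10)]
        out, thr = outlier_windows(scores)
        assert len(out) == 10

    def test_percentile_convention_1_to_1000(self):
        scores = [type("S", (), {"score": float(i), "window": None})()
                  for i in range(1, 1001)]
        out, thr = outlier_windows(scores)
        assert 950 < thr <= 951
        assert len(out) == 50

    def test_empty_scores_raise(self):
        with pytest.raises(ValueError):
            outlier_windows([])


class TestAnnotation:
    def test_overlap_and_half_open_boundary(self):
        w = [Window("chr1", 0, 50_000)]
        inside = GeneModel("gin", "chr1", "+", 10_000, 20_000,
                           exons=[(10_000, 20_000)])
        abutting = GeneModel("gab", "chr1", "+", 50_000, 60_000,
                             exons=[(50_000, 60_000)])
        per_window, uniq = annotate_windows(w, [inside, abutting])
        assert uniq == ["gin"]
        assert per_window[w[0]] == ["gin"]

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(7)
        windows = [Window("chr1", s, s + 50_000)
                   for s in range(0, 500_000, 25_000)][:3]
        genes = []
        for i in range(50):
            start = int(rng.integers(0, 600_000))
            genes.append(GeneModel(f"g{i}", "chr1", "+", start, start + 3000,
                                   exons=[(start, start + 3000)]))
        _, uniq = annotate_windows(windows, genes)
        brute = [g.gene_id for g in genes
                 if any(g.start < w.end and g.end > w.start for w in windows)]
        assert set(uniq) == set(brute)

    def test_unknown_chromosome_warns_not_raises(self, caplog):
        w = [Window("chr1", 0, 1000)]
        g = GeneModel("g9", "chr9", "+", 0, 100, exons=[(0, 100)])
        _, uniq = annotate_windows(w, [g])
        assert uniq == []


class TestOverlapPercent:
    def test_identical_sets(self):
        out = gene_overlap_percent({"a", "b"}, {"a", "b"})
        assert out == {"pct_of_a": 100.0, "pct_of_b": 100.0, "jaccard": 100.0}

    def test_disjoint_sets(self):
        out = gene_overlap_percent({"a"}, {"b"})
        assert (out["pct_of_a"], out["pct_of_b"], out["jaccard"]) == (0, 0, 0)

    def test_asymmetric_denominators(self):
        a = set(range(10))
        b = set(range(5))
        out = gene_overlap_percent(a, b)
        assert out["pct_of_a"] == pytest.approx(50.0)
        assert out["pct_of_b"] == pytest.approx(100.0)
        assert out["jaccard"] == pytest.approx(50.0)

    def test_both_empty_undefined(self):
        out = gene_overlap_percent(set(), set())
        assert all(math.isnan(v) for v in out.values())
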