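"""Meta-profiles, domain tests, Pol II classes, per-gene tests, categories."""

import numpy as np
import pytest
from scipy import stats

from tilechip.config import PipelineConfig
from tilechip.core_io import GeneModel, Interval, IntervalSet, ValidationError
from tilechip.profiles import (GeneTestResult, InsufficientDataError,
                               anchored_profile, boundary_anchors,
                               chromatin_change_class, classify_polII,
                               domain_signal_test, fold_category, region_test,
                               smooth_profile, tss_anchors)
from tilechip.simulate import simulate_annotation, simulate_chip_tracks
from conftest import make_track


def naive_profile(positions, values, anchor, strand, span, window, stat, flip):
    """Direct per-position recomputation for one anchor."""
    rel = [(anchor - p if (flip and strand == "-") else p - anchor, v)
           for p, v in zip(positions, values)]
    lo_off, hi_off = -(window // 2), (window - 1) // 2
    out = []
    for q in range(span[0], span[1] + 1):
        vals = [v for r, v in rel if q + lo_off <= r <= q + hi_off]
        out.append(np.median(vals) if vals else np.nan)
    return np.array(out)


class TestAnchoredProfile:
    def test_constant_track_gives_constant_aggregate(self):
        t = make_track(np.arange(0, 3000, 33), np.full(91, 4.2))
        prof = anchored_profile(t, [("chr1", 1500, "+")], (-500, 500),
                                window=10, stat="mean")
        covered = ~np.isnan(prof.aggregate)
        assert covered.any()
        assert np.allclose(prof.aggregate[covered], 4.2)

    def test_matches_naive_recomputation(self, rng):
        pos = np.sort(rng.choice(5000, size=120, replace=False))
        vals = rng.normal(size=120)
        t = make_track(pos, vals)
        anchors = [("chr1", 2000, "+"), ("chr1", 3000, "-")]
        prof = anchored_profile(t, anchors, (-800, 800), window=25,
                                stat="median")
        for row, (chrom, a, s) in zip(prof.matrix, anchors):
            expect = naive_profile(pos, vals, a, s, (-800, 800), 25,
                                   "median", True)
            assert np.allclose(row, expect, equal_nan=True)

    def test_coordinate_reflection_symmetry(self, rng):
        """Mirroring the genome and flipping strands leaves the flipped
        TSS-anchored aggregate unchanged."""
        L = 10_000
        pos = np.sort(rng.choice(L - 50, size=150, replace=False))
        vals = rng.normal(size=150)
        t_fwd = make_track(pos, vals)
        mirror_pos = (L - 1) - pos[::-1]
        t_rev = make_track(mirror_pos, vals[::-1])
        anchor = 4000
        p_fwd = anchored_profile(t_fwd, [("chr1", anchor, "+")],
                                 (-1000, 1000), window=15)
        p_rev = anchored_profile(t_rev, [("chr1", (L - 1) - anchor, "-")],
                                 (-1000, 1000), window=15)
        assert np.allclose(p_fwd.aggregate, p_rev.aggregate, equal_nan=True)

    def test_identical_anchors_equal_single_anchor(self, rng):
        pos = np.arange(0, 6000, 33)
        vals = rng.normal(size=pos.size)
        t = make_track(pos, vals)
        one = anchored_profile(t, [("chr1", 3000, "+")], (-400, 400))
        many = anchored_profile(t, [("chr1", 3000, "+")] * 5, (-400, 400))
        assert np.allclose(one.aggregate, many.aggregate, equal_nan=True)

    def test_triangular_signal_peaks_at_anchor(self):
        pos = np.arange(0, 4000, 33)
        anchor = 2013                     # a probe position
        vals = 10.0 - np.abs(pos - anchor) / 200.0
        t = make_track(pos, vals)
        prof = anchored_profile(t, [("chr1", anchor, "+")], (-900, 900),
                                window=10, stat="mean")
        # relative position 0 attains the maximum (the 10 bp window makes
        # every position whose window holds only the apex probe tie with it)
        assert prof.aggregate[900] == np.nanmax(prof.aggregate)

    def test_inverted_span_rejected(self):
        t = make_track([0, 33], [1.0, 2.0])
        with pytest.raises(ValidationError):
            anchored_profile(t, [("chr1", 0, "+")], (100, -100))

    def test_boundary_anchors_point_into_domain(self):
        anchors = boundary_anchors(IntervalSet([Interval("chr1", 100, 500)]))
        assert anchors == [("chr1", 100, "+"), ("chr1", 499, "-")]


class TestSmoothProfile:
    def test_constant_curve_unchanged(self):
        c = np.full(50, 3.3)
        assert np.allclose(smooth_profile(c, 900), c)

    def test_unit_impulse_window_3(self):
        c = np.zeros(9)
        c[4] = 1.0
        out = smooth_profile(c, 3)
        assert np.allclose(out[3:6], [1 / 3, 1 / 3, 1 / 3])
        assert np.allclose(out[[0, 1, 2, 6, 7, 8]], 0)

    def test_matches_direct_recomputation(self, rng):
        c = rng.normal(size=200)
        for window in (1, 3, 10, 51):
            out = smooth_profile(c, window)
            lo_off, hi_off = -(window // 2), (window - 1) // 2
            expect = np.array([
                c[max(0, i + lo_off):min(c.size, i + hi_off + 1)].mean()
                for i in range(c.size)])
            assert np.allclose(out, expect)


class TestDomainSignalTest:
    def _tracks(self, delta, noise, rng, n=400):
        pos = np.arange(0, n * 33, 33)
        base = rng.normal(0, noise, size=n) if noise else np.zeros(n)
        ctrl = make_track(pos, 2.0 + base)
        mut_noise = rng.normal(0, noise, size=n) if noise else np.zeros(n)
        mut = make_track(pos, 2.0 - delta + mut_noise, condition="mutant")
        return ctrl, mut

    def test_identical_signal_no_difference(self, rng):
        pos = np.arange(0, 3300, 33)
        vals = rng.normal(size=100)
        ctrl = make_track(pos, vals)
        mut = make_track(pos, vals, condition="mutant")
        domains = IntervalSet([Interval("chr1", 0, 3300)])
        mc, mm, t, p = domain_signal_test(ctrl, mut, domains)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_pure_shift_recovers_delta(self, rng):
        ctrl, mut = self._tracks(delta=0.7, noise=0.0, rng=rng)
        domains = IntervalSet([Interval("chr1", 0, 100_000)])
        mc, mm, t, p = domain_signal_test(ctrl, mut, domains)
        assert mc - mm == pytest.approx(0.7)

    def test_too_few_probes_raises(self):
        ctrl = make_track([0], [1.0])
        mut = make_track([0], [1.0], condition="mutant")
        with pytest.raises(InsufficientDataError):
            domain_signal_test(ctrl, mut, IntervalSet([Interval("chr1", 0, 50)]))

    def test_simulated_depletion_detected(self):
        """Half-depleted 2-unit plateaus at noise 0.3: p < 1e-6, control higher."""
        for seed in range(5):
            genome, genes, truth = simulate_annotation(seed=seed, n_genes=10,
                                                       chrom_len=300_000)
            tracks = simulate_chip_tracks(
                genome, genes, truth, domain_depletion=0.5,
                domain_plateau=2.0, noise_sd=0.3, seed=seed + 77)
            mc, mm, t, p = domain_signal_test(
                tracks[("h3k27", "control")], tracks[("h3k27", "mutant")],
                IntervalSet(d.interval for d in truth.domains))
            assert p < 1e-6 and mc > mm


class TestClassifyPolII:
    def _gene(self, gid="g", length=3000, strand="+", start=5000):
        return GeneModel(gid, "chr1", strand, start, start + length)

    def test_short_gene_excluded(self):
        pos = np.arange(0, 20_000, 33)
        ctrl = make_track(pos, np.ones(pos.size))
        mut = make_track(pos, np.zeros(pos.size), condition="mutant")
        res = classify_polII(ctrl, mut, [self._gene(length=999)])
        assert res[0].category == "excluded"
        assert "short" in res[0].reason

    def test_exact_tie_excluded(self):
        pos = np.arange(0, 20_000, 33)
        vals = np.linspace(0, 1, pos.size)
        ctrl = make_track(pos, vals)
        mut = make_track(pos, vals, condition="mutant")
        res = classify_polII(ctrl, mut, [self._gene()])
        assert res[0].category == "excluded"
        assert "tie" in res[0].reason

    def test_direction_sets_category(self):
        pos = np.arange(0, 20_000, 33)
        ctrl = make_track(pos, np.full(pos.size, 1.0))
        lower = make_track(pos, np.full(pos.size, 0.5), condition="mutant")
        higher = make_track(pos, np.full(pos.size, 1.5), condition="mutant")
        g = self._gene()
        assert classify_polII(ctrl, lower, [g])[0].category == 1
        assert classify_polII(ctrl, higher, [g])[0].category == 2

    def test_minus_strand_paused_region_oriented(self):
        """Signal only over the minus gene's paused region drives the call."""
        g = GeneModel("g", "chr1", "-", 5000, 9000)      # TSS 8999
        pos = np.arange(0, 12_000, 33)
        ctrl_vals = np.zeros(pos.size)
        sel = (pos >= 8699) & (pos <= 9029)               # TSS-300 .. TSS+30
        ctrl_vals[sel] = 2.0
        ctrl = make_track(pos, ctrl_vals)
        mut = make_track(pos, ctrl_vals * 0.25, condition="mutant")
        res = classify_polII(ctrl, mut, [g])
        assert res[0].category == 1
        assert res[0].paused_ctrl == pytest.approx(2.0)

    def test_planted_regimes_recovered(self):
        """>= 95% of planted regime-1 and regime-2 genes recovered at low noise."""
        correct = {1: 0, 2: 0}
        total = {1: 0, 2: 0}
        for seed in range(20):
            genome, genes, truth = simulate_annotation(seed=seed)
            tracks = simulate_chip_tracks(genome, genes, truth,
                                          noise_sd=0.1, seed=seed + 31)
            res = classify_polII(tracks[("polii", "control")],
                                 tracks[("polii", "mutant")], genes)
            for r in res:
                regime = truth.polII_regime[r.gene_id]
                total[regime] += 1
                correct[regime] += (r.category == regime)
        for regime in (1, 2):
            assert correct[regime] / total[regime] >= 0.95, \
                f"regime {regime}: {correct[regime]}/{total[regime]}"


class TestRegionTest:
    def test_identical_conditions_all_null(self, rng):
        _, genes, _ = simulate_annotation(seed=3)
        pos = np.arange(0, 300_000, 33)
        vals = rng.normal(size=pos.size)
        ctrl = make_track(pos, vals)
        mut = make_track(pos, vals, condition="mutant")
        genes1 = [g for g in genes if g.chrom == "chr1"]
        res = region_test(ctrl, mut, genes1, region="k27_interval",
                          test="mannwhitney")
        assert res and all(r.p == pytest.approx(1.0) for r in res)
        assert sum(r.q < 0.05 for r in res) == 0

    def test_mannwhitney_exact_small_sample(self):
        u, p = stats.mannwhitneyu([1, 2, 3], [4, 5, 6],
                                  alternative="two-sided", method="exact")
        from tilechip.profiles import _mannwhitney_p
        got_u, got_p = _mannwhitney_p(np.array([1., 2, 3]), np.array([4., 5, 6]))
        assert got_p == pytest.approx(0.1)      # 2/20 orderings as extreme
        assert (got_u, got_p) == (u, p)

    def test_bh_step_up_hand_example(self):
        from statsmodels.stats.multitest import multipletests
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, 0.04)

    def test_type_one_error_under_global_null(self):
        """q < 0.05 rate stays at or below 0.05 over ~200 null genes."""
        sig = 0
        tested = 0
        for seed in range(4):
            genome, genes, truth = simulate_annotation(seed=seed)
            rng = np.random.default_rng(seed + 900)
            pos = {c: np.arange(0, genome[c], 33) for c in genome.chroms}
            from tilechip.core_io import ProbeTrack
            ctrl = ProbeTrack(50, [("control", 1)], {
                c: (p, rng.normal(size=(p.size, 1))) for c, p in pos.items()})
            mut = ProbeTrack(50, [("mutant", 1)], {
                c: (p, rng.normal(size=(p.size, 1))) for c, p in pos.items()})
            res = region_test(ctrl, mut, genes, region="k27_interval",
                              test="ttest")
            sig += sum(r.q < 0.05 for r in res)
            tested += len(res)
        assert tested >= 200
        assert sig / tested <= 0.05

    def test_directional_shift_detected_with_direction(self, rng):
        _, genes, _ = simulate_annotation(seed=6)
        pos = np.arange(0, 300_000, 33)
        ctrl = make_track(pos, rng.normal(2.0, 0.1, size=pos.size))
        mut = make_track(pos, rng.normal(1.0, 0.1, size=pos.size),
                         condition="mutant")
        genes1 = [g for g in genes if g.chrom == "chr1"]
        res = region_test(ctrl, mut, genes1, region="k27_interval",
                          test="ttest")
        assert all(r.direction == "down" for r in res)
        assert all(r.q < 0.05 for r in res)


class TestCategories:
    @pytest.mark.parametrize("fold,expect", [
        (1.99, "none"), (2.0, "moderate"), (3.0, "moderate"), (5.0, "moderate"),
        (5.01, "high"), (10.0, "high"), (10.5, "maximal"),
    ])
    def test_fold_category_boundaries(self, fold, expect):
        assert fold_category(fold) == expect

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValidationError):
            fold_category(0.0)

    @pytest.mark.parametrize("q27,d27,q4,d4,expect", [
        (0.01, "down", 0.50, "up", "K27depletedOnly"),
        (0.50, "down", 0.01, "up", "K4enrichedOnly"),
        (0.01, "down", 0.01, "up", "both"),
        (0.50, "down", 0.50, "up", "unchanged"),
        (0.01, "up", 0.01, "down", "unchanged"),   # wrong directions
    ])
    def test_chromatin_change_classes(self, q27, d27, q4, d4, expect):
        k27 = GeneTestResult("g", 0.0, q27, q27, d27)
        k4 = GeneTestResult("g", 0.0, q4, q4, d4)
        assert chromatin_change_class(k27, k4, 0.05) == expect

    def test_mismatched_gene_ids_rejected(self):
        k27 = GeneTestResult("a", 0.0, 0.5, 0.5, "down")
        k4 = GeneTestResult("b", 0.0, 0.5, 0.5, "up")
        with pytest.raises(ValidationError):
            chromatin_change_class(k27, k4)
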