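"""Chi-square testing, p-value adjustment, and DMR calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import medmir as m
from medmir.errors import InputError
from medmir.reads import SiteCountTrack
from tests.test_regions import make_annotation


def textbook_chi2(a, b, c, d):
    """Sum((O-E)^2 / E) over the four cells of [[a,b],[c,d]]."""
    n = a + b + c + d
    chi2 = 0.0
    for obs, rt, ct in [(a, a + b, a + c), (b, a + b, b + d),
                        (c, c + d, a + c), (d, c + d, b + d)]:
        e = rt * ct / n
        chi2 += (obs - e) ** 2 / e
    return chi2


class TestChi2CountsTest:
    def test_identical_proportions(self):
        chi2, p, fc = m.chi2_counts_test(10, 1000, 10, 1000)
        assert chi2 == 0.0 and p == 1.0 and fc == 1.0

    def test_zero_counts_degenerate(self):
        chi2, p, fc = m.chi2_counts_test(0, 100, 0, 100)
        assert chi2 == 0.0 and p == 1.0 and fc == 1.0

    def test_matches_textbook_formula(self):
        chi2, p, _ = m.chi2_counts_test(10, 1000, 30, 1000)
        expect = textbook_chi2(10, 990, 30, 970)
        assert chi2 == pytest.approx(expect, rel=1e-12)
        assert p == pytest.approx(sps.chi2.sf(expect, 1), rel=1e-12)

    def test_random_tables_against_oracles(self, rng):
        """Random 2x2 tables: agreement with both the explicit textbook sum
        and scipy's uncorrected chi2_contingency, to 1e-10 relative error."""
        for _ in range(200):
            ta, tb = rng.integers(50, 5000, size=2)
            ca = int(rng.integers(1, ta))
            cb = int(rng.integers(1, tb))
            chi2, p, _ = m.chi2_counts_test(ca, int(ta), cb, int(tb))
            expect = textbook_chi2(ca, int(ta) - ca, cb, int(tb) - cb)
            assert chi2 == pytest.approx(expect, rel=1e-10)
            sp_chi2, sp_p, _, _ = sps.chi2_contingency(
                [[ca, int(ta) - ca], [cb, int(tb) - cb]], correction=False
            )
            assert chi2 == pytest.approx(sp_chi2, rel=1e-10)
            assert p == pytest.approx(sp_p, rel=1e-10, abs=1e-300)

    @given(
        st.integers(1, 500), st.integers(501, 2000),
        st.integers(1, 500), st.integers(501, 2000),
    )
    @settings(derandomize=True, max_examples=50)
    def test_group_swap_symmetry(self, ca, ta, cb, tb):
        """Swapping the groups preserves chi2 and p and inverts the fold
        change when totals are equal."""
        chi2_1, p1, fc1 = m.chi2_counts_test(ca, ta, cb, tb)
        chi2_2, p2, fc2 = m.chi2_counts_test(cb, tb, ca, ta)
        assert chi2_1 == pytest.approx(chi2_2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12, abs=1e-300)
        if ta == tb:
            assert fc1 * fc2 == pytest.approx(1.0, rel=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(InputError):
            m.chi2_counts_test(0, 0, 5, 10)

    def test_pseudocount_fold_change(self):
        _, _, fc = m.chi2_counts_test(0, 100, 10, 100)
        assert fc == pytest.approx((11 / 100) / (1 / 100))


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        for method in ("bh", "bonferroni"):
            assert m.adjust_pvalues([0.03], method)[0] == pytest.approx(0.03)

    def test_bh_hand_computed_step_up(self):
        """(0.01,0.02,0.03,0.04): p*m/rank = (.04,.04,.04,.04) after the
        cumulative-minimum step."""
        out = m.adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_bonferroni_scalar_multiply(self):
        assert np.allclose(m.adjust_pvalues([0.3, 0.4], "bonferroni"), [0.6, 0.8])

    def test_bonferroni_caps_at_one(self):
        assert m.adjust_pvalues([0.9, 0.8], "bonferroni").max() == 1.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    @settings(derandomize=True, max_examples=60)
    def test_bh_matches_manual_and_permutation_invariant(self, ps):
        out = m.adjust_pvalues(ps, "bh")
        # manual step-up
        p = np.asarray(ps)
        n = len(p)
        order = np.argsort(p, kind="stable")
        ranked = p[order] * n / np.arange(1, n + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        manual = np.empty(n)
        manual[order] = np.minimum(ranked, 1.0)
        assert np.allclose(out, manual)
        # permutation invariance (up to re-ordering)
        perm = np.random.RandomState(0).permutation(n)
        out_perm = m.adjust_pvalues(p[perm], "bh")
        assert np.allclose(np.sort(out_perm), np.sort(out))

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            m.adjust_pvalues([0.5, 1.5], "bh")


def null_tracks(n_pairs=3, seed=0, depth=40, contig_length=30_000):
    ref, ann = m.generate_reference(seed=seed, contig_length=contig_length,
                                    n_genes=5, n_islands=3)
    profiles, _ = m.generate_methylomes(
        ref, ann, n_pairs=n_pairs, noise_concentration=np.inf, seed=seed + 1
    )
    tracks = m.tracks_from_profiles(profiles, ref, mean_depth=depth, seed=seed + 2)
    labels = {p.sample_id: p.group for p in profiles}
    return ref, ann, tracks, labels


class TestCallRegionDmrs:
    def test_null_discovery_at_most_alpha(self):
        ref, ann, tracks, labels = null_tracks(seed=41)
        regions = m.build_regions(ann, ref)
        mat = m.count_regions(tracks, regions)
        calls = m.call_region_dmrs(mat, labels, alpha=0.05)
        assert len(calls) / len(regions) <= 0.05 + 0.05  # Monte-Carlo slack

    def test_planted_region_recovered(self):
        ref, ann = m.generate_reference(seed=43, contig_length=30_000,
                                        n_genes=5, n_islands=3)
        regions = m.build_regions(ann, ref)
        isl = regions.by_class("CpG-island").iloc[0]
        spec = [m.DmrSpec("contig1", int(isl.start), int(isl.end), 4.0)]
        profiles, _ = m.generate_methylomes(
            ref, ann, n_pairs=3, dmr_spec=spec,
            baseline_beta_params=(2.0, 8.0), seed=44,
        )
        tracks = m.tracks_from_profiles(profiles, ref, mean_depth=50, seed=45)
        labels = {p.sample_id: p.group for p in profiles}
        calls = m.call_region_dmrs(m.count_regions(tracks, regions), labels)
        assert isl.region_id in {c.region_id for c in calls}
        hit = next(c for c in calls if c.region_id == isl.region_id)
        assert hit.direction == "hyper" and hit.fold_change > 1.5

    def test_min_fc_one_is_significance_only(self):
        ref, ann, tracks, labels = null_tracks(seed=46)
        regions = m.build_regions(ann, ref)
        mat = m.count_regions(tracks, regions)
        a = m.call_region_dmrs(mat, labels, min_fc=1.0, alpha=0.5)
        b = m.call_region_dmrs(mat, labels, min_fc=1.0 + 1e-12, alpha=0.5)
        assert {c.region_id for c in a} == {c.region_id for c in b}

    def test_zero_library_total_rejected(self):
        ref, ann, tracks, labels = null_tracks(seed=47)
        for t in tracks:
            if labels[t.sample_id] == "primary":
                t.library_total = 0
                for c in t.sites:
                    t.sites[c] = (t.sites[c][0], np.zeros_like(t.sites[c][1]))
        regions = m.build_regions(ann, ref)
        with pytest.raises(InputError):
            m.call_region_dmrs(m.count_regions(tracks, regions), labels)


class TestSlidingWindowDmrs:
    def test_planted_dmr_recovered_with_span(self):
        """One 20-site fold-4 interval at deep coverage: a single called DMR
        covers >=80% of the planted span."""
        ref, ann = m.generate_reference(seed=51, contig_length=40_000,
                                        n_genes=5, n_islands=3)
        sites = ref.cpg_sites["contig1"]
        lo, hi = int(sites[300]), int(sites[319]) + 2
        spec = [m.DmrSpec("contig1", lo, hi, 4.0)]
        profiles, _ = m.generate_methylomes(
            ref, ann, n_pairs=4, dmr_spec=spec,
            baseline_beta_params=(2.0, 8.0), seed=52,
        )
        tracks = m.tracks_from_profiles(profiles, ref, mean_depth=150, seed=53)
        labels = {p.sample_id: p.group for p in profiles}
        calls = m.sliding_window_dmrs(tracks, labels, min_sites=4, max_gap=2)
        cover = [
            (max(0, min(c.end, hi) - max(c.start, lo))) / (hi - lo) for c in calls
        ]
        assert max(cover, default=0.0) >= 0.8
        best = calls[int(np.argmax(cover))]
        assert best.direction == "hyper"
        assert best.n_sites >= 15

    def test_null_tracks_yield_no_dmrs(self):
        _, _, tracks, labels = null_tracks(seed=54)
        assert m.sliding_window_dmrs(tracks, labels, min_sites=4) == []

    def test_empty_tracks_give_empty_result(self):
        assert m.sliding_window_dmrs([], {}) == []

    def test_opposite_directions_never_merge(self):
        """Two adjacent significant sites with opposite direction form two
        single-site bins."""
        pos = np.array([100, 150], dtype=np.int64)
        t_a = SiteCountTrack("a.1", {"c": (pos, np.array([200, 5]))}, 10_000)
        t_b = SiteCountTrack("b.2", {"c": (pos, np.array([5, 200]))}, 10_000)
        labels = {"a.1": "primary", "b.2": "recurrent"}
        calls = m.sliding_window_dmrs(
            [t_a, t_b], labels, min_sites=1, min_size_bp=1, min_fc=1.0, max_gap=0
        )
        assert len(calls) == 2
        assert {c.direction for c in calls} == {"hyper", "hypo"}

    def test_tight_settings_partition_significant_sites(self):
        """max_gap=0 with all minimum thresholds at 1: every significant site
        belongs to exactly one reported DMR."""
        ref, ann = m.generate_reference(seed=55, contig_length=30_000,
                                        n_genes=4, n_islands=2)
        sites = ref.cpg_sites["contig1"]
        spec = [
            m.DmrSpec("contig1", int(sites[50]), int(sites[64]) + 2, 4.0),
            m.DmrSpec("contig1", int(sites[200]), int(sites[214]) + 2, 0.25),
        ]
        profiles, _ = m.generate_methylomes(
            ref, ann, n_pairs=3, dmr_spec=spec,
            baseline_beta_params=(2.0, 8.0), seed=56,
        )
        tracks = m.tracks_from_profiles(profiles, ref, mean_depth=100, seed=57)
        labels = {p.sample_id: p.group for p in profiles}
        alpha, method = 0.05, "bh"
        calls = m.sliding_window_dmrs(
            tracks, labels, alpha=alpha, method=method,
            min_sites=1, min_size_bp=1, min_fc=1.0, max_gap=0,
        )
        # recompute per-site significance independently
        from medmir.dmr import _pooled_site_table, chi2_counts_test
        contigs, pa, pb, ta, tb = _pooled_site_table(tracks, labels)
        stats = [
            chi2_counts_test(int(pa[c][i]), ta, int(pb[c][i]), tb)
            for c in contigs for i in range(len(contigs[c]))
        ]
        padj = m.adjust_pvalues([s[1] for s in stats], method)
        flat_pos = [
            (c, int(contigs[c][i])) for c in contigs for i in range(len(contigs[c]))
        ]
        sig = [
            pos for (c, pos), (chi2, p, fc), q in zip(flat_pos, stats, padj)
            if q < alpha and fc != 1.0
        ]
        covered = 0
        for pos in sig:
            n_in = sum(1 for c in calls if c.start <= pos < c.end)
            assert n_in == 1
            covered += 1
        assert covered == len(sig) > 0

    def test_alpha_monotonicity(self, paired_tracks):
        """Raising alpha never reduces the number of significant sites, hence
        total significant-site mass in DMRs is monotone."""
        tracks, labels, _ = paired_tracks
        totals = []
        for alpha in (0.01, 0.05, 0.2):
            calls = m.sliding_window_dmrs(
                tracks, labels, alpha=alpha, min_sites=1, min_size_bp=1,
                min_fc=1.0, max_gap=0,
            )
            totals.append(sum(c.n_sites for c in calls))
        assert totals == sorted(totals)


class TestAnnotateDmrs:
    def make_dmr(self, contig, start, end):
        return m.DMR(contig, start, end, 1, 2.0, 5.0, 0.01, 0.02, "bh", "hyper")

    def test_dmr_inside_tss_region(self):
        rs = m.build_regions(make_annotation([("g", "c", "+", 5000, 9000)]))
        d = self.make_dmr("c", 4500, 4600)
        out = m.annotate_dmrs([d], rs)
        assert ("TSS", "g") in out[0].overlaps

    def test_touching_endpoint_is_not_overlap(self):
        rs = m.build_regions(make_annotation([], [("isl", "c", 100, 400)]))
        d = self.make_dmr("c", 400, 500)  # starts exactly at island end
        assert m.annotate_dmrs([d], rs)[0].overlaps == []

    def test_matches_brute_force_intersection(self, rng):
        genes = [("g1", "c", "+", 3000, 8000), ("g2", "c", "-", 16000, 11000)]
        islands = [("i1", "c", 2500, 3500), ("i2", "c", 12_000, 12_400)]
        rs = m.build_regions(make_annotation(genes, islands))
        dmrs = []
        for _ in range(50):
            s = int(rng.integers(0, 19_000))
            dmrs.append(self.make_dmr("c", s, s + int(rng.integers(10, 900))))
        out = m.annotate_dmrs(dmrs, rs)
        for d in out:
            brute = sorted(
                {
                    (r.region_class, str(r.parent))
                    for _, r in rs.regions.iterrows()
                    if max(d.start, r.start) < min(d.end, r.end)
                }
            )
            assert d.overlaps == brute
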