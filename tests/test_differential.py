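import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from enhancerkit import SimulationConfig, simulate_chip
from enhancerkit.differential import (
    RegionStats,
    annotate_nearest_tss,
    cluster_regions,
    compute_region_stats,
    correlate_marks,
    filter_differential_peaks,
    find_inverse_regions,
)
from enhancerkit.io import GenomicRegion, RegionSet, TSSAnnotation
from enhancerkit.signal import SignalMatrix, extract_signal_matrix, quantile_normalize


def make_stats(width, mean1, mean2):
    region = GenomicRegion("chr1", 1000, 1000 + width)
    return RegionStats.from_means(region, mean1, mean2)


class TestFilterDifferentialPeaks:
    def test_worked_up_example(self):
        # FC = (1200+1)/(800+1) ~ 1.4995 > 1.3 and width/intensity pass
        up, down = filter_differential_peaks([make_stats(2500, 800, 1200)])
        assert len(up) == 1 and len(down) == 0
        assert up[0].score == pytest.approx(1201 / 801)

    def test_width_gate(self):
        up, down = filter_differential_peaks([make_stats(1500, 5000, 10_000)])
        assert len(up) == 0 and len(down) == 0

    def test_worked_down_example(self):
        # FC = 1401/2001 ~ 0.700 < 0.75
        up, down = filter_differential_peaks([make_stats(3000, 2000, 1400)])
        assert len(down) == 1 and len(up) == 0

    def test_intensity_max_keeps_silenced_peaks(self):
        # silenced in condition 2: mean2 tiny but mean1 > 1000 still callable
        up, down = filter_differential_peaks([make_stats(3000, 4000, 10)])
        assert len(down) == 1
        up, down = filter_differential_peaks(
            [make_stats(3000, 4000, 10)], intensity_mode="mean"
        )
        assert len(down) == 1  # mean of means 2005 > 1000 too

    def test_matches_exhaustive_oracle(self, rng):
        stats = [
            make_stats(
                int(rng.integers(500, 8000)),
                float(rng.uniform(0, 5000)),
                float(rng.uniform(0, 5000)),
            )
            for _ in range(1000)
        ]
        up, down = filter_differential_peaks(stats)
        up_ids, down_ids = {id(r) for r in up}, {id(r) for r in down}
        n_up = n_down = 0
        for st in stats:
            fc = (st.mean2 + 1) / (st.mean1 + 1)
            passes = st.width > 2000 and max(st.mean1, st.mean2) > 1000
            n_up += passes and fc > 1.3
            n_down += passes and fc < 0.75
        assert len(up) == n_up and len(down) == n_down
        # and the actual membership matches, not just the counts
        called_up = {
            (s.region.start, s.region.end) for s in stats
            if s.width > 2000 and max(s.mean1, s.mean2) > 1000 and s.fold_change > 1.3
        }
        assert {(r.start, r.end) for r in up} == called_up

    def test_monotone_in_fc_threshold(self, rng):
        stats = [
            make_stats(3000, float(rng.uniform(0, 4000)), float(rng.uniform(0, 4000)))
            for _ in range(300)
        ]
        sizes = [
            len(filter_differential_peaks(stats, fc_up=t)[0])
            for t in (1.1, 1.3, 1.5, 2.0, 3.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_monotone_in_width_and_intensity(self, rng):
        stats = [
            make_stats(
                int(rng.integers(500, 8000)),
                float(rng.uniform(0, 5000)),
                float(rng.uniform(0, 5000)),
            )
            for _ in range(300)
        ]
        by_width = [
            sum(map(len, filter_differential_peaks(stats, min_width_bp=w)))
            for w in (1000, 2000, 4000)
        ]
        by_int = [
            sum(map(len, filter_differential_peaks(stats, min_intensity=i)))
            for i in (500, 1000, 2000)
        ]
        assert by_width == sorted(by_width, reverse=True)
        assert by_int == sorted(by_int, reverse=True)


def _qnormed_matrix(chip):
    m = extract_signal_matrix(chip.tracks, chip.peaks)
    return quantile_normalize(m)


class TestClusterRegions:
    def test_noiseless_identical_conditions_all_common(self):
        cfg = SimulationConfig(seed=3, noise_cv=0.0, n_common=30, n_up=0, n_down=0)
        chip = simulate_chip(cfg)
        q = _qnormed_matrix(chip)
        res = cluster_regions(
            q,
            chip.condition_samples["sensitive"],
            chip.condition_samples["resistant"],
            k=3,
        )
        assert set(res.region_labels) == {"common"}

    def test_same_seed_identical_assignment(self, default_chip):
        q = _qnormed_matrix(default_chip)
        c1 = default_chip.condition_samples["sensitive"]
        c2 = default_chip.condition_samples["resistant"]
        a = cluster_regions(q, c1, c2, k=3, seed=42)
        b = cluster_regions(q, c1, c2, k=3, seed=42)
        np.testing.assert_array_equal(a.cluster_id, b.cluster_id)

    def test_planted_clusters_recovered(self, default_chip):
        """ARI vs planted truth on regions above the 2 kb size filter."""
        q = _qnormed_matrix(default_chip)
        res = cluster_regions(
            q,
            default_chip.condition_samples["sensitive"],
            default_chip.condition_samples["resistant"],
            k=3,
            seed=0,
        )
        eligible = np.array([r.width > 2000 for r in default_chip.peaks])
        truth = np.array(default_chip.truth.region_labels)
        ari = adjusted_rand_score(truth[eligible], res.cluster_id[eligible])
        assert ari >= 0.95

    def test_k_larger_than_regions_rejected(self, default_chip):
        q = _qnormed_matrix(default_chip)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_regions(
                q,
                default_chip.condition_samples["sensitive"],
                default_chip.condition_samples["resistant"],
                k=10_000,
            )


class TestAnnotateNearestTss:
    def test_midpoint_at_tss_distance_zero(self):
        regions = RegionSet([GenomicRegion("chr1", 4000, 6000)])  # midpoint 5000
        tss = TSSAnnotation([("geneA", "chr1", 5000, "+")])
        (hit,) = annotate_nearest_tss(regions, tss)
        assert hit.gene == "geneA" and hit.distance == 0

    def test_nearest_wins(self):
        regions = RegionSet([GenomicRegion("chr1", 4000, 6000)])
        tss = TSSAnnotation(
            [("geneA", "chr1", 4000, "+"), ("geneB", "chr1", 20_000, "+")]
        )
        (hit,) = annotate_nearest_tss(regions, tss)
        assert (hit.gene, hit.distance) == ("geneA", 1000)

    def test_minus_strand_sign_flip(self):
        regions = RegionSet([GenomicRegion("chr1", 4000, 6000)])
        tss = TSSAnnotation([("geneA", "chr1", 6000, "-")])
        (hit,) = annotate_nearest_tss(regions, tss)
        assert hit.distance == 1000  # upstream in genome coords = downstream of gene

    def test_tie_broken_by_gene_name(self):
        regions = RegionSet([GenomicRegion("chr1", 4000, 6000)])
        tss = TSSAnnotation(
            [("zz", "chr1", 4500, "+"), ("aa", "chr1", 5500, "+")]
        )
        (hit,) = annotate_nearest_tss(regions, tss)
        assert hit.gene == "aa"

    def test_chrom_without_tss_flagged(self):
        regions = RegionSet([GenomicRegion("chrZ", 0, 100)])
        tss = TSSAnnotation([("geneA", "chr1", 5000, "+")])
        (hit,) = annotate_nearest_tss(regions, tss)
        assert not hit.assigned and hit.distance is None

    def test_matches_brute_force(self, rng):
        regions = RegionSet(
            [
                GenomicRegion("chr1", int(s), int(s) + 500)
                for s in rng.integers(0, 200_000, size=40)
            ]
        )
        entries = [
            (f"g{i:03d}", "chr1", int(p), "+" if i % 2 else "-")
            for i, p in enumerate(rng.integers(1, 200_000, size=60))
        ]
        tss = TSSAnnotation(entries)
        hits = annotate_nearest_tss(regions, tss)
        for region, hit in zip(regions, hits):
            mid = (region.start + region.end) // 2
            best = min(entries, key=lambda e: (abs(mid - e[2]), e[0]))
            assert hit.gene == best[0]
            expected = mid - best[2]
            if best[3] == "-":
                expected = -expected
            assert hit.distance == expected


def _matrix_from_values(values):
    n = values.shape[0]
    regions = RegionSet(
        [GenomicRegion("chr1", 10_000 * i + 5000, 10_000 * i + 7000) for i in range(n)]
    )
    return SignalMatrix(values, regions, ["s1"], 1000, 100)


class TestCorrelateMarks:
    def test_self_correlation_is_one(self, rng):
        v = rng.uniform(0, 10, size=(20, 10, 1))
        res = correlate_marks(_matrix_from_values(v), _matrix_from_values(v.copy()))
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_negated_correlation_is_minus_one(self, rng):
        v = rng.uniform(0, 10, size=(20, 10, 1))
        res = correlate_marks(_matrix_from_values(v), _matrix_from_values(-v + 20))
        assert res.pearson_r == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        va = rng.uniform(0, 10, size=(20, 10, 1))
        vb = rng.uniform(0, 10, size=(20, 10, 1))
        res = correlate_marks(_matrix_from_values(va), _matrix_from_values(vb))
        a, b = va.mean(axis=(1, 2)), vb.mean(axis=(1, 2))
        r = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert res.pearson_r == pytest.approx(r, abs=1e-12)
        assert res.n == 20

    def test_too_few_regions_rejected(self, rng):
        v = rng.uniform(size=(2, 10, 1))
        with pytest.raises(ValueError, match="3 regions"):
            correlate_marks(_matrix_from_values(v), _matrix_from_values(v))


def _rs(intervals, label=""):
    return RegionSet(
        [GenomicRegion("chr1", s, e, name=f"{s}-{e}", score=1.0) for s, e in intervals],
        label=label,
    )


class TestFindInverseRegions:
    def test_exact_match_semantics(self):
        up_a = _rs([(0, 100), (200, 300)])
        down_b = _rs([(200, 300), (400, 500)])
        res = find_inverse_regions((up_a, _rs([])), (_rs([]), down_b))
        assert [(a.start, b.start) for a, b in res.up_down] == [(200, 200)]
        assert res.down_up == []

    def test_disjoint_coordinates_empty(self):
        res = find_inverse_regions(
            (_rs([(0, 10)]), _rs([(20, 30)])),
            (_rs([(40, 50)]), _rs([(60, 70)])),
        )
        assert res.n_up_down == 0 and res.n_down_up == 0

    def test_matches_all_pairs_oracle(self, rng):
        def random_set(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 5000))
                out.append((s, s + int(rng.integers(1, 400))))
            return _rs(out)

        up_a, down_a = random_set(50), random_set(50)
        up_b, down_b = random_set(50), random_set(50)
        res = find_inverse_regions((up_a, down_a), (up_b, down_b))

        def oracle(sa, sb):
            return {
                (a.start, a.end, b.start, b.end)
                for a in sa
                for b in sb
                if a.start < b.end and b.start < a.end
            }

        got_ud = {(a.start, a.end, b.start, b.end) for a, b in res.up_down}
        got_du = {(a.start, a.end, b.start, b.end) for a, b in res.down_up}
        assert got_ud == oracle(up_a, down_b)
        assert got_du == oracle(down_a, up_b)

    def test_reciprocal_fraction_threshold(self):
        # 10 bp overlap of a 100 bp and a 1000 bp region: fractions 0.1, 0.01
        up_a = _rs([(0, 100)])
        down_b = _rs([(90, 1090)])
        assert find_inverse_regions((up_a, _rs([])), (_rs([]), down_b)).n_up_down == 1
        res = find_inverse_regions(
            (up_a, _rs([])), (_rs([]), down_b), min_overlap_frac=0.05
        )
        assert res.n_up_down == 0

    def test_fold_changes_carried(self):
        up_a = RegionSet([GenomicRegion("chr1", 0, 100, score=2.5)])
        down_b = RegionSet([GenomicRegion("chr1", 50, 150, score=0.4)])
        res = find_inverse_regions((up_a, _rs([])), (_rs([]), down_b))
        (a, b), = res.up_down
        assert (a.score, b.score) == (2.5, 0.4)


def test_planted_truth_recovery_sensitivity_precision(default_chip):
    """Filter recovers planted up/down classes among size-eligible peaks."""
    q = _qnormed_matrix(default_chip)
    stats = compute_region_stats(
        q,
        default_chip.condition_samples["sensitive"],
        default_chip.condition_samples["resistant"],
    )
    up, down = filter_differential_peaks(stats)
    truth = default_chip.truth.region_labels
    for label, called in (("up", up), ("down", down)):
        true_names = {
            r.name
            for r, t in zip(default_chip.peaks, truth)
            if t == label and r.width > 2000
        }
        called_names = {r.name for r in called}
        tp = len(true_names & called_names)
        assert tp / len(true_names) >= 0.9  # sensitivity
        assert tp / len(called_names) >= 0.9  # precision
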