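import numpy as np
import pytest

from squigmeth import evaluation as E
from squigmeth.types import AnnotationTrack, SiteRecord, WgbsRecord


def wgbs(pos, n_meth, n_unmeth, contig="c"):
    return WgbsRecord(contig=contig, position=pos, n_meth=n_meth, n_unmeth=n_unmeth)


def site(pos, cov, n_mod, contig="c", strand="+"):
    return SiteRecord(contig=contig, position=pos, strand=strand, coverage=cov, n_mod=n_mod)


def track(label, intervals, strands=None, contig="c"):
    t = AnnotationTrack(label=label)
    t.intervals[contig] = np.asarray(intervals, dtype=np.int64)
    t.strands[contig] = strands or ["."] * len(intervals)
    return t


class TestFilterTruth:
    def test_lower_bound_is_at_least_five(self):
        # coverage distribution with P5 = 3: lower bound must still be 5
        records = [wgbs(i, c, 0) for i, c in enumerate([3] * 10 + [20] * 90)]
        kept = E.filter_truth(records, E.EvalConfig(), "classification")
        assert all(r.coverage >= 5 for r in kept)
        assert len(kept) == 90

    def test_partial_sites_excluded_for_classification_only(self):
        records = [wgbs(0, 10, 10), wgbs(1, 20, 0), wgbs(2, 0, 20)]
        classification = E.filter_truth(records, E.EvalConfig(), "classification")
        correlation = E.filter_truth(records, E.EvalConfig(), "correlation")
        assert [r.position for r in classification] == [1, 2]
        assert [r.position for r in correlation] == [0, 1, 2]

    def test_correlation_upper_bound_p95(self):
        covs = list(range(10, 110))  # P95 (nearest rank) = 104
        records = [wgbs(i, c, 0) for i, c in enumerate(covs)]
        kept = E.filter_truth(records, E.EvalConfig(), "correlation")
        assert max(r.coverage for r in kept) == 104

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(10_000):
            cov = int(rng.integers(0, 60))
            meth = int(rng.integers(0, cov + 1)) if cov else 0
            records.append(wgbs(i, meth, cov - meth))
        config = E.EvalConfig()
        kept = E.filter_truth(records, config, "classification")
        covs = np.sort([r.coverage for r in records if r.coverage > 0])
        p5 = covs[max(1, int(np.ceil(0.05 * len(covs)))) - 1]
        lower = max(p5, 5)
        expected = [
            r for r in records
            if r.coverage >= lower and not (0.01 < r.frequency < 0.99)
        ]
        assert [r.position for r in kept] == [r.position for r in expected]

    def test_empty_input(self):
        assert E.filter_truth([], E.EvalConfig()) == []


class TestConfusionMetrics:
    def test_closed_form_example(self):
        # TP=2, FP=1, TN=1, FN=0
        scores = np.array([0.9, 0.8, 0.7, 0.2])
        labels = np.array([1, 1, 0, 0])
        m = E.confusion_metrics(scores, labels)
        assert (m.counts.tp, m.counts.fp, m.counts.tn, m.counts.fn) == (2, 1, 1, 0)
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(1.0)
        assert m.accuracy == pytest.approx(3 / 4)
        assert m.fpr == pytest.approx(1 / 2)
        assert m.f1 == pytest.approx(4 / 5)

    def test_perfect_ranking_has_unit_average_precision(self):
        scores = np.array([0.9, 0.8, 0.3, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert E.confusion_metrics(scores, labels).average_precision == pytest.approx(1.0)

    def test_average_precision_matches_ranked_sweep(self):
        rng = np.random.default_rng(1)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        m = E.confusion_metrics(scores, labels)
        # brute-force sweep: AP = sum (R_k - R_{k-1}) P_k over descending scores
        order = np.argsort(-scores, kind="stable")
        y = labels[order]
        tp = np.cumsum(y)
        precision = tp / (np.arange(200) + 1)
        recall = tp / y.sum()
        ap = precision[0] * recall[0] + np.sum((recall[1:] - recall[:-1]) * precision[1:])
        assert m.average_precision == pytest.approx(ap, abs=1e-10)

    def test_f1_harmonic_identity_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            scores = rng.random(50)
            labels = rng.integers(0, 2, 50)
            m = E.confusion_metrics(scores, labels)
            c = m.counts
            assert m.accuracy == pytest.approx((c.tp + c.tn) / c.total)
            if not np.isnan(m.precision) and m.precision + m.recall > 0:
                assert m.f1 == pytest.approx(
                    2 * m.precision * m.recall / (m.precision + m.recall)
                )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            E.confusion_metrics(np.array([]), np.array([]))

    def test_perfect_caller_recovery(self):
        labels = np.array([1, 0] * 25)
        m = E.confusion_metrics(labels.astype(float), labels)
        assert m.accuracy == m.recall == m.f1 == 1.0
        assert m.fpr == 0.0


class TestAnnotateContexts:
    def test_promoter_beats_exon(self):
        tracks = {
            "tss": track("tss", [[5000, 5001]]),
            "exon": track("exon", [[4000, 7000]]),
            "gene": track("gene", [[3000, 9000]]),
        }
        (ctx,) = E.annotate_contexts([site(6000, 10, 5)], tracks, None)
        assert ctx["genic"] == "promoter"

    def test_intron_is_gene_minus_exon(self):
        tracks = {
            "tss": track("tss", [[0, 1]]),
            "exon": track("exon", [[4000, 5000]]),
            "gene": track("gene", [[3000, 9000]]),
        }
        (a, b, c) = E.annotate_contexts(
            [site(4500, 10, 5), site(8000, 10, 5), site(20000, 10, 5)], tracks, None
        )
        assert a["genic"] == "exon"
        assert b["genic"] == "intron"
        assert c["genic"] == "intergenic"

    def test_island_shore_shelf_geometry(self):
        tracks = {"island": track("island", [[10000, 10800]])}
        positions = {
            10400: "island",
            9999: "shore",   # [8000, 10000)
            8000: "shore",
            10800: "shore",  # [10800, 12800)
            12799: "shore",
            7999: "shelf",   # [6000, 8000)
            12800: "shelf",
            14799: "shelf",
            14800: "open_sea",
            5999: "open_sea",
        }
        ctxs = E.annotate_contexts(
            [site(p, 10, 5) for p in positions], tracks, None
        )
        for (p, expected), ctx in zip(positions.items(), ctxs):
            assert ctx["island_zone"] == expected, p

    def test_gc_bucket_of_five_base_window(self):
        reference = {"c": "ACGTA"}
        (ctx,) = E.annotate_contexts([site(2, 10, 5)], {}, reference)
        assert ctx["gc_bucket"] == 40

    def test_singleton_rule(self):
        #            0123456789012345678901234567890
        reference = {"c": "AAAAAAAAAACGAAAAAAAAAAAAACGAAAA"}
        # CG at 10 and at 25: distance 15 > 10 -> both singletons
        (a,) = E.annotate_contexts([site(10, 10, 5)], {}, reference)
        assert a["singleton"] is True
        reference2 = {"c": "AAAAAAAAAACGAAACGAAAAAAAAAAAAAA"}
        # CG at 10 and 15: within 10 bp -> not singleton
        (b,) = E.annotate_contexts([site(10, 10, 5)], {}, reference2)
        assert b["singleton"] is False

    def test_repeat_priority_order(self):
        tracks = {
            "LINE": track("LINE", [[100, 200]]),
            "SINE": track("SINE", [[150, 250]]),
        }
        (ctx,) = E.annotate_contexts([site(160, 10, 5)], tracks, None)
        assert ctx["repeat"] == "SINE"

    def test_missing_tracks_marked_unavailable(self):
        (ctx,) = E.annotate_contexts([site(5, 10, 5)], {}, None)
        assert ctx["genic"] is None
        assert ctx["island_zone"] is None
        assert ctx["gc_bucket"] is None


class TestCorrelation:
    def test_identical_frequencies_give_unit_correlation(self):
        rng = np.random.default_rng(3)
        ont, truth = [], []
        for i in range(100):
            meth = int(rng.integers(0, 21))
            ont.append(site(i, 20, meth))
            truth.append(wgbs(i, meth, 20 - meth))
        r, n = E.correlate_sites(ont, truth)
        assert n > 50
        assert r == pytest.approx(1.0)

    def test_anti_correlated(self):
        ont = [site(i, 20, 20 - i % 21) for i in range(100)]
        truth = [wgbs(i, i % 21, 20 - i % 21) for i in range(100)]
        r, _ = E.correlate_sites(ont, truth)
        assert r == pytest.approx(-1.0)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(4)
        ont, truth, x, y = [], [], [], []
        for i in range(1000):
            f = rng.random()
            meth_ont = int(round(f * 20))
            noisy = float(np.clip(f + rng.normal(0, 0.1), 0, 1))
            meth_w = int(round(noisy * 30))
            ont.append(site(i, 20, meth_ont))
            truth.append(wgbs(i, meth_w, 30 - meth_w))
        config = E.EvalConfig()
        kept = {(r.contig, r.position): r.frequency
                for r in E.filter_truth(truth, config, "correlation")}
        for s in ont:
            if s.coverage > 5 and ("c", s.position) in kept:
                x.append(s.frequency)
                y.append(kept[("c", s.position)])
        x, y = np.array(x), np.array(y)
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        r, n = E.correlate_sites(ont, truth)
        assert n == len(x)
        assert r == pytest.approx(expected, abs=1e-12)

    def test_too_few_pairs_undefined(self):
        r, n = E.correlate_sites([site(0, 20, 5)], [wgbs(0, 5, 15)])
        assert np.isnan(r) and n <= 1


class TestTssProfile:
    def test_bin_arithmetic(self):
        anchors = [("c", 1000, "+")]
        sites_ = [site(1000, 10, 10), site(1025, 10, 0), site(974, 10, 10)]
        profile = E.tss_profile(sites_, anchors, bin_size=50)
        assert profile[0] == pytest.approx(1.0)   # pos = P
        assert profile[1] == pytest.approx(0.0)   # offset +25
        assert profile[-1] == pytest.approx(1.0)  # offset -26

    def test_minus_strand_offsets_negated(self):
        anchors = [("c", 1000, "-")]
        profile = E.tss_profile([site(1100, 10, 10)], anchors, bin_size=50)
        assert list(profile) == [-2]  # +100 downstream becomes -100

    def test_coverage_floors(self):
        anchors = [("c", 0, "+")]
        sites_ = [site(10, 2, 2), site(20, 10, 10)]
        truth = [wgbs(20, 1, 1)]  # WGBS coverage 2 < 5
        assert E.tss_profile(sites_, anchors) == {0: 1.0}
        assert E.tss_profile(sites_, anchors, wgbs=truth) == {}

    def test_invalid_bin_size(self):
        with pytest.raises(ValueError):
            E.tss_profile([], [], bin_size=0)


class TestCoverageCcdf:
    def test_worked_example(self):
        ccdf = E.coverage_ccdf(np.array([0, 5, 10, 10]))
        assert ccdf[0] == 1.0
        assert ccdf[5] == pytest.approx(3 / 4)
        assert ccdf[10] == pytest.approx(2 / 4)

    def test_nonincreasing_and_matches_counting(self):
        rng = np.random.default_rng(5)
        covs = rng.integers(0, 30, 500)
        ccdf = E.coverage_ccdf(covs)
        values = [ccdf[c] for c in sorted(ccdf)]
        assert all(a >= b for a, b in zip(values, values[1:]))
        for cov, p in ccdf.items():
            if cov > 0:
                assert p == pytest.approx(np.mean(covs >= cov))
        assert ccdf[0] == 1.0

    def test_strand_specific_coverage(self):
        assert E.strand_specific_coverage(40, 10) == pytest.approx(2.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            E.coverage_ccdf(np.array([]), n_sites=0)


class TestConfidentComparison:
    def test_status_rules(self):
        assert E.site_status(site(0, 5, 3)) == "positive"
        assert E.site_status(site(0, 5, 2)) == "negative"  # exactly 50% -> negative
        assert E.site_status(site(0, 4, 4)) == "uncalled"  # low coverage
        assert E.site_status(None) == "uncalled"

    def test_concordant_positive(self):
        comparison = E.confident_site_comparison(
            [site(0, 5, 3)], [site(0, 10, 6)]
        )
        assert comparison.concordant["positive"] == 1
        assert comparison.total == 1

    def test_unique_and_discordant_with_support(self):
        a = [site(0, 10, 9), site(1, 10, 9), site(2, 10, 0)]
        b = [site(0, 10, 0), site(2, 3, 0)]
        support = [[site(0, 10, 8)]]  # backs A's positive call at site 0
        comparison = E.confident_site_comparison(a, b, support)
        assert comparison.discordant_a_supported == 1
        assert comparison.unique_a["positive"] == 1  # site 1: B absent
        assert comparison.unique_a["negative"] == 1  # site 2: B below coverage
        assert comparison.total == 3

    def test_categories_partition_universe(self):
        rng = np.random.default_rng(6)

        def random_sites(n, seed):
            r = np.random.default_rng(seed)
            out = []
            for i in range(n):
                if r.random() < 0.8:
                    cov = int(r.integers(1, 12))
                    out.append(site(i, cov, int(r.integers(0, cov + 1))))
            return out

        a, b = random_sites(200, 1), random_sites(200, 2)
        support = [random_sites(200, 3)]
        comparison = E.confident_site_comparison(a, b, support)
        universe = {s.position for s in a} | {s.position for s in b}
        assert comparison.total == len(universe)


class TestHighFiltering:
    @pytest.mark.parametrize(
        "overall,valid,expected",
        [
            (10, 4, "missing-due-to-filtering"),
            (20, 17, "high-filtering"),  # 3 filtered > 2 expected
            (20, 19, "ok"),             # 1 filtered <= 2 expected
            (3, 2, "missing-low-overall"),
            (4, 4, "missing-low-overall"),
            (5, 5, "ok"),
        ],
    )
    def test_classification(self, overall, valid, expected):
        assert E.high_filtering_analysis(overall, valid) == expected

    def test_valid_above_overall_rejected(self):
        with pytest.raises(ValueError):
            E.high_filtering_analysis(5, 6)
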