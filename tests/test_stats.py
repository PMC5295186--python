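"""Rank-sum comparisons, frequency profiles and publication summaries."""

import itertools

import numpy as np
import pytest

from pvburden.cohort import CohortVariant
from pvburden.stats import (
    PublicationRecord,
    fraction_below,
    frequency_profile,
    publication_summary,
    rank_sum_test,
    threshold_report,
)


def brute_force_ranksum_p(a, b):
    """Exact two-sided p by enumerating all group labelings (no ties)."""
    combined = sorted(a + b)
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    mean = n_a * len(b) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(combined)), n_a):
        grp_a = [combined[i] for i in idx]
        grp_b = [combined[i] for i in range(len(combined)) if i not in idx]
        u = sum(1 for x in grp_a for y in grp_b if x > y)
        total += 1
        if abs(u - mean) >= abs(u_obs - mean):
            count += 1
    return count / total


class TestRankSum:
    def test_identical_multisets_give_p_one(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_small_sample_matches_enumeration_oracle(self):
        a, b = [1.0, 2.0], [3.0, 4.0]
        res = rank_sum_test(a, b)
        assert res.p_value == pytest.approx(brute_force_ranksum_p(a, b))
        assert res.p_value == pytest.approx(2 / 6)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_path_matches_enumeration_on_random_tie_free_samples(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(1.0, 12.0))
        a, b = list(vals[:5]), list(vals[5:11])
        res = rank_sum_test(a, b)
        assert res.p_value == pytest.approx(brute_force_ranksum_p(a, b))

    @pytest.mark.parametrize("seed", range(10))
    def test_two_sided_p_symmetric_under_sample_swap(self, seed):
        rng = np.random.default_rng(seed)
        a = list(rng.normal(size=30))
        b = list(rng.normal(0.5, size=40))
        assert rank_sum_test(a, b).p_value == pytest.approx(
            rank_sum_test(b, a).p_value
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestFractionBelow:
    def test_printed_ratio(self):
        mafs = [0.0] * 1356 + [1e-4] * 8
        assert fraction_below(mafs, 5e-5) == pytest.approx(1356 / 1364)

    def test_all_zeros_below_any_positive_threshold(self):
        assert fraction_below([0.0] * 10, 1e-9) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_threshold_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        mafs = list(rng.uniform(0, 1e-3, size=50))
        thresholds = sorted(rng.uniform(1e-6, 1e-3, size=5))
        fracs = [fraction_below(mafs, t) for t in thresholds]
        assert fracs == sorted(fracs)
        shuffled = list(rng.permutation(mafs))
        assert fraction_below(shuffled, thresholds[2]) == fracs[2]

    def test_empty_input_is_none_and_bad_threshold_rejected(self):
        assert fraction_below([], 1e-4) is None
        with pytest.raises(ValueError):
            fraction_below([0.0], 0.0)


def cvs(acs, an=121_000):
    return [
        CohortVariant("1", i + 1, "A", "T", ac_adj=ac, an_adj=an, gene="G")
        for i, ac in enumerate(acs)
    ]


class TestFrequencyProfile:
    def test_counts_and_outliers(self):
        profile = frequency_profile(cvs([0, 0, 0, 1, 1, 2, 3, 4, 30]))
        assert profile.n_total == 9
        assert profile.n_absent == 3
        assert profile.n_singleton == 2
        assert len(profile.outliers) == 2
        assert list(profile.outliers.ac_adj) == [30, 4]

    def test_empty_set_degenerates_to_none_fractions(self):
        profile = frequency_profile([])
        assert profile.n_total == 0
        assert all(v is None for v in profile.fraction_below.values())

    def test_fraction_below_monotone_across_thresholds(self):
        profile = frequency_profile(cvs([0, 1, 5, 50, 500]))
        vals = [profile.fraction_below[t] for t in sorted(profile.fraction_below)]
        assert vals == sorted(vals)


class TestThresholdReport:
    def test_conservation_captured_plus_above_equals_total(self):
        variants = cvs([0, 0, 1, 2, 13, 40, 200])
        report = threshold_report(variants)
        assert (report.n_captured + report.n_above == len(variants)).all()

    def test_threshold_above_all_mafs_captures_everything(self):
        variants = cvs([0, 1, 2])
        report = threshold_report(variants, [0.5])
        row = report.iloc[0]
        assert row.n_above == 0
        assert row.captured_percent == 100.0
        assert row.outliers_above == ""

    def test_outliers_are_listed_with_review_flag(self):
        variants = cvs([0, 100])
        report = threshold_report(variants, [1e-4])
        row = report.iloc[0]
        assert row.n_above == 1
        assert "requires literature review" in row.outliers_above


def pubs(pairs, cls="pathogenic"):
    return [
        PublicationRecord("1", i + 1, "A", "T", cls, maf, count)
        for i, (maf, count) in enumerate(pairs)
    ]


class TestPublicationSummary:
    def test_all_zero_counts_median_zero_r_none(self):
        records = pubs([(1e-4, 0), (2e-4, 0), (3e-4, 0)])
        out = publication_summary(records)
        cls = out["classes"]["pathogenic"]
        assert cls["summary"]["median"] == 0.0
        assert cls["r"] is None
        assert cls["n_zero_publications"] == 3

    def test_five_number_summary_matches_numpy_quartiles(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 50, size=40)
        records = pubs([(1e-4, int(c)) for c in counts])
        s = publication_summary(records)["classes"]["pathogenic"]["summary"]
        q1, med, q3 = np.percentile(counts, [25, 50, 75])
        assert (s["q1"], s["median"], s["q3"]) == (q1, med, q3)
        assert (s["min"], s["max"]) == (counts.min(), counts.max())

    def test_planted_linear_dependence_recovered(self):
        rng = np.random.default_rng(4)
        mafs = rng.uniform(1e-4, 1e-2, size=400)
        counts = (5000 * mafs + rng.normal(0, 0.5, size=400)).round().clip(0)
        records = pubs(list(zip(mafs, counts.astype(int))))
        out = publication_summary(records)
        r = out["classes"]["pathogenic"]["r"]
        true_r = np.corrcoef(mafs, counts)[0, 1]
        assert r == pytest.approx(true_r, abs=1e-9)
        assert r > 0.9

    def test_stochastically_larger_pathogenic_counts_detected(self):
        """Pathogenic counts drawn stochastically larger than benign:
        rank-sum p < 0.05 in at least 95% of 200 replicates at n=100/100."""
        rng = np.random.default_rng(5)
        rejections = 0
        for _ in range(200):
            path = pubs(
                [(1e-4, int(c)) for c in rng.poisson(8, size=100)], "pathogenic"
            )
            ben = pubs(
                [(1e-4, int(c)) for c in rng.poisson(5, size=100)], "benign"
            )
            out = publication_summary(path + ben)
            if out["rank_sum_pathogenic_vs_benign"]["p_value"] < 0.05:
                rejections += 1
        assert rejections >= 190

    def test_spearman_option_and_unknown_method_rejected(self):
        records = pubs([(1e-4, 1), (2e-4, 2), (3e-4, 3)])
        out = publication_summary(records, method="spearman")
        assert out["classes"]["pathogenic"]["r"] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            publication_summary(records, method="kendall")
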