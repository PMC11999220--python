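import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from her2seg.core import (
    BACKGROUND,
    ClassDistribution,
    HER2_0,
    HER2_1,
    HER2_2,
    HER2_3,
    LabelMask,
    NONINVASIVE,
    SchemaError,
)
from her2seg.scoring import (
    EXCLUDED,
    MarginPolicy,
    NoInvasiveTissueError,
    ScoringRules,
    calibrated_score,
    her2_ratios,
    her2_score,
    region_report,
    score_to_status,
    score_with_margin,
)


def dist(n0=0, n1=0, n2=0, n3=0, ni=0, bg=0) -> ClassDistribution:
    return ClassDistribution(
        {HER2_0: n0, HER2_1: n1, HER2_2: n2, HER2_3: n3, NONINVASIVE: ni, BACKGROUND: bg}
    )


class TestRatios:
    def test_half_one_plus(self):
        assert her2_ratios(dist(n0=50, n1=50)) == (0.5, 0.0, 0.0)

    def test_twenty_percent_three_plus(self):
        r1, r2, r3 = her2_ratios(dist(n0=80, n3=20))
        assert r3 == r2 == r1 == pytest.approx(0.2)

    def test_matches_bruteforce_cumulative_sums(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 100, 4)
            if counts.sum() == 0:
                counts[0] = 1
            r1, r2, r3 = her2_ratios(dist(*counts))
            n = counts.sum()
            assert r3 == pytest.approx(counts[3] / n)
            assert r2 == pytest.approx((counts[2] + counts[3]) / n)
            assert r1 == pytest.approx((counts[1] + counts[2] + counts[3]) / n)
            assert 1 >= r1 >= r2 >= r3 >= 0

    def test_noninvasive_and_background_excluded(self):
        assert her2_ratios(dist(n1=10, ni=500, bg=1000)) == (1.0, 0.0, 0.0)

    def test_no_invasive_tissue_raises(self):
        with pytest.raises(NoInvasiveTissueError):
            her2_ratios(dist(ni=50, bg=50))


class TestScore:
    def test_fifteen_percent_three_plus(self):
        assert her2_score(dist(n0=85, n3=15)) == 3

    def test_two_plus_rule_uses_cumulative_ratio(self):
        # r3 = 5% fails the 3+ rule; r2 = 12% passes the 2+ rule
        assert her2_score(dist(n0=88, n2=7, n3=5)) == 2

    def test_exact_ten_percent_falls_to_lower_score(self):
        assert her2_score(dist(n0=90, n1=10)) == 0
        assert her2_score(dist(n1=90, n2=10)) == 1
        assert her2_score(dist(n2=90, n3=10)) == 2

    def test_score_invariant_to_noninvasive_and_background(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 50, 4)
            if counts.sum() == 0:
                counts[2] = 5
            base = her2_score(dist(*counts))
            assert her2_score(dist(*counts, ni=int(rng.integers(0, 1000)), bg=777)) == base

    @given(
        n0=st.integers(0, 200),
        n1=st.integers(0, 200),
        n2=st.integers(0, 200),
        n3=st.integers(0, 200),
        upgrades=st.integers(1, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_moving_mass_to_higher_grade_never_lowers_score(self, n0, n1, n2, n3, upgrades):
        if n0 + n1 + n2 + n3 == 0 or n0 == 0:
            return
        before = her2_score(dist(n0, n1, n2, n3))
        moved = min(upgrades, n0)
        after = her2_score(dist(n0 - moved, n1, n2, n3 + moved))
        assert after >= before


class TestCalibration:
    def test_borderline_two_plus_flips_under_calibration(self):
        d = dist(n0=23, n1=70, n2=6, n3=1)  # r2 = 7%, r3 = 1%, r1 = 77%
        assert her2_score(d) == 1
        assert calibrated_score(d) == 2

    def test_below_both_thresholds_stays_one(self):
        d = dist(n0=26, n1=70, n2=4)  # r2 = 4%
        assert her2_score(d) == 1
        assert calibrated_score(d) == 1

    def test_three_plus_untouched_by_calibration(self):
        d = dist(n0=80, n3=20)
        assert her2_score(d) == calibrated_score(d) == 3


class TestMargin:
    def test_ratio_inside_band_is_excluded(self):
        d = dist(n0=89, n2=11)  # r2 = 0.11 in (0.05, 0.15]
        assert score_with_margin(d, policy=MarginPolicy(margin=0.05)) == EXCLUDED

    def test_clear_ratios_scored_normally(self):
        d = dist(n1=55, n2=5, n3=30, n0=10)  # r1=.9, r2=.35, r3=.30
        assert score_with_margin(d, policy=MarginPolicy(margin=0.05)) == 3

    def test_zero_margin_equals_plain_score(self, rng):
        for _ in range(30):
            counts = rng.integers(0, 100, 4)
            if counts.sum() == 0:
                counts[1] = 3
            d = dist(*counts)
            assert score_with_margin(d, policy=MarginPolicy(margin=0.0)) == her2_score(d)

    def test_inclusion_antitone_in_margin(self, rng):
        margins = [0.0, 0.02, 0.05, 0.08]
        dists = []
        for _ in range(100):
            counts = rng.integers(0, 100, 4)
            if counts.sum() == 0:
                counts[1] = 3
            dists.append(dist(*counts))
        included = [
            {i for i, d in enumerate(dists) if score_with_margin(d, policy=MarginPolicy(margin=m)) != EXCLUDED}
            for m in margins
        ]
        for small, large in zip(included[1:], included[:-1]):
            assert small <= large

    def test_one_sided_variant_keeps_below_threshold_cases(self):
        d = dist(n1=91, n2=9)  # r2 = 0.09 < t2, r1 well clear
        assert score_with_margin(d, policy=MarginPolicy(margin=0.05, rule="band")) == EXCLUDED
        assert score_with_margin(d, policy=MarginPolicy(margin=0.05, rule="one_sided")) == 1

    def test_margin_must_stay_below_thresholds(self):
        with pytest.raises(SchemaError):
            score_with_margin(dist(n1=10), policy=MarginPolicy(margin=0.2))


class TestStatus:
    @pytest.mark.parametrize(
        "score,fish,want",
        [
            (0, None, "negative"),
            (1, None, "low"),
            (2, None, "equivocal"),
            (2, True, "positive"),
            (2, False, "low"),
            (3, None, "positive"),
        ],
    )
    def test_mapping(self, score, fish, want):
        assert score_to_status(score, fish) == want


class TestRegionReport:
    def test_pure_three_plus_region(self):
        data = np.zeros((20, 20), dtype=np.uint8)
        data[2:10, 2:10] = HER2_3
        reports = region_report(LabelMask(data), [(2, 2, 8, 8)])
        region = reports[1]
        assert region.ratios[2] == 1.0
        assert region.score == 3

    def test_whole_report_matches_full_distribution_score(self, rng):
        from her2seg.core import class_distribution

        data = rng.integers(0, 6, (30, 30)).astype(np.uint8)
        mask = LabelMask(data)
        reports = region_report(mask)
        assert reports[0].score == her2_score(class_distribution(mask))

    def test_disjoint_regions_counts_are_additive(self, rng):
        data = rng.integers(0, 6, (20, 20)).astype(np.uint8)
        mask = LabelMask(data)
        r = region_report(mask, [(0, 0, 10, 20), (10, 0, 10, 20)])
        whole, top, bottom = r[0], r[1], r[2]
        for c in range(6):
            assert whole.distribution.get(c, 0) == top.distribution.get(c, 0) + bottom.distribution.get(c, 0)

    def test_region_without_invasive_tissue_reports_undefined_score(self):
        data = np.zeros((10, 10), dtype=np.uint8)
        data[0:5] = NONINVASIVE
        data[7, 7] = HER2_1
        reports = region_report(LabelMask(data), [(0, 0, 5, 10)])
        assert reports[1].score is None
        assert reports[1].distribution[NONINVASIVE] == 50
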