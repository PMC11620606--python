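"""Summaries, the gated test battery, rank statistics and sex calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu as scipy_mwu

from odontochron import (
    call_sex,
    cohens_d,
    compare_two_groups,
    count_individual_sexes,
    load_table1,
    mann_whitney_u,
    summarize_parameters,
)
from odontochron.stats import AMELX_MZ, AMELY_MZ, summary_value


@pytest.fixture(scope="module")
def summary(table1_records):
    return summarize_parameters(table1_records)


class TestSummaries:
    def test_fixture_shape(self, table1_records):
        assert len(table1_records) == 34
        assert sum(r.cft_ci_eligible for r in table1_records) == 12
        assert sum(r.cc_excluded for r in table1_records) == 2

    @pytest.mark.parametrize(
        "grouping, group, parameter, mean, n",
        [
            ("overall", "overall", "cft", 386, 12),
            ("overall", "overall", "ci", 172, 12),
            ("overall", "overall", "cc", 208, 32),
            ("arch", "lower", "cc", 231, 18),
            ("arch", "upper", "cc", 179, 14),
            ("sex", "M", "cc", 203, 24),
            ("sex", "F", "cc", 223, 8),
        ],
    )
    def test_group_means(self, summary, grouping, group, parameter, mean, n):
        assert summary_value(summary, grouping, group, parameter) == mean
        assert summary_value(summary, grouping, group, parameter, "n") == n

    def test_dsr_summary(self, summary):
        assert summary_value(summary, "overall", "overall", "dsr") == pytest.approx(3.17, abs=0.005)
        assert summary_value(summary, "overall", "overall", "dsr", "n") == 34

    def test_single_record(self, table1_records):
        s = summarize_parameters(table1_records[:1])
        assert summary_value(s, "overall", "overall", "cft", "mean") == 418
        assert np.isnan(summary_value(s, "overall", "overall", "cft", "sd"))


class TestMannWhitney:
    def test_complete_separation(self):
        u_a, u_b, _ = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert (u_a, u_b) == (0.0, 4.0)

    def test_midranks_against_brute_force(self):
        """U from midranks equals the pair count (ties worth 1/2)."""
        a, b = [1.0, 3.0], [2.0, 2.0]
        u_a, u_b, _ = mann_whitney_u(a, b)
        brute = sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b
        )
        assert u_a == brute == 2.0
        assert u_a + u_b == len(a) * len(b)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=12),
        st.lists(st.integers(0, 8), min_size=1, max_size=12),
    )
    def test_u_identity_and_brute_force_with_ties(self, a, b):
        u_a, u_b, _ = mann_whitney_u(a, b)
        brute = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
        assert u_a == pytest.approx(brute)
        assert u_a + u_b == pytest.approx(len(a) * len(b))

    def test_exact_p_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.normal(0, 1, int(rng.integers(4, 15)))
            b = rng.normal(0.5, 1, int(rng.integers(4, 15)))
            u_a, _, p = mann_whitney_u(a, b)
            ref = scipy_mwu(a, b, method="exact")
            assert u_a == ref.statistic
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_tied_p_matches_scipy_asymptotic(self):
        a = [219.0, 226.0, 226.0, 233.0, 219.0, 224.0]
        b = [193.0, 182.0, 210.0, 226.0, 194.0]
        u_a, _, p = mann_whitney_u(a, b)
        ref = scipy_mwu(a, b, method="asymptotic")
        assert u_a == ref.statistic
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_published_cc_rank_statistic(self, table1_records):
        """Lower vs upper crown-completion ages give U = 247 for the lower arch."""
        lower = [r.cc for r in table1_records
                 if r.arch == "lower" and not r.cc_excluded and r.cc is not None]
        upper = [r.cc for r in table1_records
                 if r.arch == "upper" and not r.cc_excluded and r.cc is not None]
        assert (len(lower), len(upper)) == (18, 14)
        u_lower, u_upper, p = mann_whitney_u(lower, upper)
        assert u_lower == 247.0
        assert u_lower + u_upper == 18 * 14
        assert p < 0.05


class TestGatedComparison:
    def test_identical_groups_not_significant(self):
        a = [200.0, 210.0, 220.0, 230.0, 240.0]
        res = compare_two_groups(a, list(a))
        assert res.p_value > 0.9
        assert res.decision_trace

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_two_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_fixture_reproduces_decision_branches(self, table1_records):
        """Decision families on the bundled table: pooled t for CFT by arch,
        Mann-Whitney for Cc by arch; Ci by sex stays parametric and not
        significant (with only three females the two-sided F-test cannot
        reject homogeneity, so the gate records the variance ratio in its
        trace and the parametric branch decides)."""
        elig = [r for r in table1_records if r.cft_ci_eligible]
        cft_low = [r.cft for r in elig if r.arch == "lower"]
        cft_up = [r.cft for r in elig if r.arch == "upper"]
        res = compare_two_groups(cft_low, cft_up)
        assert res.test_name == "student_t"
        assert res.p_value < 0.05  # arches genuinely differ in CFT

        ci_m = [r.ci for r in elig if r.sex == "M"]
        ci_f = [r.ci for r in elig if r.sex == "F"]
        assert (len(ci_m), len(ci_f)) == (9, 3)
        res = compare_two_groups(ci_m, ci_f)
        assert res.test_name in ("student_t", "welch_t")
        assert any("f_test" in line for line in res.decision_trace)
        assert res.p_value > 0.05  # no sex difference, matching the report

        cc_low = [r.cc for r in table1_records
                  if r.arch == "lower" and not r.cc_excluded and r.cc is not None]
        cc_up = [r.cc for r in table1_records
                 if r.arch == "upper" and not r.cc_excluded and r.cc is not None]
        res = compare_two_groups(cc_low, cc_up)
        assert res.test_name == "mann_whitney"
        assert res.statistic == 247.0


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_unit_effect(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(4000) + 1.0
        b = rng.standard_normal(4000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.05)

    def test_inner_dsr_effect_from_population_moments(self):
        """Prenatal vs postnatal inner-DSR moments give d ~ 0.31."""
        def exact_moment_sample(mean, sd, n, seed):
            z = np.random.default_rng(seed).standard_normal(n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z

        a = exact_moment_sample(3.20, 0.26, 1002, 1)
        b = exact_moment_sample(3.12, 0.25, 853, 2)
        assert cohens_d(a, b) == pytest.approx(0.313, abs=0.005)

    def test_zero_pooled_sd_is_error(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestSexCalls:
    @pytest.mark.parametrize(
        "amelx, amely, expected",
        [(True, True, "male"), (False, True, "male"),
         (True, False, "female"), (False, False, "indeterminate")],
    )
    def test_presence_absence_rule(self, amelx, amely, expected):
        call = call_sex(amelx, amely)
        assert call.call == expected
        assert call.marker_mz == {"AMELX": AMELX_MZ, "AMELY": AMELY_MZ}

    def test_individual_level_counts(self, table1_records):
        counts = count_individual_sexes(table1_records)
        assert counts == {"M": 19, "F": 8, "unknown": 0}
        by_site = {}
        for r in table1_records:
            by_site.setdefault(r.site, []).append(r)
        assert count_individual_sexes(by_site["Casalmoro"]) == {"M": 7, "F": 3, "unknown": 0}
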