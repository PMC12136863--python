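import math
from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from scipy import stats as sps

from dxalo.core import Diagnosis, DomainError, score_patient, Region, Side
from dxalo.stats import (
    build_composition_summary,
    compare_groups_delta_rc,
    fisher_exact_rxc,
    holm_adjust,
    normality_gate,
    one_way_anova,
    paired_t_test,
    predominant_tissue_table,
    unpaired_t_test,
)
from conftest import build_scan


class TestPairedT:
    def test_closed_form_example(self):
        res = paired_t_test([1, 2, 3], [2, 4, 6])
        assert res.statistic == pytest.approx(-3.4641016, abs=1e-6)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.0742, abs=1e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError, match="zero variance"):
            paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_sign_flip_symmetry(self):
        a = paired_t_test([1, 2, 3], [2, 4, 6])
        b = paired_t_test([2, 4, 6], [1, 2, 3])
        assert b.statistic == pytest.approx(-a.statistic)
        assert b.p_value == pytest.approx(a.p_value)

    def test_length_mismatch(self):
        with pytest.raises(DomainError, match="length mismatch"):
            paired_t_test([1, 2], [1, 2, 3])

    def test_equals_one_sample_t_on_differences(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(3, 30)
            x, y = rng.normal(0, 1, n), rng.normal(0.3, 1.5, n)
            mine = paired_t_test(x, y)
            oracle = sps.ttest_1samp(x - y, 0.0)
            assert mine.statistic == pytest.approx(float(oracle.statistic), rel=1e-12)
            assert mine.p_value == pytest.approx(float(oracle.pvalue), rel=1e-12)


class TestUnpairedT:
    def test_identical_groups_null(self):
        res = unpaired_t_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_hand_computation(self):
        # means 2.5 vs 4.5, pooled variance 5/3, se = sqrt(5/3 * 1/2)
        res = unpaired_t_test([1, 2, 3, 4], [3, 4, 5, 6])
        assert res.statistic == pytest.approx(-2.19089, abs=1e-4)
        assert res.df == 6
        assert res.p_value == pytest.approx(0.0708, abs=1e-3)

    def test_both_groups_constant_rejected(self):
        with pytest.raises(DomainError, match="zero variance"):
            unpaired_t_test([0, 0, 0, 0], [1, 1, 1, 1])

    def test_welch_flag(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 8.0])
        b = np.array([1.1, 1.2, 1.3])
        res = unpaired_t_test(a, b, welch=True)
        oracle = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(float(oracle.statistic))
        assert res.test_name == "welch_t"


class TestAnova:
    def test_hand_computed_example(self):
        # SSB = 6, SSW = 6 -> F = (6/2)/(6/6) = 3 with (2, 6) df
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.statistic == pytest.approx(3.0)
        assert res.df == (2.0, 6.0)
        assert res.p_value == pytest.approx(0.125, abs=1e-3)

    def test_identical_groups(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_group_order_invariance(self):
        groups = [[1.0, 2.5, 3.0], [4.0, 5.5], [0.5, 1.5, 2.0, 2.5]]
        f1 = one_way_anova(groups).statistic
        f2 = one_way_anova(groups[::-1]).statistic
        assert f1 == pytest.approx(f2)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = rng.normal(0, 1, int(rng.integers(3, 20)))
            b = rng.normal(0.5, 1, int(rng.integers(3, 20)))
            f = one_way_anova([a, b])
            t = unpaired_t_test(a, b)
            assert f.statistic == pytest.approx(t.statistic**2, rel=1e-10)
            assert f.p_value == pytest.approx(t.p_value, rel=1e-10)

    def test_too_few_groups(self):
        with pytest.raises(DomainError):
            one_way_anova([[1, 2, 3]])


def bruteforce_fisher(table):
    """Independent exact-test oracle: enumerate all tables cell-by-cell.

    Iterates the full product of per-cell ranges, keeps margin-compatible
    tables, and sums exact multivariate hypergeometric probabilities of
    those no more probable than the observed table.
    """
    t = np.asarray(table, dtype=int)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())

    def prob(cells):
        num = 1
        for r in rows:
            num *= math.factorial(int(r))
        for c in cols:
            num *= math.factorial(int(c))
        den = math.factorial(n)
        for v in cells:
            den *= math.factorial(int(v))
        return Fraction(num, den)

    p_obs = prob(t.ravel())
    total = Fraction(0)
    tail = Fraction(0)
    ranges = [range(min(int(rows[i]), int(cols[j])) + 1)
              for i in range(t.shape[0]) for j in range(t.shape[1])]
    for cells in product(*ranges):
        m = np.array(cells).reshape(t.shape)
        if (m.sum(axis=1) == rows).all() and (m.sum(axis=0) == cols).all():
            p = prob(cells)
            total += p
            if p <= p_obs:
                tail += p
    assert total == 1
    return float(tail)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[3, 1], [1, 3]], 34 / 70),
            ([[5, 0], [0, 5]], 2 / 252),
        ],
    )
    def test_enumerated_2x2(self, table, expected):
        assert fisher_exact_rxc(table).p_value == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_2x2(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            t = rng.integers(0, 10, (2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            mine = fisher_exact_rxc(t).p_value
            ref = float(sps.fisher_exact(t)[1])
            assert mine == pytest.approx(ref, abs=1e-9)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            t = rng.integers(0, 8, (2, 3)) + np.eye(2, 3, dtype=int)
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert fisher_exact_rxc(t).p_value == pytest.approx(
                fisher_exact_rxc(t.T).p_value, abs=1e-12
            )

    def test_freeman_halton_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            t = rng.integers(0, 6, (2, 3))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            res = fisher_exact_rxc(t)
            assert res.test_name == "fisher_freeman_halton"
            assert res.p_value == pytest.approx(bruteforce_fisher(t), abs=1e-12)

    def test_freeman_halton_3x3_known_oracle(self):
        t = [[4, 1, 0], [1, 3, 1], [0, 1, 4]]
        assert fisher_exact_rxc(t).p_value == pytest.approx(
            bruteforce_fisher(t), abs=1e-12
        )

    def test_monte_carlo_fallback_close_to_asymptotic(self):
        # Margins too large to enumerate; MC estimate should be
        # reproducible (fixed default seed) and carry a standard error.
        t = np.ones((3, 4), dtype=int) * 40
        t[0, 0] += 25
        res = fisher_exact_rxc(t, max_enumeration=1000, mc_samples=20_000)
        assert res.test_name == "fisher_monte_carlo"
        assert res.mc_standard_error is not None
        res2 = fisher_exact_rxc(t, max_enumeration=1000, mc_samples=20_000)
        assert res.p_value == res2.p_value  # deterministic default seed
        chi2_p = float(sps.chi2_contingency(t)[1])
        assert res.p_value == pytest.approx(chi2_p, abs=0.05)

    def test_invalid_tables_rejected(self):
        with pytest.raises(DomainError):
            fisher_exact_rxc([[1.5, 2], [3, 4]])
        with pytest.raises(DomainError):
            fisher_exact_rxc([[-1, 2], [3, 4]])
        with pytest.raises(DomainError):
            fisher_exact_rxc([[0, 0], [3, 4]])


class TestNormalityGate:
    def test_exact_normal_quantiles_look_normal(self):
        q = sps.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        res = normality_gate(q)
        assert res.statistic > 0.95

    def test_lognormal_flagged(self):
        rng = np.random.default_rng(12)
        x = np.exp(rng.normal(0, 1, 50))
        assert normality_gate(x).p_value < 0.05

    def test_constant_vector_rejected(self):
        with pytest.raises(DomainError, match="zero variance"):
            normality_gate([1.0, 1.0, 1.0, 1.0])

    def test_n_out_of_range(self):
        with pytest.raises(DomainError):
            normality_gate([1.0, 2.0])


class TestHolm:
    def test_monotone_and_bounded(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert all(0 <= p <= 1 for p in adj)
        assert adj[0] == pytest.approx(0.03)


def scored_cohort(spec):
    """Build {pid: (diagnosis, AggregateResult)} from (diag, scale) specs."""
    out = {}
    for i, (diag, thigh_scale) in enumerate(spec):
        scan = build_scan(
            f"P{i}",
            scale={(Region.THIGH, Side.LEFT): thigh_scale},
            clinical={(Region.THIGH, Side.LEFT)},
            diagnosis=diag,
        )
        _, agg = score_patient(scan)
        out[f"P{i}"] = (diag, agg)
    return out


class TestCohortSummaries:
    def test_symmetric_cohort_zero_deltas_flagged(self):
        cohort = scored_cohort([(Diagnosis.PROS, 1.0)] * 4)
        summary = build_composition_summary(cohort)
        s = summary.groups["PROS"]["adipose"]
        assert s.delta_mean == pytest.approx(0.0)
        assert s.paired_p is None
        assert "zero variance" in s.paired_flag

    def test_two_patient_means_match_hand_computation(self):
        # Uniform scaling leaves RC unchanged: deltas are exactly zero,
        # affected mean equals the phantom thigh composition.
        cohort = scored_cohort([(Diagnosis.PROS, 1.2), (Diagnosis.PROS, 1.4)])
        summary = build_composition_summary(cohort)
        thigh_total = 2000.0 + 4700.0 + 300.0
        assert summary.groups["PROS"]["adipose"].affected_mean == pytest.approx(
            2000.0 / thigh_total * 100
        )
        assert summary.n_per_group == {"PROS": 2}

    def test_group_counts_sum_to_cohort(self):
        cohort = scored_cohort(
            [(Diagnosis.PROS, 1.2)] * 3 + [(Diagnosis.BWSP, 1.3)] * 2
        )
        summary = build_composition_summary(cohort)
        assert sum(summary.n_per_group.values()) == len(cohort)

    def test_single_diagnosis_comparison_rejected(self):
        cohort = scored_cohort([(Diagnosis.PROS, 1.2), (Diagnosis.PROS, 1.3)])
        with pytest.raises(DomainError, match="2 groups"):
            compare_groups_delta_rc(cohort)

    def test_predominant_table_counts(self):
        cohort = scored_cohort(
            [(Diagnosis.PROS, 1.2)] * 2 + [(Diagnosis.BWSP, 1.3)] * 2
        )
        counts, diags, tissues, _ = predominant_tissue_table(cohort)
        assert counts.sum() == 4
        assert diags == ["BWSp", "PROS"]
        assert tissues == ["adipose", "muscle", "bone"]
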