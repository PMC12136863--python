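"""Cohort statistics for scored bilateral-composition data.

Implements the battery applied to a scored cohort: paired t-tests of
affected vs contralateral relative composition within patients, pooled
unpaired t-tests and one-way ANOVA of composition discrepancies between
diagnostic subgroups, an exact r x c test of predominant-tissue
prevalence, a Shapiro-Wilk normality annotation, and a subgroup summary
table (mean +/- SD of RC and dRC per tissue).

The parametric tests wrap scipy; the exact contingency test is computed
here with exact rational arithmetic: 2x2 tables by hypergeometric
enumeration, larger tables by complete Freeman-Halton enumeration when
the margin-constrained table space is small enough, and otherwise by
Monte Carlo over the margin-fixed table distribution with a reported
standard error.

No multiple-testing correction is applied by default; a Holm adjustment
helper is provided for users who want one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core import AggregateResult, Diagnosis, DomainError, Tissue

__all__ = [
    "TestResult",
    "CompositionSummary",
    "paired_t_test",
    "unpaired_t_test",
    "one_way_anova",
    "fisher_exact_rxc",
    "normality_gate",
    "build_composition_summary",
    "compare_groups_delta_rc",
    "predominant_tissue_table",
    "holm_adjust",
]

TISSUES = (Tissue.ADIPOSE, Tissue.MUSCLE, Tissue.BONE)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None
    n: tuple[int, ...]
    mc_standard_error: float | None = None
    normality_flag: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise DomainError(f"p-value {self.p_value!r} outside [0, 1]")


def _as_array(x: Sequence[float], name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise DomainError(f"{name} must be 1-dimensional")
    if not np.all(np.isfinite(a)):
        raise DomainError(f"{name} contains non-finite values")
    return a


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired t-test on matched pairs.

    t = mean(d) / (sd(d)/sqrt(n)) on the differences d = x - y, with
    n - 1 degrees of freedom.  Raises on length mismatch or when the
    differences have zero variance (the statistic is undefined).
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if len(xa) != len(ya):
        raise DomainError(f"length mismatch: {len(xa)} vs {len(ya)}")
    if len(xa) < 2:
        raise DomainError("need at least 2 pairs")
    d = xa - ya
    if np.ptp(d) == 0.0:
        raise DomainError("zero variance of differences")
    res = sps.ttest_rel(xa, ya)
    return TestResult(
        test_name="paired_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(len(xa) - 1),
        n=(len(xa),),
    )


def unpaired_t_test(
    a: Sequence[float], b: Sequence[float], *, welch: bool = False
) -> TestResult:
    """Two-sided two-sample t-test, pooled-variance (classic Student) by default.

    Welch's unequal-variance form is available behind ``welch=True``.
    """
    aa, ba = _as_array(a, "a"), _as_array(b, "b")
    if len(aa) < 2 or len(ba) < 2:
        raise DomainError("need at least 2 observations per group")
    if np.ptp(aa) == 0.0 and np.ptp(ba) == 0.0:
        raise DomainError("zero variance in both groups")
    res = sps.ttest_ind(aa, ba, equal_var=not welch)
    if welch:
        df = float(res.df)
        name = "welch_t"
    else:
        df = float(len(aa) + len(ba) - 2)
        name = "student_t"
    return TestResult(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=df,
        n=(len(aa), len(ba)),
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA across k >= 2 groups.

    F = MS_between / MS_within with (k - 1, N - k) degrees of freedom and
    an upper-tail p-value.
    """
    if len(groups) < 2:
        raise DomainError("need at least 2 groups")
    arrays = [_as_array(g, f"group {i}") for i, g in enumerate(groups)]
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise DomainError(f"group {i} has n < 2")
    if all(np.ptp(g) == 0.0 for g in arrays):
        raise DomainError("zero within-group variance overall")
    res = sps.f_oneway(*arrays)
    k = len(arrays)
    n_total = sum(len(g) for g in arrays)
    return TestResult(
        test_name="one_way_anova",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=(float(k - 1), float(n_total - k)),
        n=tuple(len(g) for g in arrays),
    )


# ---------------------------------------------------------------------------
# Exact r x c contingency test


def _validate_table(table: Sequence[Sequence[int]]) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise DomainError("table must have at least 2 rows and 2 columns")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.all(np.equal(np.mod(t, 1), 0)):
            raise DomainError("table cells must be integers")
        t = t.astype(np.int64)
    if np.any(t < 0):
        raise DomainError("table cells must be non-negative")
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        raise DomainError("all row and column margins must be positive")
    return t


def _fisher_2x2_exact(t: np.ndarray) -> Fraction:
    """Exact two-sided 2x2 p by hypergeometric enumeration (rational arithmetic)."""
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {a: math.comb(r1, a) * math.comb(r2, c1 - a) for a in range(lo, hi + 1)}
    w_obs = weights[int(t[0, 0])]
    total = sum(weights.values())
    tail = sum(w for w in weights.values() if w <= w_obs)
    return Fraction(tail, total)


def _enumerate_tables(row_margins: list[int], col_margins: list[int]):
    """Yield every non-negative integer table with the given margins."""

    def rec(row_idx: int, remaining_cols: list[int]):
        if row_idx == len(row_margins) - 1:
            yield [list(remaining_cols)]
            return
        target = row_margins[row_idx]

        def fill(col_idx: int, left: int, row: list[int]):
            if col_idx == len(remaining_cols) - 1:
                if left <= remaining_cols[col_idx]:
                    yield row + [left]
                return
            upper = min(left, remaining_cols[col_idx])
            for v in range(upper + 1):
                yield from fill(col_idx + 1, left - v, row + [v])

        for row in fill(0, target, []):
            rest = [remaining_cols[j] - row[j] for j in range(len(remaining_cols))]
            for tail in rec(row_idx + 1, rest):
                yield [row] + tail

    yield from rec(0, list(col_margins))


def _count_tables(row_margins: list[int], col_margins: list[int], cap: int) -> int:
    """Count margin-compatible tables, stopping once the count exceeds ``cap``."""
    count = 0
    for _ in _enumerate_tables(row_margins, col_margins):
        count += 1
        if count > cap:
            return count
    return count


def _table_weight(cells: list[int]) -> Fraction:
    # Probability of a table under fixed margins is proportional to
    # 1 / prod(cell!); the margin factorials cancel in the tail ratio.
    denom = 1
    for v in cells:
        denom *= math.factorial(v)
    return Fraction(1, denom)


def fisher_exact_rxc(
    table: Sequence[Sequence[int]],
    *,
    max_enumeration: int = 1_000_000,
    mc_samples: int = 200_000,
    mc_seed: int = 20240,
) -> TestResult:
    """Exact test of independence for an r x c count table.

    2x2 tables use the classical hypergeometric two-sided rule (sum the
    probabilities of all tables no more probable than the observed one).
    Larger tables use the Freeman-Halton generalization by complete
    enumeration of the margin-constrained table space when it holds at
    most ``max_enumeration`` tables; beyond that, the p-value is
    estimated by Monte Carlo over the margin-fixed distribution with a
    fixed default seed, and the binomial standard error is reported.
    """
    t = _validate_table(table)
    n = tuple(int(v) for v in t.sum(axis=1))
    if t.shape == (2, 2):
        p = _fisher_2x2_exact(t)
        return TestResult(
            test_name="fisher_exact_2x2",
            statistic=float("nan"),
            p_value=float(p),
            df=None,
            n=n,
        )
    row_margins = [int(v) for v in t.sum(axis=1)]
    col_margins = [int(v) for v in t.sum(axis=0)]
    if _count_tables(row_margins, col_margins, max_enumeration) <= max_enumeration:
        obs_w = _table_weight([int(v) for v in t.ravel()])
        total = Fraction(0)
        tail = Fraction(0)
        for candidate in _enumerate_tables(row_margins, col_margins):
            w = _table_weight([v for row in candidate for v in row])
            total += w
            if w <= obs_w:
                tail += w
        return TestResult(
            test_name="fisher_freeman_halton",
            statistic=float("nan"),
            p_value=float(tail / total),
            df=None,
            n=n,
        )
    # Monte Carlo fallback: sample tables with the observed margins.
    rng = np.random.default_rng(mc_seed)
    dist = sps.random_table(row_margins, col_margins)
    samples = dist.rvs(mc_samples, random_state=rng)
    obs_logw = -sum(math.lgamma(v + 1) for v in t.ravel())
    logw = -np.sum(_lgamma_table(samples), axis=(1, 2))
    hits = int(np.sum(logw <= obs_logw + 1e-9))
    p = (hits + 1) / (mc_samples + 1)
    se = math.sqrt(p * (1 - p) / mc_samples)
    return TestResult(
        test_name="fisher_monte_carlo",
        statistic=float("nan"),
        p_value=p,
        df=None,
        n=n,
        mc_standard_error=se,
    )


def _lgamma_table(samples: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(samples + 1.0)


def normality_gate(x: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality check used to annotate parametric tests.

    The result never switches methods automatically; downstream tests
    carry a warning flag when p < 0.05.  Supported for 3 <= n <= 5000.
    """
    xa = _as_array(x, "x")
    if not (3 <= len(xa) <= 5000):
        raise DomainError(f"Shapiro-Wilk supported for 3 <= n <= 5000, got {len(xa)}")
    if np.ptp(xa) == 0.0:
        raise DomainError("zero variance")
    res = sps.shapiro(xa)
    return TestResult(
        test_name="shapiro_wilk",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=None,
        n=(len(xa),),
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (optional; nothing applies it by default)."""
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(list(p_values), method="holm")[1])


# ---------------------------------------------------------------------------
# Cohort summaries


@dataclass
class GroupTissueSummary:
    affected_mean: float
    affected_sd: float
    contra_mean: float
    contra_sd: float
    delta_mean: float
    delta_sd: float
    paired_p: float | None
    paired_flag: str | None = None


@dataclass
class CompositionSummary:
    """Mean +/- SD of affected RC, contralateral RC and dRC per subgroup.

    ``groups`` maps diagnosis name -> tissue name -> GroupTissueSummary;
    an ``"Total"`` entry pools all patients.  ``n_per_group`` records the
    patient counts; the group counts sum to the cohort size.
    """

    n_per_group: dict[str, int] = field(default_factory=dict)
    groups: dict[str, dict[str, GroupTissueSummary]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {"n": dict(self.n_per_group), "groups": {}}
        for g, tissues in self.groups.items():
            out["groups"][g] = {
                t: {
                    "affected_mean": s.affected_mean,
                    "affected_sd": s.affected_sd,
                    "contra_mean": s.contra_mean,
                    "contra_sd": s.contra_sd,
                    "delta_mean": s.delta_mean,
                    "delta_sd": s.delta_sd,
                    "paired_p": s.paired_p,
                    "paired_flag": s.paired_flag,
                }
                for t, s in tissues.items()
            }
        return out


def _rc_arrays(aggregates: Sequence[AggregateResult], tissue: Tissue):
    idx = TISSUES.index(tissue)
    aff = np.array([a.rc_affected.as_tuple()[idx] for a in aggregates]) * 100.0
    con = np.array([a.rc_contra.as_tuple()[idx] for a in aggregates]) * 100.0
    delta = np.array([a.delta_rc.as_tuple()[idx] for a in aggregates])
    return aff, con, delta


def build_composition_summary(
    scored: dict[str, tuple[Diagnosis, AggregateResult]]
) -> CompositionSummary:
    """Subgroup summary of affected RC, contralateral RC and dRC (percent).

    One row per diagnosis per tissue, plus a pooled "Total" row.  Paired
    t-test p-values (affected vs contralateral RC) are computed where a
    group has n >= 2 and non-degenerate differences; otherwise the entry
    carries a flag instead of a p-value.
    """
    if not scored:
        raise DomainError("empty scored cohort")
    by_group: dict[str, list[AggregateResult]] = {}
    for diagnosis, aggregate in scored.values():
        by_group.setdefault(diagnosis.value, []).append(aggregate)
    summary = CompositionSummary()
    pooled: list[AggregateResult] = [agg for _, agg in scored.values()]
    for name, aggregates in list(by_group.items()) + [("Total", pooled)]:
        if name != "Total":
            summary.n_per_group[name] = len(aggregates)
        summary.groups[name] = {}
        for tissue in TISSUES:
            aff, con, delta = _rc_arrays(aggregates, tissue)
            p: float | None = None
            flag: str | None = None
            if len(aggregates) < 2:
                flag = "n<2"
            else:
                try:
                    test = paired_t_test(aff, con)
                    p = test.p_value
                    if len(delta) >= 3 and np.ptp(delta) > 0:
                        norm = normality_gate(delta)
                        if norm.p_value < 0.05:
                            flag = "non-normal differences (Shapiro-Wilk p < 0.05)"
                except DomainError as exc:
                    flag = str(exc)
            summary.groups[name][tissue.value] = GroupTissueSummary(
                affected_mean=float(aff.mean()),
                affected_sd=float(aff.std(ddof=1)) if len(aff) > 1 else 0.0,
                contra_mean=float(con.mean()),
                contra_sd=float(con.std(ddof=1)) if len(con) > 1 else 0.0,
                delta_mean=float(delta.mean()),
                delta_sd=float(delta.std(ddof=1)) if len(delta) > 1 else 0.0,
                paired_p=p,
                paired_flag=flag,
            )
    return summary


def compare_groups_delta_rc(
    scored: dict[str, tuple[Diagnosis, AggregateResult]]
) -> dict[str, dict]:
    """Between-subgroup comparison of composition discrepancies per tissue.

    For each tissue: a one-way ANOVA across all diagnoses present plus
    every pairwise pooled t-test.  Results are labeled and reported
    without multiplicity adjustment.
    """
    by_group: dict[str, list[AggregateResult]] = {}
    for diagnosis, aggregate in scored.values():
        by_group.setdefault(diagnosis.value, []).append(aggregate)
    groups = {g: a for g, a in by_group.items() if len(a) >= 2}
    if len(groups) < 2:
        raise DomainError("need >= 2 groups with n >= 2")
    names = sorted(groups)
    out: dict[str, dict] = {}
    for tissue in TISSUES:
        deltas = {g: _rc_arrays(groups[g], tissue)[2] for g in names}
        anova = one_way_anova([deltas[g] for g in names])
        pairwise = {}
        for i, g1 in enumerate(names):
            for g2 in names[i + 1 :]:
                try:
                    pairwise[f"{g1} vs {g2}"] = unpaired_t_test(deltas[g1], deltas[g2])
                except DomainError as exc:
                    pairwise[f"{g1} vs {g2}"] = str(exc)
        out[tissue.value] = {"anova": anova, "pairwise": pairwise, "groups": names}
    return out


def predominant_tissue_table(
    scored: dict[str, tuple[Diagnosis, AggregateResult]]
) -> tuple[np.ndarray, list[str], list[str], TestResult | None]:
    """Predominant-tissue x diagnosis count table and its exact test.

    Returns (counts, diagnosis_names, tissue_names, test); the test is
    None when the table is degenerate (a single diagnosis or a single
    observed tissue).
    """
    by_group: dict[str, dict[str, int]] = {}
    for diagnosis, aggregate in scored.values():
        row = by_group.setdefault(diagnosis.value, {t.value: 0 for t in TISSUES})
        row[aggregate.predominant_tissue.value] += 1
    diag_names = sorted(by_group)
    tissue_names = [t.value for t in TISSUES]
    counts = np.array(
        [[by_group[d][t] for t in tissue_names] for d in diag_names], dtype=int
    )
    keep = counts.sum(axis=0) > 0
    trimmed = counts[:, keep]
    test = None
    if trimmed.shape[0] >= 2 and trimmed.shape[1] >= 2:
        test = fisher_exact_rxc(trimmed)
    return counts, diag_names, tissue_names, test
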