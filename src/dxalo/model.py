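"""Study-level modelling interface.

:class:`OvergrowthStudy` is built from a cohort of bilateral regional
scans (from CSV files or in-memory objects); its :meth:`~OvergrowthStudy.fit`
scores every patient and returns an :class:`OvergrowthResults` carrying
the per-region and aggregate discrepancy statistics, the subgroup
composition summary with paired-test p-values, the between-group
comparisons of composition discrepancy, the predominant-tissue
contingency test, and the clinical-concordance report, with a
``summary()`` table rendering the lot.

    >>> study = OvergrowthStudy.simulate(n_patients=46, seed=7)
    >>> results = study.fit()
    >>> print(results.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import concordance as conc
from . import io as io_formats
from . import stats as cohort_stats
from .core import (
    AggregateResult,
    AnalysisConfig,
    Diagnosis,
    DomainError,
    PatientScan,
    RegionPairResult,
    score_patient,
)

__all__ = ["OvergrowthStudy", "OvergrowthResults"]


class OvergrowthStudy:
    """A cohort of bilateral regional DXA scans ready for LO scoring.

    Parameters
    ----------
    scans
        Mapping of patient id to :class:`~dxalo.core.PatientScan`.
    config
        Analysis thresholds; defaults to the 10% call threshold with a
        5-point near-threshold band.
    """

    def __init__(
        self,
        scans: dict[str, PatientScan],
        config: AnalysisConfig | None = None,
    ) -> None:
        if not scans:
            raise DomainError("empty cohort")
        self.scans = scans
        self.config = config or AnalysisConfig()

    @classmethod
    def from_csv(
        cls,
        scans_path: Path | str,
        labels_path: Path | str | None = None,
        config: AnalysisConfig | None = None,
        column_map: dict[str, str] | None = None,
    ) -> "OvergrowthStudy":
        """Build a study from ``scans.csv`` and (optionally) ``labels.csv``."""
        scans = io_formats.read_scans(scans_path, column_map)
        if labels_path is not None:
            io_formats.read_labels(labels_path, scans, column_map)
        return cls(scans, config)

    @classmethod
    def simulate(
        cls,
        n_patients: int = 46,
        seed: int = 0,
        config: AnalysisConfig | None = None,
        generator_config=None,
    ) -> "OvergrowthStudy":
        """Build a study from the synthetic cohort generator."""
        from .simulate import default_config, simulate_cohort

        gen = generator_config or default_config(n_patients=n_patients, seed=seed)
        scans, _ = simulate_cohort(gen)
        return cls(scans, config)

    def fit(self) -> "OvergrowthResults":
        """Score every patient and assemble cohort-level statistics."""
        scored: dict[str, tuple[list[RegionPairResult], AggregateResult | None]] = {}
        for pid in sorted(self.scans):
            scored[pid] = score_patient(self.scans[pid], self.config)
        return OvergrowthResults(study=self, scored=scored)


@dataclass
class OvergrowthResults:
    """Fitted cohort results.

    Attributes are computed lazily where they need labeled patients; a
    cohort without clinical labels still exposes per-region results.
    """

    study: OvergrowthStudy
    scored: dict[str, tuple[list[RegionPairResult], AggregateResult | None]]
    _summary_cache: cohort_stats.CompositionSummary | None = field(
        default=None, repr=False
    )

    # -- tabular views -----------------------------------------------------

    @property
    def region_results(self) -> pd.DataFrame:
        """One row per scored (patient, region) pair."""
        rows = []
        for pid, (per_region, _) in self.scored.items():
            for r in per_region:
                rows.append(
                    {
                        "patient_id": pid,
                        "region": r.region.value,
                        "affected_side": r.affected_side.value,
                        "anchor": r.anchor,
                        "mt_affected_g": r.mt_affected_g,
                        "mt_contra_g": r.mt_contra_g,
                        "discrepancy_ratio": r.discrepancy_ratio,
                        "delta_rc_adipose_pp": r.delta_rc.d_adipose,
                        "delta_rc_muscle_pp": r.delta_rc.d_muscle,
                        "delta_rc_bone_pp": r.delta_rc.d_bone,
                        "lo_call": r.lo_call,
                    }
                )
        return pd.DataFrame(rows)

    @property
    def aggregate_results(self) -> dict[str, AggregateResult]:
        """Per-patient affected-aggregate results (labeled patients only)."""
        return {
            pid: agg for pid, (_, agg) in self.scored.items() if agg is not None
        }

    def _labeled(self) -> dict[str, tuple[Diagnosis, AggregateResult]]:
        out = {}
        for pid, agg in self.aggregate_results.items():
            out[pid] = (self.study.scans[pid].diagnosis, agg)
        if not out:
            raise DomainError("no patients with clinical labels; nothing to summarize")
        return out

    # -- cohort statistics -------------------------------------------------

    def composition_summary(self) -> cohort_stats.CompositionSummary:
        """Subgroup mean +/- SD of affected RC, contralateral RC and dRC."""
        if self._summary_cache is None:
            self._summary_cache = cohort_stats.build_composition_summary(
                self._labeled()
            )
        return self._summary_cache

    def group_comparisons(self) -> dict[str, dict]:
        """Per-tissue ANOVA + pairwise t-tests of dRC between subgroups."""
        return cohort_stats.compare_groups_delta_rc(self._labeled())

    def predominant_tissue_test(self):
        """Predominant-tissue x diagnosis counts and exact test."""
        return cohort_stats.predominant_tissue_table(self._labeled())

    def concordance(self, per_region: bool = False) -> conc.ConcordanceReport:
        """Clinical-vs-DXA agreement report."""
        return conc.cohort_concordance(
            self.study.scans, self.study.config, per_region=per_region
        )

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Human-readable cohort summary table.

        Renders the subgroup composition summary in ``mean +/- SD``
        style with 1-decimal percentages, followed by the between-group
        comparisons when at least two subgroups are present.  Rounding
        is applied at display time only.
        """
        lines: list[str] = []
        lines.append("Lateralized overgrowth cohort summary")
        lines.append("=" * 72)
        try:
            summary = self.composition_summary()
        except DomainError as exc:
            lines.append(f"(no cohort summary: {exc})")
            return "\n".join(lines)
        n_total = sum(summary.n_per_group.values())
        lines.append(
            "n = "
            + ", ".join(f"{g}: {n}" for g, n in sorted(summary.n_per_group.items()))
            + f" (total {n_total})"
        )
        header = (
            f"{'group':<8}{'tissue':<9}{'RC affected':>16}{'RC contralateral':>19}"
            f"{'dRC (pp)':>15}{'paired p':>10}"
        )
        lines.append(header)
        lines.append("-" * len(header))
        order = [g for g in ("PROS", "BWSp", "ILO", "other") if g in summary.groups]
        order += [g for g in summary.groups if g not in order and g != "Total"]
        order.append("Total")
        for group in order:
            for tissue in ("adipose", "muscle", "bone"):
                s = summary.groups[group][tissue]
                p = f"{s.paired_p:.3f}" if s.paired_p is not None else "-"
                lines.append(
                    f"{group:<8}{tissue:<9}"
                    f"{s.affected_mean:>7.1f}% ± {s.affected_sd:>4.1f}%"
                    f"{s.contra_mean:>10.1f}% ± {s.contra_sd:>4.1f}%"
                    f"{s.delta_mean:>8.1f} ± {s.delta_sd:>4.1f}"
                    f"{p:>10}"
                )
        try:
            comparisons = self.group_comparisons()
        except DomainError as exc:
            lines.append("")
            lines.append(f"(between-group comparisons omitted: {exc})")
            return "\n".join(lines)
        lines.append("")
        lines.append("Between-group comparison of dRC (one-way ANOVA + pairwise t)")
        for tissue, block in comparisons.items():
            anova = block["anova"]
            lines.append(
                f"  dRC {tissue}: F({anova.df[0]:.0f}, {anova.df[1]:.0f}) = "
                f"{anova.statistic:.2f}, p = {anova.p_value:.4f}"
            )
            for pair, res in block["pairwise"].items():
                if isinstance(res, str):
                    lines.append(f"    {pair}: ({res})")
                else:
                    lines.append(
                        f"    {pair}: t = {res.statistic:.2f}, p = {res.p_value:.4f}"
                    )
        return "\n".join(lines)

    def plot_delta_rc(self, ax=None):
        """Dot plot of per-patient dRC by tissue and subgroup."""
        import matplotlib.pyplot as plt
        import numpy as np

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        labeled = self._labeled()
        groups = sorted({d.value for d, _ in labeled.values()})
        tissues = ("adipose", "muscle", "bone")
        rng = np.random.default_rng(0)
        for ti, tissue in enumerate(tissues):
            for gi, group in enumerate(groups):
                values = [
                    agg.delta_rc.as_tuple()[ti]
                    for d, agg in labeled.values()
                    if d.value == group
                ]
                x = ti * (len(groups) + 1) + gi
                ax.scatter(
                    x + rng.uniform(-0.15, 0.15, len(values)),
                    values,
                    s=12,
                    alpha=0.6,
                    label=group if ti == 0 else None,
                )
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xticks(
            [ti * (len(groups) + 1) + (len(groups) - 1) / 2 for ti in range(3)]
        )
        ax.set_xticklabels([f"dRC {t}" for t in tissues])
        ax.set_ylabel("percentage points")
        ax.legend(frameon=False, fontsize=8)
        return ax
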