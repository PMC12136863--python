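"""Agreement between clinical LO labels and DXA-derived LO calls.

Clinical overgrowth is typically reported at limb level, so agreement is
evaluated on pooled region groups by default: upper limb (arm + forearm
+ hand), lower limb (thigh + leg + foot), hemihead and hemipelvis, each
per side.  Per-region granularity is available behind a flag.

For every group the two sides are summed, the discrepancy ratio is
computed with each side as candidate-affected, and the LO call is made
on the heavier side's ratio.  A patient is concordant when every
clinically labeled group is DXA-called on the same side.  Two kinds of
side findings are reported alongside the rate:

* ``near_threshold`` — a clinically labeled group whose ratio fell just
  short of the call threshold (within the configured band);
* ``dxa_only`` — a group called LO by DXA with no clinical label, the
  "clinically overlooked" finding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import (
    AnalysisConfig,
    DomainError,
    PatientScan,
    Region,
    Side,
    aggregate_regions,
    call_lo,
    mt_discrepancy_ratio,
)

__all__ = [
    "REGION_GROUPS",
    "GroupCall",
    "ConcordanceDetail",
    "ConcordanceReport",
    "dxa_calls",
    "patient_concordance",
    "cohort_concordance",
]

logger = logging.getLogger(__name__)

#: Pooled region groups used for limb-level concordance.
REGION_GROUPS: dict[str, frozenset[Region]] = {
    "upper_limb": frozenset({Region.ARM, Region.FOREARM, Region.HAND}),
    "lower_limb": frozenset({Region.THIGH, Region.LEG, Region.FOOT}),
    "hemihead": frozenset({Region.HEMIHEAD}),
    "hemipelvis": frozenset({Region.HEMIPELVIS}),
}

_PER_REGION_GROUPS: dict[str, frozenset[Region]] = {
    r.value: frozenset({r}) for r in Region
}


@dataclass(frozen=True)
class GroupCall:
    """DXA evaluation of one region group."""

    group: str
    ratio_left: float  # left side as candidate-affected
    ratio_right: float
    called_side: Side | None  # heavier side when the call fires, else None
    lo_call: bool

    def ratio(self, side: Side) -> float:
        return self.ratio_left if side is Side.LEFT else self.ratio_right


@dataclass(frozen=True)
class ConcordanceDetail:
    patient_id: str
    group: str
    side: Side
    ratio: float
    kind: str  # confirmed | near_threshold | below_threshold | opposite_side | dxa_only


@dataclass
class ConcordanceReport:
    """Cohort-level agreement between clinical labels and DXA calls."""

    n_patients: int = 0
    n_concordant: int = 0
    excluded_no_labels: list[str] = field(default_factory=list)
    near_threshold: list[ConcordanceDetail] = field(default_factory=list)
    dxa_only: list[ConcordanceDetail] = field(default_factory=list)
    discordant_details: list[ConcordanceDetail] = field(default_factory=list)

    @property
    def concordance_fraction(self) -> float:
        if self.n_patients == 0:
            raise DomainError("no evaluable patients (all lacked clinical labels)")
        return self.n_concordant / self.n_patients

    def to_dict(self) -> dict:
        def rows(items: list[ConcordanceDetail]) -> list[dict]:
            return [
                {
                    "patient_id": d.patient_id,
                    "group": d.group,
                    "side": d.side.value,
                    "ratio": d.ratio,
                    "kind": d.kind,
                }
                for d in items
            ]

        return {
            "n_patients": self.n_patients,
            "n_concordant": self.n_concordant,
            "concordance_fraction": self.concordance_fraction,
            "excluded_no_labels": list(self.excluded_no_labels),
            "near_threshold": rows(self.near_threshold),
            "dxa_only": rows(self.dxa_only),
            "discordant": rows(self.discordant_details),
        }


def _groups(per_region: bool) -> dict[str, frozenset[Region]]:
    return _PER_REGION_GROUPS if per_region else REGION_GROUPS


def dxa_calls(
    scan: PatientScan,
    config: AnalysisConfig | None = None,
    *,
    per_region: bool = False,
) -> dict[str, GroupCall]:
    """Evaluate every region group of a scan for LO.

    Group masses are summed per side; the ratio is computed with each
    side as candidate-affected and the call is made on the heavier
    side's ratio.  Groups with any member missing on either side are
    skipped with a warning.
    """
    config = config or AnalysisConfig()
    calls: dict[str, GroupCall] = {}
    for name, members in _groups(per_region).items():
        complete = all(
            scan.lookup(r, s) is not None for r in members for s in Side
        )
        if not complete:
            logger.warning(
                "patient %s: group %s incomplete on one side; skipped",
                scan.patient_id,
                name,
            )
            continue
        left, right = aggregate_regions(scan, {(r, Side.LEFT) for r in members})
        ratio_left = mt_discrepancy_ratio(left.total_g, right.total_g)
        ratio_right = mt_discrepancy_ratio(right.total_g, left.total_g)
        heavier = Side.LEFT if ratio_left >= ratio_right else Side.RIGHT
        top = max(ratio_left, ratio_right)
        fired = call_lo(top, config)
        calls[name] = GroupCall(
            group=name,
            ratio_left=ratio_left,
            ratio_right=ratio_right,
            called_side=heavier if fired else None,
            lo_call=fired,
        )
    return calls


def _clinical_groups(
    scan: PatientScan, per_region: bool
) -> dict[str, Side]:
    """Map clinically labeled region-sides up to group level."""
    out: dict[str, Side] = {}
    for name, members in _groups(per_region).items():
        for region, side in scan.clinical_affected:
            if region in members:
                out[name] = side  # at most one side per region enforced upstream
    return out


def patient_concordance(
    scan: PatientScan,
    config: AnalysisConfig | None = None,
    *,
    per_region: bool = False,
) -> tuple[bool, list[ConcordanceDetail]]:
    """Agreement of one patient's clinical labels with the DXA calls.

    Concordant iff every clinically labeled group is called on the same
    side.  Details enumerate each labeled group's outcome plus any
    DXA-only calls in unlabeled groups.  Requires a non-empty clinical
    label set.
    """
    config = config or AnalysisConfig()
    labeled = _clinical_groups(scan, per_region)
    if not labeled:
        raise DomainError(
            f"patient {scan.patient_id} has no clinical labels; "
            "excluded from the concordance rate"
        )
    calls = dxa_calls(scan, config, per_region=per_region)
    details: list[ConcordanceDetail] = []
    concordant = True
    lo, band = config.lo_threshold, config.near_threshold_band
    for group, side in sorted(labeled.items()):
        if group not in calls:
            concordant = False
            continue
        call = calls[group]
        ratio = call.ratio(side)
        if call.lo_call and call.called_side is side:
            kind = "confirmed"
        else:
            concordant = False
            if call.lo_call and call.called_side is not side:
                kind = "opposite_side"
            elif lo - band <= ratio < lo:
                kind = "near_threshold"
            else:
                kind = "below_threshold"
        details.append(ConcordanceDetail(scan.patient_id, group, side, ratio, kind))
    for group, call in sorted(calls.items()):
        if call.lo_call and group not in labeled:
            assert call.called_side is not None
            details.append(
                ConcordanceDetail(
                    scan.patient_id,
                    group,
                    call.called_side,
                    call.ratio(call.called_side),
                    "dxa_only",
                )
            )
    return concordant, details


def cohort_concordance(
    scans: dict[str, PatientScan],
    config: AnalysisConfig | None = None,
    *,
    per_region: bool = False,
) -> ConcordanceReport:
    """Pool per-patient concordance into a cohort report.

    Patients without clinical labels are excluded from the rate's
    denominator and listed separately.
    """
    config = config or AnalysisConfig()
    report = ConcordanceReport()
    for pid in sorted(scans):
        scan = scans[pid]
        if not _clinical_groups(scan, per_region):
            report.excluded_no_labels.append(pid)
            continue
        concordant, details = patient_concordance(scan, config, per_region=per_region)
        report.n_patients += 1
        if concordant:
            report.n_concordant += 1
        for d in details:
            if d.kind == "near_threshold":
                report.near_threshold.append(d)
            elif d.kind == "dxa_only":
                report.dxa_only.append(d)
            elif d.kind in ("below_threshold", "opposite_side"):
                report.discordant_details.append(d)
    if report.n_patients == 0:
        raise DomainError("no evaluable patients (all lacked clinical labels)")
    return report
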