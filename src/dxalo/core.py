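"""Domain model for regional bilateral body-composition analysis.

A total-body DXA scan is partitioned into eight paired regions (hemihead,
arm, forearm, hand, hemipelvis, thigh, leg, foot), each measured on the
left and right side.  For every region-side the scanner reports the mass
of the three tissue compartments: adipose (fat), muscle (DXA "lean") and
bone (bone mineral content).  Lateralized overgrowth (LO) of a region is
quantified by comparing it with its contralateral homologue:

* total-mass discrepancy ratio r = (m_t - m_t') / m_t', where m_t is the
  total mass of the affected region and m_t' of its mirror;
* relative composition RC_x = m_x / m_t per tissue (the three RCs sum
  to 1);
* composition discrepancy dRC_x = RC_x - RC'_x in percentage points (the
  three dRCs sum to 0).

LO is called when r exceeds a clinical threshold (10% by default), and
the tissue with the largest dRC in the affected aggregate is reported as
the predominant overgrown tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "Region",
    "Side",
    "Diagnosis",
    "Tissue",
    "TissueMasses",
    "RegionMeasurement",
    "PatientScan",
    "CompositionVector",
    "DeltaComposition",
    "RegionPairResult",
    "AggregateResult",
    "AnalysisConfig",
    "DomainError",
    "relative_composition",
    "mt_discrepancy_ratio",
    "call_lo",
    "delta_rc",
    "aggregate_regions",
    "classify_predominant",
    "score_patient",
]

logger = logging.getLogger(__name__)


class DomainError(ValueError):
    """A violation of the model's preconditions (zero mass, empty set...)."""


class Region(str, Enum):
    """The eight paired body regions.

    Hemithorax and hemiabdomen are deliberately not representable: organ
    laterality makes their two sides intrinsically asymmetric, so they
    carry no information about overgrowth.
    """

    HEMIHEAD = "hemihead"
    ARM = "arm"
    FOREARM = "forearm"
    HAND = "hand"
    HEMIPELVIS = "hemipelvis"
    THIGH = "thigh"
    LEG = "leg"
    FOOT = "foot"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"

    @property
    def mirror(self) -> "Side":
        return Side.RIGHT if self is Side.LEFT else Side.LEFT


class Diagnosis(str, Enum):
    """Diagnostic subgroups of lateralized overgrowth."""

    PROS = "PROS"  # PIK3CA-related overgrowth spectrum
    BWSP = "BWSp"  # Beckwith-Wiedemann spectrum
    ILO = "ILO"  # isolated lateralized overgrowth
    OTHER = "other"


class Tissue(str, Enum):
    ADIPOSE = "adipose"
    MUSCLE = "muscle"
    BONE = "bone"


@dataclass(frozen=True)
class TissueMasses:
    """Gram masses of the three tissue compartments of one region-side.

    The region total ``total_g`` is always derived as the sum of the
    components, never stored independently.
    """

    adipose_g: float
    muscle_g: float
    bone_g: float

    def __post_init__(self) -> None:
        for name in ("adipose_g", "muscle_g", "bone_g"):
            v = getattr(self, name)
            if not (v >= 0.0):  # also rejects NaN
                raise DomainError(f"{name} must be non-negative, got {v!r}")

    @property
    def total_g(self) -> float:
        return self.adipose_g + self.muscle_g + self.bone_g

    def __add__(self, other: "TissueMasses") -> "TissueMasses":
        return TissueMasses(
            self.adipose_g + other.adipose_g,
            self.muscle_g + other.muscle_g,
            self.bone_g + other.bone_g,
        )


@dataclass(frozen=True)
class RegionMeasurement:
    """One region-side record of a scan."""

    region: Region
    side: Side
    masses: TissueMasses


@dataclass
class PatientScan:
    """A patient's full bilateral regional scan plus clinical labels.

    ``clinical_affected`` holds the (region, side) pairs judged overgrown
    at clinical examination; at most one side of a region may be labeled.
    """

    patient_id: str
    measurements: list[RegionMeasurement] = field(default_factory=list)
    clinical_affected: set[tuple[Region, Side]] = field(default_factory=set)
    diagnosis: Diagnosis = Diagnosis.OTHER
    sex: str = "unknown"
    age_years: float = 0.0

    def __post_init__(self) -> None:
        seen: set[tuple[Region, Side]] = set()
        for m in self.measurements:
            key = (m.region, m.side)
            if key in seen:
                raise DomainError(
                    f"patient {self.patient_id}: duplicate measurement for "
                    f"{m.region.value}/{m.side.value}"
                )
            seen.add(key)
        regions_affected: set[Region] = set()
        for region, side in self.clinical_affected:
            if (region, side) not in seen:
                raise DomainError(
                    f"patient {self.patient_id}: clinical label "
                    f"{region.value}/{side.value} has no measurement"
                )
            if region in regions_affected:
                raise DomainError(
                    f"patient {self.patient_id}: both sides of "
                    f"{region.value} labeled affected"
                )
            regions_affected.add(region)

    def lookup(self, region: Region, side: Side) -> RegionMeasurement | None:
        for m in self.measurements:
            if m.region is region and m.side is side:
                return m
        return None


@dataclass(frozen=True)
class CompositionVector:
    """Relative composition: each tissue's fraction of the region total."""

    rc_adipose: float
    rc_muscle: float
    rc_bone: float

    def __post_init__(self) -> None:
        s = self.rc_adipose + self.rc_muscle + self.rc_bone
        if abs(s - 1.0) > 1e-9:
            raise DomainError(f"composition fractions sum to {s!r}, not 1")
        for name in ("rc_adipose", "rc_muscle", "rc_bone"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name}={v!r} outside [0, 1]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.rc_adipose, self.rc_muscle, self.rc_bone)


@dataclass(frozen=True)
class DeltaComposition:
    """Composition discrepancy in percentage points, one value per tissue.

    When produced by :func:`delta_rc` the three components sum to zero:
    any relative gain of one tissue is a loss of the others.
    """

    d_adipose: float
    d_muscle: float
    d_bone: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.d_adipose, self.d_muscle, self.d_bone)


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds governing LO calling.

    lo_threshold
        Discrepancy-ratio cut-off for calling LO; 0.10 by default, with
        the boundary included so exactly-10% cases are flagged.
    near_threshold_band
        Width of the sub-threshold band reported for review; ratios in
        [lo_threshold - band, lo_threshold) are flagged as near-threshold.
    tie_order
        Fixed tissue priority used to break exact ties in the
        predominant-tissue classification.
    """

    lo_threshold: float = 0.10
    near_threshold_band: float = 0.05
    tie_order: tuple[Tissue, ...] = (Tissue.ADIPOSE, Tissue.MUSCLE, Tissue.BONE)

    def __post_init__(self) -> None:
        if not (0.0 < self.near_threshold_band < self.lo_threshold < 1.0):
            raise DomainError(
                "require 0 < near_threshold_band < lo_threshold < 1, got "
                f"band={self.near_threshold_band}, threshold={self.lo_threshold}"
            )
        if tuple(sorted(t.value for t in self.tie_order)) != (
            "adipose",
            "bone",
            "muscle",
        ):
            raise DomainError("tie_order must be a permutation of the three tissues")


@dataclass(frozen=True)
class RegionPairResult:
    """Discrepancy statistics for one region against its mirror.

    ``anchor`` records how the affected side was chosen: ``"clinical"``
    when a clinical label fixed it, ``"heavier"`` when the heavier side
    was taken as candidate-affected in the absence of a label.
    """

    region: Region
    affected_side: Side
    anchor: str
    mt_affected_g: float
    mt_contra_g: float
    discrepancy_ratio: float
    rc_affected: CompositionVector
    rc_contra: CompositionVector
    delta_rc: DeltaComposition
    lo_call: bool


@dataclass(frozen=True)
class AggregateResult:
    """Statistics over the summed masses of a set of affected regions."""

    regions: frozenset[tuple[Region, Side]]
    mt_affected_g: float
    mt_contra_g: float
    discrepancy_ratio: float
    rc_affected: CompositionVector
    rc_contra: CompositionVector
    delta_rc: DeltaComposition
    lo_call: bool
    predominant_tissue: Tissue


def relative_composition(masses: TissueMasses, *, label: str = "region") -> CompositionVector:
    """Relative composition of one region-side: each tissue mass over the total.

    Raises :class:`DomainError` on zero total mass, naming ``label``.
    """
    mt = masses.total_g
    if mt <= 0.0:
        raise DomainError(f"zero total mass in {label}")
    return CompositionVector(
        masses.adipose_g / mt, masses.muscle_g / mt, masses.bone_g / mt
    )


def mt_discrepancy_ratio(mt_affected_g: float, mt_contra_g: float) -> float:
    """Signed total-mass discrepancy ratio (affected - contralateral) / contralateral.

    Negative when the nominally affected side is the lighter one.
    """
    if not mt_contra_g > 0.0:
        raise DomainError(
            f"contralateral total mass must be positive, got {mt_contra_g!r}"
        )
    return (mt_affected_g - mt_contra_g) / mt_contra_g


def call_lo(ratio: float, config: AnalysisConfig | None = None) -> bool:
    """LO call: true iff the discrepancy ratio reaches the threshold (inclusive)."""
    config = config or AnalysisConfig()
    if not (ratio == ratio and abs(ratio) != float("inf")):
        raise DomainError(f"discrepancy ratio must be finite, got {ratio!r}")
    return ratio >= config.lo_threshold


def delta_rc(rc_affected: CompositionVector, rc_contra: CompositionVector) -> DeltaComposition:
    """Composition discrepancy in percentage points, affected minus contralateral."""
    return DeltaComposition(
        (rc_affected.rc_adipose - rc_contra.rc_adipose) * 100.0,
        (rc_affected.rc_muscle - rc_contra.rc_muscle) * 100.0,
        (rc_affected.rc_bone - rc_contra.rc_bone) * 100.0,
    )


def aggregate_regions(
    scan: PatientScan, regions: set[tuple[Region, Side]] | frozenset[tuple[Region, Side]]
) -> tuple[TissueMasses, TissueMasses]:
    """Componentwise mass sums over a set of region-sides and their mirrors.

    Returns ``(affected, contralateral)`` totals.  The set must be
    non-empty, reference only measured region-sides, and never list both
    sides of one region.
    """
    if not regions:
        raise DomainError("empty affected set")
    by_region: dict[Region, Side] = {}
    for region, side in regions:
        if region in by_region:
            raise DomainError(f"region {region.value} listed with both sides")
        by_region[region] = side
    affected = TissueMasses(0.0, 0.0, 0.0)
    contra = TissueMasses(0.0, 0.0, 0.0)
    for region, side in sorted(regions, key=lambda rs: (rs[0].value, rs[1].value)):
        m_aff = scan.lookup(region, side)
        m_con = scan.lookup(region, side.mirror)
        if m_aff is None or m_con is None:
            raise DomainError(
                f"patient {scan.patient_id}: missing measurement for "
                f"{region.value} (need both sides)"
            )
        affected = affected + m_aff.masses
        contra = contra + m_con.masses
    return affected, contra


def classify_predominant(
    delta: DeltaComposition, config: AnalysisConfig | None = None
) -> Tissue:
    """The tissue with the largest composition discrepancy.

    Exact ties are broken by the configured fixed priority
    (adipose > muscle > bone by default).
    """
    config = config or AnalysisConfig()
    values = {
        Tissue.ADIPOSE: delta.d_adipose,
        Tissue.MUSCLE: delta.d_muscle,
        Tissue.BONE: delta.d_bone,
    }
    best = max(values.values())
    for tissue in config.tie_order:
        if values[tissue] == best:
            return tissue
    raise AssertionError("unreachable")


def _pair_result(
    scan: PatientScan,
    region: Region,
    affected_side: Side,
    anchor: str,
    config: AnalysisConfig,
) -> RegionPairResult:
    m_aff = scan.lookup(region, affected_side)
    m_con = scan.lookup(region, affected_side.mirror)
    assert m_aff is not None and m_con is not None
    ratio = mt_discrepancy_ratio(m_aff.masses.total_g, m_con.masses.total_g)
    rc_aff = relative_composition(
        m_aff.masses, label=f"{region.value}/{affected_side.value}"
    )
    rc_con = relative_composition(
        m_con.masses, label=f"{region.value}/{affected_side.mirror.value}"
    )
    return RegionPairResult(
        region=region,
        affected_side=affected_side,
        anchor=anchor,
        mt_affected_g=m_aff.masses.total_g,
        mt_contra_g=m_con.masses.total_g,
        discrepancy_ratio=ratio,
        rc_affected=rc_aff,
        rc_contra=rc_con,
        delta_rc=delta_rc(rc_aff, rc_con),
        lo_call=call_lo(ratio, config),
    )


def score_patient(
    scan: PatientScan, config: AnalysisConfig | None = None
) -> tuple[list[RegionPairResult], AggregateResult | None]:
    """Score every bilateral region pair of a scan, plus the affected aggregate.

    Per-region results are anchored on the clinically affected side where
    a label exists, otherwise on the heavier side (candidate-affected),
    with the anchoring recorded.  Regions missing on either side are
    skipped with a warning, never imputed.  When ``clinical_affected`` is
    non-empty an :class:`AggregateResult` over the summed affected masses
    is produced as well.
    """
    config = config or AnalysisConfig()
    labeled = {region: side for region, side in scan.clinical_affected}
    per_region: list[RegionPairResult] = []
    for region in Region:
        left = scan.lookup(region, Side.LEFT)
        right = scan.lookup(region, Side.RIGHT)
        if left is None and right is None:
            continue
        if left is None or right is None:
            logger.warning(
                "patient %s: region %s present on one side only; skipped",
                scan.patient_id,
                region.value,
            )
            continue
        if region in labeled:
            side, anchor = labeled[region], "clinical"
        else:
            # Heavier side as candidate-affected; left on an exact tie.
            side = (
                Side.RIGHT
                if right.masses.total_g > left.masses.total_g
                else Side.LEFT
            )
            anchor = "heavier"
        per_region.append(_pair_result(scan, region, side, anchor, config))

    aggregate: AggregateResult | None = None
    if scan.clinical_affected:
        masses_aff, masses_con = aggregate_regions(scan, scan.clinical_affected)
        ratio = mt_discrepancy_ratio(masses_aff.total_g, masses_con.total_g)
        rc_aff = relative_composition(masses_aff, label="affected aggregate")
        rc_con = relative_composition(masses_con, label="contralateral aggregate")
        d = delta_rc(rc_aff, rc_con)
        aggregate = AggregateResult(
            regions=frozenset(scan.clinical_affected),
            mt_affected_g=masses_aff.total_g,
            mt_contra_g=masses_con.total_g,
            discrepancy_ratio=ratio,
            rc_affected=rc_aff,
            rc_contra=rc_con,
            delta_rc=d,
            lo_call=call_lo(ratio, config),
            predominant_tissue=classify_predominant(d, config),
        )
    return per_region, aggregate
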