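"""Synthetic bilateral body-composition cohort generator.

Generates cohorts with the statistical structure the scoring pipeline
assumes, so every stage is testable without patient data:

* subgroup-specific relative-composition (RC) and composition-
  discrepancy (dRC) distributions for the three diagnostic subgroups
  (PROS: adipose-predominant overgrowth; BWSp and ILO: osteo-muscular);
* total-mass overgrowth of the affected regions above a configurable
  floor, against physiological asymmetry noise on unaffected regions;
* imperfect clinical labeling via a sensitivity parameter.

The compositional simplex is sampled with truncated normals plus
closure: adipose and bone fractions are drawn at the configured means
and SDs and muscle takes the remainder, with rejection keeping the
simplex valid.  The dRC zero-sum constraint is enforced the same way,
by solving for the muscle component; the configured muscle dRC mean is
therefore implied as minus the sum of the adipose and bone means.

Determinism contract: the same seed and config produce byte-identical
output files.  Each patient draws from an independent substream derived
from the cohort seed by counter, so cohorts are reproducible under
partial regeneration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .concordance import REGION_GROUPS
from .core import (
    Diagnosis,
    DomainError,
    PatientScan,
    Region,
    RegionMeasurement,
    Side,
    TissueMasses,
)
from . import io as io_formats

__all__ = [
    "SubgroupParams",
    "GeneratorConfig",
    "default_config",
    "default_mask_catalog",
    "simulate_patient",
    "simulate_cohort",
    "write_cohort",
]

_MAX_REJECTIONS = 1000

#: Adult-scale phantom region masses in grams (one side).  Invented
#: defaults — the RC and dRC statistics are scale-invariant, so these
#: only set the relative weight of regions within limb aggregates.
DEFAULT_BASE_MASS_G: dict[str, float] = {
    "hemihead": 2500.0,
    "arm": 1800.0,
    "forearm": 1000.0,
    "hand": 400.0,
    "hemipelvis": 4000.0,
    "thigh": 7000.0,
    "leg": 2500.0,
    "foot": 800.0,
}


def default_mask_catalog() -> list[tuple[float, list[tuple[str, str]]]]:
    """Weighted catalog of affected region-group sets.

    Entries are (weight, [(group, side), ...]) at region-group
    granularity: clinical overgrowth involves whole limbs or head/pelvis
    segments, and keeping masks group-complete guarantees every affected
    group's mass discrepancy reflects the drawn overgrowth ratio rather
    than being diluted by unaffected members.
    """
    catalog: list[tuple[float, list[tuple[str, str]]]] = []
    for side in ("left", "right"):
        catalog.extend(
            [
                (0.15, [("lower_limb", side)]),
                (0.075, [("upper_limb", side)]),
                (0.05, [("hemihead", side)]),
                (0.10, [("lower_limb", side), ("hemipelvis", side)]),
                (0.05, [("upper_limb", side), ("lower_limb", side)]),
                (
                    0.075,
                    [
                        ("upper_limb", side),
                        ("lower_limb", side),
                        ("hemipelvis", side),
                        ("hemihead", side),
                    ],
                ),
            ]
        )
    return catalog


@dataclass
class SubgroupParams:
    """Simulation parameters for one diagnostic subgroup.

    RC means/SDs are fractions for the contralateral (unaffected) side;
    dRC means/SDs are percentage points for adipose and bone — the
    muscle component is implied by the zero-sum closure.  The overgrowth
    ratio is drawn from a normal truncated at ``overgrowth_ratio_floor``
    and applied to every masked region's total mass.
    """

    name: str
    contra_rc_mean: dict[str, float]
    contra_rc_sd: dict[str, float]
    delta_rc_mean: dict[str, float]  # pp; adipose and bone drive the draw
    delta_rc_sd: dict[str, float]
    overgrowth_ratio_mean: float = 0.25
    overgrowth_ratio_sd: float = 0.10
    overgrowth_ratio_floor: float = 0.10
    unaffected_asym_sd: float = 0.02
    rc_noise_sd: float = 0.005
    clinical_sensitivity: float = 1.0
    affected_mask_catalog: list[tuple[float, list[tuple[str, str]]]] = field(
        default_factory=default_mask_catalog
    )
    age_mean: float = 12.0
    age_sd: float = 8.0
    p_male: float = 0.5

    def __post_init__(self) -> None:
        total = sum(self.contra_rc_mean[t] for t in ("adipose", "muscle", "bone"))
        if abs(total - 1.0) > 0.01:
            raise DomainError(
                f"{self.name}: contralateral RC means sum to {total:.4f}, not 1"
            )
        for d in (self.contra_rc_sd, self.delta_rc_sd):
            if any(v <= 0 for v in d.values()):
                raise DomainError(f"{self.name}: SDs must be positive")
        if not (0.0 <= self.clinical_sensitivity <= 1.0):
            raise DomainError(f"{self.name}: clinical_sensitivity outside [0, 1]")
        for _, mask in self.affected_mask_catalog:
            for group, side in mask:
                if group not in REGION_GROUPS:
                    raise DomainError(f"{self.name}: unknown region group {group!r}")
                if side not in ("left", "right"):
                    raise DomainError(f"{self.name}: unknown side {side!r}")

    @property
    def implied_delta_muscle_pp(self) -> float:
        """Muscle dRC mean implied by the zero-sum closure."""
        return -(self.delta_rc_mean["adipose"] + self.delta_rc_mean["bone"])


@dataclass
class GeneratorConfig:
    """Cohort-level generator configuration."""

    n_patients: int = 46
    seed: int = 0
    mix: dict[str, float] = field(
        default_factory=lambda: {"PROS": 0.61, "BWSp": 0.24, "ILO": 0.15}
    )
    region_base_mass_g: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_MASS_G)
    )
    subgroups: dict[str, SubgroupParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise DomainError("n_patients must be non-negative")
        if abs(sum(self.mix.values()) - 1.0) > 1e-6:
            raise DomainError(f"mix proportions sum to {sum(self.mix.values())}, not 1")
        for name in self.mix:
            if name not in self.subgroups and self.subgroups:
                raise DomainError(f"mix names unknown subgroup {name!r}")
        for region, mass in self.region_base_mass_g.items():
            if region not in {r.value for r in Region}:
                raise DomainError(f"unknown region {region!r} in base masses")
            if mass <= 0:
                raise DomainError(f"base mass for {region} must be positive")


def default_config(n_patients: int = 46, seed: int = 0) -> GeneratorConfig:
    """Generator defaults for the three diagnostic subgroups.

    Contralateral RC and dRC distributions are parameterized per
    subgroup (fractions and percentage points respectively); the cohort
    mixes PROS, BWSp and ILO at 61/24/15 percent.  Overgrowth ratio:
    mean 0.25, SD 0.10, truncated at the 0.10 call floor.  Physiological
    asymmetry SD on unaffected regions: 0.02.  Clinical sensitivity 1.0
    (labels equal the simulated masks).
    """
    subgroups = {
        "PROS": SubgroupParams(
            name="PROS",
            contra_rc_mean={"adipose": 0.292, "muscle": 0.674, "bone": 0.031},
            contra_rc_sd={"adipose": 0.100, "muscle": 0.102, "bone": 0.013},
            delta_rc_mean={"adipose": 2.0, "muscle": -1.5, "bone": -0.3},
            delta_rc_sd={"adipose": 3.8, "muscle": 3.6, "bone": 0.4},
            age_mean=15.4,
            age_sd=11.6,
            p_male=14 / 28,
        ),
        "BWSp": SubgroupParams(
            name="BWSp",
            contra_rc_mean={"adipose": 0.2775, "muscle": 0.692, "bone": 0.031},
            contra_rc_sd={"adipose": 0.0898, "muscle": 0.091, "bone": 0.012},
            delta_rc_mean={"adipose": -0.5, "muscle": 0.8, "bone": -0.2},
            delta_rc_sd={"adipose": 1.1, "muscle": 1.0, "bone": 0.6},
            age_mean=8.8,
            age_sd=4.2,
            p_male=3 / 11,
        ),
        "ILO": SubgroupParams(
            name="ILO",
            contra_rc_mean={"adipose": 0.384, "muscle": 0.584, "bone": 0.031},
            contra_rc_sd={"adipose": 0.091, "muscle": 0.090, "bone": 0.008},
            delta_rc_mean={"adipose": -2.3, "muscle": 2.3, "bone": 0.1},
            delta_rc_sd={"adipose": 3.0, "muscle": 3.2, "bone": 0.2},
            age_mean=8.9,
            age_sd=3.0,
            p_male=4 / 7,
        ),
    }
    return GeneratorConfig(n_patients=n_patients, seed=seed, subgroups=subgroups)


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    """Independent substream for patient ``index`` of a cohort."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, index)))


def _cohort_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))


def _draw_simplex(
    rng: np.random.Generator,
    mean: dict[str, float],
    sd: dict[str, float],
) -> tuple[float, float, float]:
    """Draw (adipose, muscle, bone) fractions: truncated normals + closure."""
    for _ in range(_MAX_REJECTIONS):
        a = rng.normal(mean["adipose"], sd["adipose"])
        b = rng.normal(mean["bone"], sd["bone"])
        m = 1.0 - a - b
        if a > 0.0 and b > 0.0 and m > 0.0:
            return a, m, b
    raise DomainError("infeasible RC parameters: >1000 consecutive rejections")


def _draw_delta(
    rng: np.random.Generator,
    contra: tuple[float, float, float],
    mean: dict[str, float],
    sd: dict[str, float],
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Draw the zero-sum dRC triple (pp) and the resulting affected RC."""
    ca, cm, cb = contra
    for _ in range(_MAX_REJECTIONS):
        da = rng.normal(mean["adipose"], sd["adipose"])
        db = rng.normal(mean["bone"], sd["bone"])
        dm = -(da + db)
        affected = (ca + da / 100.0, cm + dm / 100.0, cb + db / 100.0)
        if all(v > 0.0 for v in affected):
            return (da, dm, db), affected
    raise DomainError("infeasible RC parameters: >1000 consecutive rejections")


def _jitter_rc(
    rng: np.random.Generator, rc: tuple[float, float, float], sd: float
) -> tuple[float, float, float]:
    """Small independent per-region composition noise (fractions)."""
    if sd == 0.0:
        return rc
    a, m, b = rc
    for _ in range(_MAX_REJECTIONS):
        na = a + rng.normal(0.0, sd)
        nb = b + rng.normal(0.0, sd)
        nm = 1.0 - na - nb
        if na > 0.0 and nb > 0.0 and nm > 0.0:
            return na, nm, nb
    raise DomainError("infeasible RC parameters: >1000 consecutive rejections")


def _expand_mask(mask: list[tuple[str, str]]) -> set[tuple[Region, Side]]:
    out: set[tuple[Region, Side]] = set()
    for group, side in mask:
        for region in REGION_GROUPS[group]:
            out.add((region, Side(side)))
    return out


def _masses(rc: tuple[float, float, float], mt: float) -> TissueMasses:
    a, m, b = rc
    return TissueMasses(a * mt, m * mt, b * mt)


def simulate_patient(
    params: SubgroupParams,
    config: GeneratorConfig,
    rng: np.random.Generator,
    patient_id: str = "P0001",
) -> tuple[PatientScan, dict]:
    """Simulate one patient's bilateral scan plus its ground truth.

    Draws a contralateral RC and a zero-sum dRC for the patient, an
    affected region-group mask from the catalog, per-region total masses
    (lognormal size variation around the phantom base masses), applies
    the overgrowth ratio to masked regions and physiological asymmetry
    noise elsewhere, and converts RC x total mass into tissue masses.
    Clinical labels equal the mask filtered per group by
    ``clinical_sensitivity``.
    """
    contra_rc = _draw_simplex(rng, params.contra_rc_mean, params.contra_rc_sd)
    delta_pp, affected_rc = _draw_delta(
        rng, contra_rc, params.delta_rc_mean, params.delta_rc_sd
    )
    weights = np.array([w for w, _ in params.affected_mask_catalog])
    masks = [mask for _, mask in params.affected_mask_catalog]
    if masks:
        idx = int(rng.choice(len(masks), p=weights / weights.sum()))
        group_mask = masks[idx]
    else:
        group_mask = []
    region_mask = _expand_mask(group_mask)
    masked_side = {region: side for region, side in region_mask}

    measurements: list[RegionMeasurement] = []
    overgrowth_ratios: dict[str, float] = {}
    for region in Region:
        base = config.region_base_mass_g[region.value]
        contra_mt = base * rng.lognormal(0.0, 0.15)
        if region in masked_side:
            side = masked_side[region]
            ratio = rng.normal(params.overgrowth_ratio_mean, params.overgrowth_ratio_sd)
            for _ in range(_MAX_REJECTIONS):
                if ratio >= params.overgrowth_ratio_floor:
                    break
                ratio = rng.normal(
                    params.overgrowth_ratio_mean, params.overgrowth_ratio_sd
                )
            else:
                raise DomainError("infeasible overgrowth-ratio parameters")
            overgrowth_ratios[f"{region.value}:{side.value}"] = ratio
            affected_mt = contra_mt * (1.0 + ratio)
            measurements.append(
                RegionMeasurement(region, side, _masses(affected_rc, affected_mt))
            )
            measurements.append(
                RegionMeasurement(region, side.mirror, _masses(contra_rc, contra_mt))
            )
        else:
            noisy_mt = contra_mt * (1.0 + rng.normal(0.0, params.unaffected_asym_sd))
            rc_left = _jitter_rc(rng, contra_rc, params.rc_noise_sd)
            rc_right = _jitter_rc(rng, contra_rc, params.rc_noise_sd)
            measurements.append(
                RegionMeasurement(region, Side.LEFT, _masses(rc_left, contra_mt))
            )
            measurements.append(
                RegionMeasurement(region, Side.RIGHT, _masses(rc_right, noisy_mt))
            )

    # Clinical labels: drop whole groups with probability 1 - sensitivity.
    labeled_groups = [
        (group, side)
        for group, side in group_mask
        if rng.random() < params.clinical_sensitivity
    ]
    clinical = _expand_mask(labeled_groups)

    age = max(0.5, rng.normal(params.age_mean, params.age_sd))
    sex = "M" if rng.random() < params.p_male else "F"
    scan = PatientScan(
        patient_id=patient_id,
        measurements=measurements,
        clinical_affected=clinical,
        diagnosis=Diagnosis(params.name) if params.name in Diagnosis._value2member_map_ else Diagnosis.OTHER,
        sex=sex,
        age_years=float(age),
    )
    truth = {
        "diagnosis": params.name,
        "mask_groups": [[g, s] for g, s in group_mask],
        "mask_regions": sorted(f"{r.value}:{s.value}" for r, s in region_mask),
        "contra_rc": {
            "adipose": contra_rc[0],
            "muscle": contra_rc[1],
            "bone": contra_rc[2],
        },
        "affected_rc": {
            "adipose": affected_rc[0],
            "muscle": affected_rc[1],
            "bone": affected_rc[2],
        },
        "delta_rc_pp": {
            "adipose": delta_pp[0],
            "muscle": delta_pp[1],
            "bone": delta_pp[2],
        },
        "overgrowth_ratios": overgrowth_ratios,
    }
    return scan, truth


def simulate_cohort(
    config: GeneratorConfig,
) -> tuple[dict[str, PatientScan], dict[str, dict]]:
    """Simulate a full cohort plus its ground-truth sidecar.

    Diagnoses are drawn i.i.d. from the configured mix; each patient
    uses an independent substream of the cohort seed.  Returns
    ``(scans, truth)`` keyed by patient id.
    """
    if not config.subgroups:
        raise DomainError("config has no subgroup parameters")
    cohort_rng = _cohort_rng(config.seed)
    names = sorted(config.mix)
    probs = np.array([config.mix[n] for n in names])
    scans: dict[str, PatientScan] = {}
    truth: dict[str, dict] = {}
    for i in range(config.n_patients):
        name = names[int(cohort_rng.choice(len(names), p=probs))]
        pid = f"P{i + 1:04d}"
        scan, t = simulate_patient(
            config.subgroups[name], config, _patient_rng(config.seed, i), pid
        )
        scans[pid] = scan
        truth[pid] = t
    return scans, truth


def write_cohort(
    scans: dict[str, PatientScan],
    truth: dict[str, dict],
    outdir: Path | str,
) -> dict[str, Path]:
    """Write scans.csv, labels.csv and truth.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scans": outdir / "scans.csv",
        "labels": outdir / "labels.csv",
        "truth": outdir / "truth.json",
    }
    io_formats.write_scans(scans, paths["scans"])
    io_formats.write_labels(scans, paths["labels"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def config_to_dict(config: GeneratorConfig) -> dict:
    """Plain-dict form of a generator config (for YAML/JSON round trips)."""
    out = dataclasses.asdict(config)
    for name, sub in out["subgroups"].items():
        sub["affected_mask_catalog"] = [
            [w, [list(gs) for gs in mask]] for w, mask in sub["affected_mask_catalog"]
        ]
    return out


def config_from_dict(data: dict) -> GeneratorConfig:
    data = dict(data)
    subgroups = {}
    for name, sub in (data.get("subgroups") or {}).items():
        sub = dict(sub)
        if "affected_mask_catalog" in sub:
            sub["affected_mask_catalog"] = [
                (float(w), [(str(g), str(s)) for g, s in mask])
                for w, mask in sub["affected_mask_catalog"]
            ]
        subgroups[name] = SubgroupParams(**sub)
    data["subgroups"] = subgroups
    return GeneratorConfig(**data)
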