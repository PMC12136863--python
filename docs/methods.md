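# Methods

## Scoring model

Every bilateral region pair is compared within the patient. For a
region-side with tissue masses $(m_A, m_M, m_B)$ the total is their sum
$m_t$; the discrepancy ratio against the contralateral homologue is
$r = (m_t - m_t')/m_t'$, signed, with the clinically affected side as
the numerator reference. Where no clinical label exists, the heavier
side is taken as candidate-affected and the orientation is recorded
(`anchor="heavier"`), so a ratio is always reported per pair. Relative
composition is $RC_x = m_x/m_t$ (a point on the 3-simplex) and the
composition discrepancy is $\Delta RC_x = RC_x - RC_x'$, stored in
percentage points. Multi-region involvement is handled by summing gram
masses per side over the affected set before computing $r$, $RC$ and
$\Delta RC$; this mass-weighted pooling is not the mean of per-region
RCs. The predominant overgrown tissue is the argmax of the aggregate
$\Delta RC$; exact ties (never observed with continuous data) are broken
by a fixed adipose > muscle > bone priority so the classification is
deterministic.

Assumptions: the contralateral side is a valid within-patient control
(physiological asymmetry is small relative to pathological overgrowth),
masses are non-negative and regions with a missing side carry no
information (they are skipped with a warning, never imputed). No age or
sex normalization is applied anywhere — the design is self-controlled.

## Thresholds

- `lo_threshold = 0.10`: the clinical 10% convention for calling a
  significant mass discrepancy. The boundary is **inclusive** so
  exactly-10% cases are flagged for review. The girth/length clinical
  cut-off and the DXA mass cut-off are conceptually distinct; both are
  independent config values even though they default to the same 0.10.
- `near_threshold_band = 0.05`: clinically labeled regions whose ratio
  lands in $[0.05, 0.10)$ are reported as near-threshold rather than
  silently discordant, reflecting how sub-threshold cases (7–9%) arise
  in practice.

Internal computation is at full precision; 1-decimal percentages appear
only in display columns and rendered tables, and rounding never feeds
back into calls or classification.

## Concordance

Agreement between clinical labels and DXA calls is evaluated at
region-group granularity by default — upper limb (arm+forearm+hand),
lower limb (thigh+leg+foot), hemihead, hemipelvis — because clinical
overgrowth reporting is limb-level; per-region granularity is a flag.
A patient is concordant when every clinically labeled group is called
on the same side. A DXA call on the opposite side counts as discordant
and is flagged separately. Calls in unlabeled groups are reported as
`dxa_only` ("clinically overlooked") without breaking concordance.
Patients with no clinical labels are excluded from the denominator and
listed; the rate's denominator is patients (a region-level rate is
available through the per-region flag).

## Statistical battery

Paired and pooled-variance unpaired t-tests and one-way ANOVA wrap
scipy. The unpaired test is classic Student (pooled variance) because
that is the convention in this literature; Welch is behind a flag. The
ANOVA accepts $k \ge 2$ groups, where at $k=2$ it satisfies $F = t^2$
against the pooled t. The Shapiro–Wilk check annotates parametric
results with a non-normality flag but never switches methods — the
pipeline always reports the parametric result. No multiple-testing
correction is applied by default (a Holm helper exists).

The exact contingency test is implemented here: 2×2 tables by
hypergeometric enumeration in exact rational arithmetic (the two-sided
rule sums probabilities of all tables no more probable than the
observed one); r×c tables by complete Freeman–Halton enumeration when
the margin-constrained table space holds ≤ 10⁶ tables; otherwise Monte
Carlo over the margin-fixed distribution (scipy's Patefield sampler)
with a fixed default seed and a reported binomial standard error. No
installed package provides the exact r×c form, and the 2×2 path is
cross-checked in the tests against an independent brute-force
enumeration oracle and scipy's 2×2 implementation.

Degenerate inputs (zero-variance differences, constant vectors, groups
below minimum n) raise classified errors rather than returning NaN; the
cohort summary catches these per-cell and emits a flag instead of a
p-value so one degenerate subgroup cannot abort a whole summary.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
per diagnostic subgroup:

| parameter | PROS | BWSp | ILO | units |
|---|---|---|---|---|
| contralateral RC mean (A/M/B) | 29.2 / 67.4 / 3.1 | 27.75 / 69.2 / 3.1 | 38.4 / 58.4 / 3.1 | % |
| contralateral RC SD | 10.0 / 10.2 / 1.3 | 8.98 / 9.1 / 1.2 | 9.1 / 9.0 / 0.8 | % |
| ΔRC mean (A/B drawn) | +2.0 / −0.3 | −0.5 / −0.2 | −2.3 / +0.1 | pp |
| ΔRC SD (A/B) | 3.8 / 0.4 | 1.1 / 0.6 | 3.0 / 0.2 | pp |
| subgroup mix | 0.61 | 0.24 | 0.15 | — |

Sampling: adipose and bone contralateral fractions are drawn from
normals at these means/SDs and muscle closes the simplex
(`muscle = 1 − adipose − bone`), with rejection keeping all components
positive; this maps tabulated means/SDs directly onto parameters, which
a Dirichlet would not. ΔRC is drawn the same way with the muscle delta
solved from the zero-sum constraint — so the muscle ΔRC mean is
*implied*: −(adipose+bone) means, e.g. −1.7 pp for PROS rather than the
tabulated −1.5 pp (tabulated rows do not sum exactly to zero because
they are rounded means of per-patient differences). More than 1,000
consecutive rejections raises an "infeasible RC parameters" error.

Masses: per region, the contralateral total is a phantom base mass
(adult scale, e.g. thigh 7,000 g, hand 400 g — invented, configurable,
and irrelevant to RC/ΔRC statistics by scale invariance) times a
lognormal(0, 0.15) size factor. The affected mask is drawn from a
weighted catalog of *complete* region-group sets (single limbs, limb
combinations, full hemisides), so a group's discrepancy ratio is a
mass-weighted mean of per-region overgrowth draws and never diluted by
unaffected group members. Masked regions get total mass ×(1 + ratio)
with the ratio from a normal(0.25, 0.10) truncated at the 0.10 floor;
unmasked regions get ×(1 + ε), ε ~ N(0, 0.02) physiological asymmetry,
plus small per-region composition jitter (SD 0.005) on both sides.
The patient-level affected RC applies to masked regions only. Clinical
labels equal the mask filtered per group by `clinical_sensitivity`
(default 1.0). Overgrowth magnitude and ΔRC are generated
independently — no within-patient correlation between them is imposed,
as none is established. Ages and sexes are drawn from subgroup-typical
distributions for realism but drive nothing.

Reproducibility: each patient uses a substream spawned from the cohort
seed by index, so the same seed and config give byte-identical output
files and patient *i* is invariant under cohort-size changes.

What passing tests on this generator do **not** show about real data:
real scans have measurement error in the DXA tissue partition itself,
within-patient correlation between regions' compositions, partial-limb
involvement that dilutes group ratios, and labeling error structure
richer than a per-group coin flip. Parameter-recovery results validate
the pipeline's arithmetic, not clinical sensitivity/specificity.

## Problem sizes

Parameter-recovery runs use 5,000-patient single-subgroup cohorts
(standard error of a ΔRC mean ≈ 0.05 pp, comfortably inside the 0.3 pp
recovery tolerance). The type-I-error check uses 2,000 replicates of
10 symmetric patients each; detection checks use a 400-patient default
cohort. These sizes were chosen so each check's Monte-Carlo error is at
least several times smaller than the tolerance it is compared against.

## Interface shape

The package is organized around statsmodels-style objects — an
`OvergrowthStudy` built from data with `fit()` returning an
`OvergrowthResults` that carries estimates, p-values and a `summary()`
table — with the domain operations, I/O, statistics, concordance and
generator kept as importable modules underneath. The CLI is a thin
layer over those modules; library functions are the primary interface.

## Known limitations

- The simulated contralateral RC distribution is a closed truncated
  normal, not a fitted compositional model; extreme-SD configurations
  shift realized means slightly (rejection bias ≲ 0.06 pp at defaults).
- The Monte-Carlo Fisher p-value is an estimate; its standard error is
  reported, but callers needing exactness must keep margins small
  enough to enumerate.
- Concordance granularity is limb-level by default; focal overgrowth of
  a single region inside a limb can be diluted below threshold at group
  level (use `per_region=True` for such cohorts).
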