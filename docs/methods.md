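# Methods

This note documents the models, parameters and design choices behind
`fluoroskill`: what each stage computes, what the synthetic cohort does
and does not emulate, and where genuinely open choices were settled.

## Phantom and articulation

The phantom is a schematic right upper extremity built from convex
attenuating primitives (capsules, cylinders, ellipsoids, boxes) grouped
into three rigid segments. The forearm segment carries two bone
capsules (radius, ulna), a volar plate (box, on the palmar cortex) and
four locking screws (thin cylinders); the hand carries a carpal
ellipsoid and three metacarpal capsules. Attenuation coefficients are
order-of-magnitude values — bone 0.05 /mm, implant metal 1.0 /mm, soft
tissue omitted — because the images only need to respond correctly to
articulation, not to look anatomical.

The pose is a three-angle state, all in degrees, with hard joint
limits: elbow flexion ∈ [0, 150], forearm rotation ∈ [−90, 90]
(pronation positive; neutral is mid-prone, thumb up), wrist flexion ∈
[−75, 75] (flexion positive). The kinematic chain is exactly three
transforms: the forearm rotates about a fixed elbow axis; the hand
additionally rotates axially about the forearm long axis and then
flexes about the wrist axis, which is carried by the axial rotation.
The C-arm never moves (vertical beam, source above the arm table,
detector below); an auto-centering step translates the detector so the
hand centroid projects to the image centre, mirroring a simulator that
always centres the field of view over the operative area. Shoulder
motion, soft tissue and collision handling are out of scope.

Nominal view configurations (elbow, rotation, wrist): PA (0, +90, 0),
AP (0, −90, 0), lateral (0, 0, 0), facet (+20, 0, 0), tangential
(0, +90, +70). The facet view's "elevated wrist" is represented as 20°
of elbow flexion aligning the beam with the radiocarpal joint line;
this number is a convention of this package, not a measured value.
These nominals drive only the demo renderer and the synthetic cohort's
aiming targets — scoring is expert-referenced and never consults them.

Recorded angles are beam-relative: elbow flexion is the elevation of
the forearm axis out of the detector plane, forearm rotation the axial
palm angle against the beam projected into the forearm-orthogonal
plane. Under the default vertical beam both reduce exactly to the
joint angles; tilting the beam by δ about the elbow axis shifts the
reported elbow angle by exactly −δ. The wrist angle (tangential view
only) is measured between hand and forearm and is beam-independent.

## Image formation

Pixels hold transmission `I = exp(-Σ μᵢ ℓᵢ)` where the chord lengths
`ℓᵢ` come from closed-form ray–primitive intersections (slab method for
boxes; quadratics for cylinders and unit-sphere-scaled ellipsoids;
capsules as the convex union of a finite cylinder and two cap
spheres). There is no sampling or stepping, so the log image recovers
the attenuation line integral to machine precision and the parallel
beam is exactly translation- and rotation-equivariant — which is what
the renderer tests exploit. Default detector: 256×256 px at 0.5 mm
pitch, parallel projection (cone-beam available behind the same
interface). Scatter, noise, beam hardening, dose and DICOM output are
non-goals.

## Assessment protocol

A participant performs 2 sessions × 3 repetitions. One repetition
takes at least one image per view; only the last saved image per view
survives the transfer step (last-write-wins — whether a real operator
could transfer an earlier saved image is unspecified behaviour, and
last-write-wins is the convention here), and a repetition missing any
view is an error, not a partial record. Total image count and task
time are recorded per repetition. Records round-trip through a
long-format CSV (one row per transferred image; UTF-8, header row, "."
decimal) with schema violations reported by row number.

## Scoring

Let m, s be the mean and sample SD (ddof = 1) of one recorded angle
over *all* transferred images of the experienced cohort, pooled across
both sessions and all repetitions. Every angle x becomes an absolute
z-score |x − m|/s; a per-image total z-score sums the angular z-scores
(two angles; three for the tangential view); the composite sums the
total z-scores of the discriminating views; a participant's mean
composite averages exactly six repetition composites, with listwise
exclusion (never a partial mean) otherwise. Two choices deserve
comment:

* **Mean + SD normalization.** Normalizing by the expert mean alone
  would leave scores in degrees and make angles with different
  intrinsic variability incommensurable; dividing by the expert SD
  makes them unit-free z-scores, which is what a "z-score" means. A
  consequence worth knowing: an experienced cohort scored against its
  own reference has per-angle mean |z| → √(2/π) ≈ 0.798 when aiming
  errors are normal, so the experienced composite over three two-angle
  views sits near 3 × 2 × 0.798 ≈ 4.8 by construction.
* **Per-(view, angle) references.** Moments are fitted separately for
  each view and angle, since the aiming targets differ per view.

Zero variance in any reference angle raises a degenerate-reference
error rather than producing infinite scores.

## Validity battery

* **Split-plot ANOVA** per metric (5 view totals + time + image
  count): between-participant factor experience, within factor
  repetition (6 levels). Between-group F = MS_group /
  MS_subjects-within-group; partial η² = SS_group / (SS_group +
  SS_subjects-within-group); estimated marginal means are group means
  of participant means (equal to cell means for complete data) with
  t-based CIs from the pooled between-subject mean square. The
  decomposition is verified against a brute-force mean-based oracle to
  1e-8 and against an independent implementation (pingouin) in the
  tests.
* **Holm–Bonferroni** step-down over the seven metrics at familywise
  α = 0.05: rank-r threshold α/(m−r+1), stopping at the first
  non-rejection. Only view totals may enter the composite even if a
  pacing metric were significant.
* **Session effect**: session-1 minus session-2 participant-level mean
  composite difference with a paired t CI.
* **ICC**: two-way, absolute-agreement, average-measures intraclass
  correlation (McGraw & Wong's ICC(A,k)) on the participants × 6
  repetition-composites matrix, `(MSR − MSE) / (MSR + (MSC − MSE)/n)`,
  with the standard F-based single-measures CI Spearman–Brown-scaled to
  k, and p from MSR/MSE. The unit of analysis (k = 6 repetition
  composites) is a design choice; k = 2 session means is available via
  `icc_unit="sessions"`.
* **Contrasting groups**: a normal density is fitted to each group's
  participant mean composites and the discriminatory standard is the
  density intersection between the group means (closed-form root of
  the equal-log-density quadratic; the equal-SD case degenerates to the
  midpoint). Normal fits rather than kernel estimates because ≤ 11
  points per group make KDE intersections unstable. The CI is a
  percentile bootstrap over participants resampled within groups
  (default B = 10 000, seeded); the choice of bootstrap CI is a design
  decision — analytic CIs for a density-intersection root are not
  standard.
* **Consequences**: a participant meets the standard iff their mean
  composite is strictly below it (lower = better); ties count as not
  meeting it, the conservative direction for a proficiency test. False
  positive = novice meeting the standard; false negative = experienced
  participant not meeting it.

## Synthetic cohort

Each participant draws a stable per-angle aiming bias
`b ~ Normal(group offset, τ²)` once; each image's achieved angle is
`nominal + b + σ·(√ρ·u_rep + √(1−ρ)·u)` where `u_rep` is a
repetition-level "form" shock shared by all angles of that repetition
and `u` is fresh per angle, so the marginal per-image noise is
`Normal(0, σ²)` with a fraction ρ of its variance common to the
repetition. Achieved angles are clamped (not resampled) at the joint
limits to keep cohorts a pure function of the seed. Image counts use a
per-participant log-normal retake rate feeding per-view Poisson extras;
task time is log-normal with participant and within-repetition
components.

Default preset (derived calibration constants, not measured
behaviour; re-derivable with `scripts/calibrate_preset.py`):

| parameter | value | meaning |
|---|---|---|
| τ | 1.5° | between-participant bias SD, all angles, both groups |
| σ | 4.2° | experienced per-image SD, all angles |
| ρ | 0.30 | within-repetition noise correlation |
| novice σ multipliers | PA 1.76, AP 0.90, LAT 1.82, FACET 2.98, TANG 0.98 | per-view imprecision ratio |
| aiming offsets | ~10° inside the rotation/elbow limits | shared by both groups |
| retakes / view | 3.9 (novice), 3.78 (experienced) | ≈ 24 images per repetition |
| time median | 199 s (novice), 217 s (experienced) | ≈ 210/229 s means |

Rationale for the less obvious pieces:

* **Aiming offsets.** The PA/AP rotation targets (±90°) and the
  extended-elbow targets (0°) sit exactly at joint limits; aiming at
  them would censor half of the error distribution at the limit. Both
  groups therefore conventionally aim ~10° inside the range (a
  slightly flexed, slightly under-rotated arm still yields the
  intended projection). The offsets are identical across groups: they
  encode convention, not skill.
* **Repetition correlation ρ.** With purely independent noise the
  composite's within-participant variance is small relative to the
  group separation and the pooled test–retest ICC saturates near 0.9.
  A shared per-repetition shock (good and bad repetitions) moves the
  ICC distribution to centre near 0.84 at the study's size without
  changing any per-image marginal.
* **Calibration of the multipliers.** The grid search scores a large
  cohort (n = 120–200 per group) and nudges each view's multiplier
  until the novice EM means hit their targets (PA 2.60, LAT 2.72,
  FACET 4.55; AP held at parity and the tangential gap at ~0). The
  targets preserve the intended qualitative pattern — novices clearly
  worse on PA, lateral and facet; no practical difference on AP or
  tangential; facet worst by far — while giving the small 11-vs-9
  study enough power that the Holm selection of exactly {PA, LAT,
  FACET} is stable across seeds. A preset that instead pins every
  group mean to borderline significance levels would make the selected
  view set flip from seed to seed, which no fixed acceptance band can
  accommodate.
* **No learning between sessions** in the default preset (a
  `learning_rate` knob exists for power experiments).

What the generator does *not* emulate: real radiographic anatomy and
image-quality judgements, warm-up/familiarization effects, help
requests, demographic covariates, hand tremor, or any drift in pacing.
Passing the end-to-end tests therefore shows that the *statistical
pipeline* behaves correctly on data with the assumed hierarchical
structure — it is not evidence about real surgeons.

## Numerical choices and edge cases

* Degenerate inputs raise informative errors: out-of-limit joint
  angles name the joint; incomplete repetitions name the missing
  views; a zero-variance reference, identical group means in standard
  setting, and unbalanced post-exclusion ANOVA tables are all rejected
  rather than silently handled.
* Rotation matrices are validated to 1e-9 orthonormality; chord
  computations guard parallel-ray and zero-discriminant branches
  explicitly.
* The Holm step-down uses strict `p < threshold` rejection; bootstrap
  resamples that produce degenerate group fits are skipped.
* Problem sizes in the test suite (cohorts of 20–1,000 participants,
  50–200 simulation replicates, 100-seed end-to-end sweeps) were
  chosen to keep each statistical check's Monte-Carlo error well below
  its assertion tolerance.

## Known limitations

* The phantom is schematic; rendered images are geometrically faithful
  to articulation but not anatomically realistic, and the facet view's
  20° convention is unvalidated.
* The forearm segment does not itself rotate during pronation (the
  axial rotation is applied distal to it); this does not affect
  recorded angles or scoring, only the rendered appearance of the
  plate in rotated views.
* Estimated marginal means are computed as group means of participant
  means, which equals the GLS machinery only for complete balanced
  data — guaranteed here by listwise exclusion, but not general.
* The experienced group's self-referenced composite is pinned near 4.8
  by the normality of its aiming errors; cohorts whose expert errors
  are heavy-tailed would score lower, and the package does not model
  that.
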