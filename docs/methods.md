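# Methods

`protonkbp` reimplements, at desk scale and on fully synthetic data, the
workflow of a proton-specific knowledge-based treatment-planning (KBP)
system for head-and-neck IMPT: a library of plans is parameterized into
geometric and dosimetric features, per-organ regressions predict a band of
achievable DVHs for a new patient, optimization objectives are placed at
the lower band boundary, and the resulting knowledge-based plan is compared
with a manually styled plan. This note records the models, the parameters
that matter, and the design decisions taken where the published description
is qualitative.

## Case model

Cases are voxelized on a regular grid (masks cell-centered, 0-based
indices; world coordinates in mm with x = left, y = posterior,
z = superior). A simultaneous-integrated-boost prescription delivers
70 / 54.25 Gy to the boost / elective PTV in 35 fractions; a 5-mm
transition shell (PTV_O) between them carries the intermediate level
62.125 Gy — the mean of the neighbouring prescriptions, a modeling choice
for a volume whose clinical role is a dose gradient. The three stored
levels are pairwise disjoint; their union PTV_COMP is the target of every
field. Gantry angles follow IEC 61217 (0° = anterior, clockwise from the
feet), beams are coplanar, and the isocenter is implicit (the beam-frame
construction needs only directions). The 2.5-mm calculation-grid
convention is the default spacing; all shipped analyses use 4 mm, which
keeps a 60-case study under ten minutes on one core at DVH-level fidelity.

Laterality of paired organs is assigned by PTV-overlap fraction with a
centroid-distance tie-break; model structures pool left/right organs as
ipsilateral/contralateral so the library matches anatomy by its relation to
the target.

## Synthetic cohort generator

The generator emulates a head-and-neck SIB cohort: an elliptical
water-equivalent body; an irregular boost volume (ellipsoid with smooth
correlated boundary noise); the 5-mm Euclidean shell; an elective volume
from a sampled 8–18-mm margin plus a nodal extension; paired parotids and
submandibulars; midline oral cavity, three pharyngeal constrictors, two
larynx volumes, cricopharyngeus and upper esophageal sphincter; and a
serial spinal-cord cylinder. Organ volumes are truncated normals matched to
the printed mean ± SD and min–max of a 50-patient model library; per-organ
presence probabilities (0.88–1.0) reproduce the observation that each model
organ is matched by only ~43–50 of 50 library cases. Target overlap is
steered by shifting each organ from its anatomical base position toward the
target centroid until a sampled overlap fraction is approximated; the
sampled values are recorded in the cohort manifest. Gantry angles are drawn
from 35–55°, {180°} and 305–330°. Everything is deterministic given
(seed, index).

What the generator does **not** emulate: CT intensities and tissue
heterogeneity (water-equivalent geometry only), realistic cervical
topology beyond organ placement, inter-observer contouring variation, and
setup/range uncertainty. Passing tests therefore demonstrate that the
KBP machinery works when geometry truly drives dose; they do not
demonstrate clinical accuracy on patient data.

## Geometry-based expected dose (GED)

The GED assigns each voxel a surrogate dose from beam geometry alone,
evaluated per field and per target level on a beam-frame lattice at
voxel-center resolution (nearest-neighbour sampling; for axis-aligned beams
on isotropic grids the lattice coincides with voxel centers, which is what
makes the 1-D oracle exact to 1e-9). Along each ray, disjoint in-target
runs are separate sub-targets; for a sub-target (a, b) of length L with
prescription D:

* inside: D;
* upstream at distance d: `D · r(L) · max(0, 1 − d/entry_decay)` with
  entry ratio `r(L) = 0.6 + 0.4·L/(L + 50 mm)` and
  `entry_decay = 150 mm`;
* downstream at distance d: `D · exp(−d/s)` with `s = 4 mm`.

The per-voxel value is the max over sub-targets, which makes the gap of a
non-convex target strictly colder than the single-target treatment and
never hotter anywhere. Fields are combined by **mean** and levels by
voxelwise **max**, keeping in-target values on the prescription scale; the
total is grey-dilated by 4 mm and convolved with a 4-mm 3-D Gaussian (the
penumbra). The functional forms are package choices: the source system
states only the qualitative dependencies (entry dose growing with target
length and shrinking with distance; distal fall-off with a steepness
scale), so the forms above were chosen monotone, bounded and SOBP-like,
and acceptance is via properties and closed forms, not clinical numbers.

Organs are partitioned against the smoothed GED: target overlap; in-field
(GED ≥ τ_in, no overlap); out-of-field (GED < τ_out). Both thresholds
default to 5% of the lowest prescription (≈2.71 Gy); voxels in an
intermediate band, when the thresholds differ, go to in-field so the
heavily modeled region is conservative.

## Toy dose engine

A stand-in for a clinical optimizer/dose algorithm, built for DVH-level
realism:

* **Spots.** In-air sigma 3.9 mm at isocenter, lateral spacing
  0.425 × FWHM (= 3.90 mm); energy layers whose SOBP flat tops tile the
  field-target depth range in 5-mm steps; proximal/distal/lateral margins
  2/3/5 mm; a 57-mm water-equivalent range-shifter offset enters the energy
  bookkeeping (in a homogeneous phantom it does not change dose shapes).
* **Kernel.** Separable: a 1-D depth profile (entry plateau 0.35, unit flat
  top of one layer step, distal `exp(−d/4 mm)` truncated below 4e-4) times
  a lateral Gaussian whose sigma grows linearly with depth
  (0.015 mm/mm), evaluated per layer at the flat-top centre so each layer's
  kernel stays separable. Influence entries and the final dose are sampled
  at identical beam-frame-lattice coordinates, so the optimizer's sampled
  dose and the full-grid dose agree at every sampled voxel (depth
  comparisons are kept in float64 because flat-top boundaries coincide
  exactly with lattice depths).
* **Objectives.** Quadratic penalties: two-sided uniformity for the boost;
  uniformity with a small overdose weight (0.05–0.1) for elective and
  transition levels, whose voxels next to the boost are legitimately hot;
  one-sided max-point for serial structures (cord 45 Gy) and a conformity
  shell; mean-dose-to-zero for organ sparing, applied to the sparable
  (non-target-overlapping) part of each organ; upper dose-volume objectives
  with the standard per-iteration voxel-selection heuristic. Priorities
  weigh mean-per-voxel penalties, so the large elective volume carries a
  higher priority (300 vs 100) to keep its per-voxel coverage pull
  comparable to the boost's.
* **Optimizer.** Projected gradient on the nonnegative spot weights with a
  diagonal (column-norm) preconditioner, an exact line step for the current
  active sets, and backtracking through the projection — the logged
  objective is monotone non-increasing and the run is deterministic.
  Optimization acts on a sampled voxel set: all target voxels (so target
  metrics are exact), organ voxels strided to ≤600 per structure, and a
  strided 12-mm conformity shell.
* **Manual-style plans.** Interactive planning is emulated by two
  re-weighting rounds (organs still above half the elective prescription
  get a 1.5× priority bump) plus a continue-optimization pass (target
  priorities ×4, warm start) when V95 aims (99%/98%) or the V107 cap are
  unmet. A per-case planner-skill factor (uniform 0.6–1.0, seeded from the
  case id) scales all organ priorities and injects the inter-plan
  variability a knowledge-based model exists to learn.

## Knowledge-based model

Per organ, the in-field achieved DVH and in-field GED DVH are sampled as
dose-at-volume curves on a fixed 100-point volume grid (dose normalized to
the boost prescription) and reduced by PCA — the smallest number of
components explaining ≥95% of variance, capped at 5. Dose PC scores are
regressed by OLS on standardized features (geometry PC scores plus organ
volume, overlap fraction, out-of-field fraction, target volume), with a
tiny ridge term when the Gram matrix condition number exceeds 1e8. R² is
reported for dose PC1, the axis the source system's regression plots show.
Low-modulation regions (overlap, out-of-field) get mean ± SD
volume-at-dose bands. Organs matched by fewer than `min_train` cases
(default 20) are skipped with a warning.

Prediction reconstructs the median in-field curve from the regressed
scores. The band half-width is the quadrature sum of the per-PC residual
SDs propagated through the component curves — identical to the ±1 SD
reconstruction for one component, and, unlike reconstructing at shifted
scores, guaranteed to keep lower ≤ median ≤ upper when components change
sign. Region curves are mixed volume-weighted by the case's own partition
fractions, projected to monotone non-increasing, and clipped to [0, 1].
Scalar features outside the training min–max raise geometric-outlier
flags ("volume-out-of-range", ...): extrapolation warnings, not errors.
Outlier curation flags training points with |studentized residual| > 3 on
dose PC1 or leverage > 3(p+1)/n; residual SDs at numerical-noise level
(saturated fits, n ≈ p) are excluded. Removal is a user action.

## Objective placement and KBP creation

For each organ with a band, three upper dose-volume objectives are placed
at the lower boundary's dose at 10/50/85% volume (offset 0 by default),
alongside the standard target and serial objectives. Priorities are
mirrored from the same case's manual plan (including its skill factor) and
multiplied by a fixed scale of 16: a dose-volume penalty acts only on its
active voxel subset, so per unit priority it pulls far more weakly than the
manual mean-dose penalty, and the scale was calibrated once so that KBPs
match manual plans in organ sparing (near-zero mean paired dose
difference) — the parity the workflow is designed to deliver. KBPs reuse
the manual beam geometry, get the same continue-optimization rule, and are
normalized to the manual plan's mean boost dose before comparison.

## Evaluation

Study endpoints on any cohort: per-organ predicted (median-band) vs
achieved mean dose with the count within 3 Gy; paired KBP-vs-manual deltas
(KBP − manual) for HI = 100·(D2% − D98%)/D50% and V95 of both PTVs, for
individual organ mean doses, for composite salivary
(parotids + submandibulars) and swallowing (constrictors + larynx +
cricopharyngeus + UES) structures — membership is configurable since the
source defines the composites only by name — and max-dose deltas for serial
structures. DVHs use 0.05-Gy bins with interpolated queries; Dv% resolves
plateaus to their high-dose end, matching the sort-based definition.

## Numerical choices and degenerate inputs

* Beam-frame lattice step = the finer axial spacing; nearest-neighbour
  sampling both ways; lattice/voxel agreement is exact for axis-aligned
  beams on isotropic grids.
* The influence matrix is stored in float32 (halves matvec bandwidth;
  ~1e-7 relative rounding), with depth-profile boundary comparisons in
  float64 as noted above. Lateral kernels are truncated at 3 sigma.
* Empty masks, empty targets, inconsistent grids, non-decreasing
  prescriptions and invalid thresholds raise immediately with specific
  messages; a prediction for an organ absent from the model is skipped, and
  an organ whose in-field region is empty is predicted from the
  low-modulation bands alone.
* Identical training curves give a defined PCA (one arbitrary orthonormal
  component, zero scores).

## Problem sizes

The shipped study analog uses 50 training + 10 evaluation phantoms on a
4-mm grid — the library and evaluation sizes of the source study at a
coarser grid, chosen so the whole pipeline (≈130 optimizations plus GED
and training) completes in minutes on a single core. Model quality at this
scale (per-organ R² ≈ 0.80–0.95, mean ≈ 0.89) lands in the range the
clinical system reported (0.76–0.93, mean 0.85), and the evaluation
accuracy (≈87% of organs within 3 Gy) matches the reported 88/109 ≈ 81%
qualitatively; these are properties of the synthetic conditions, not
claims about patient data.

## Known limitations

Non-robust optimization only; physical dose (constant RBE); no
heterogeneity, range uncertainty or delivery constraints; the interactive
"fixed diagonal distance" planning heuristic is emulated, not reproduced;
the commercial estimation algorithm's internals (component counts, band
multipliers, outlier criteria) are unknown, so this package's choices are
documented defaults rather than claims of equivalence.
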