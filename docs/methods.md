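# Methods

## Measurement model

The quantity of interest is the kinetic energy of blood inside a segmented
region over the cardiac cycle. Per voxel, KE = ½ m v² with
m = V·ρ (voxel volume × blood density, ρ = 1.05 g/cm³) and v the magnitude
of the three-directional velocity vector; voxel energies are summed over
the region per reconstructed phase. Velocities are held in cm/s throughout
(the velocity-encoding convention of phase-contrast MRI; venc defaults to
100 cm/s) and converted to SI only inside the KE formula; energies are
reported in mJ. A voxel belongs to a region iff its label matches
(voxel-center semantics), and the physical voxel volume is the product of
the spacings — so ROI sums are plain voxel counts times closed-form voxel
energies, which is what makes the analytic phantoms exact oracles.

The cycle is split at the ventricular **volume** curve, not at KE
morphology: end-diastole = argmax volume (cycle start), end-systole =
argmin, ties to the earliest phase. The systolic KE peak is the maximum
over [end-diastole, end-systole); diastole is the complement. The early
diastolic peak is the first sufficiently prominent local maximum of the
diastolic window; a late (atrial) peak is a second such maximum in the
final 30% of diastole separated from the first by a trough ≥ 10% below
the smaller peak, otherwise the peaks are reported as fused. A *plateau*
is flagged when the KE range over the central 50% of diastole stays below
15% of the diastolic peak. The systole/diastole ratio (> 1
systolic-dominant, < 1 diastolic-dominant) classifies the pattern; a ratio
within 1e-6 of 1 is refused as indeterminate rather than guessed.

**Peak prominence.** "First local maximum" is ill-posed under measurement
noise — an epsilon ripple just after end-systole would otherwise become
the early peak. A local maximum must therefore rise at least 5% of the
diastolic maximum above its surroundings (`prominence_frac`, configurable
and recorded with the other thresholds in the result). All peak/plateau
thresholds are deliberate quantitative stand-ins for qualitative visual
criteria, and all are configurable arguments of `analyze_peaks`.

## Preprocessing

Order is fixed: **unwrap → eddy-correct → reconstruct**, because the eddy
fit assumes wrap-free static tissue and interpolation assumes jump-free
series.

* *Phase unwrapping* is 1-D temporal per voxel-component with period
  2·venc, trusting phase 0: whenever a step between consecutive phases
  exceeds venc in magnitude, a multiple of 2·venc is added to minimize it.
  Values may legitimately exceed venc afterwards. No spatial unwrapping is
  attempted; recovery is exact whenever the true per-voxel series changes
  by less than venc between phases (guaranteed by the phantoms up to
  1.8×venc peak speeds).
* *Eddy-current compensation* fits, per velocity component, one
  first-order spatial polynomial (offset cm/s + gradients cm/s per **mm**,
  so coefficients are spacing-invariant) to the time-averaged velocity of
  static-tissue voxels by least squares, and subtracts the plane from
  every phase. Static tissue is selected by temporal SD of every
  component < 5% of venc *and* temporal-mean speed < 10% of venc
  (defaults scale with venc because both artifact and noise do). On
  statics that truly are polynomial the fit is exact to numerical
  precision; voxels carrying faint moving-blood tails (ellipsoid-boundary
  voxels of the ventricle phantom, slow near-wall laminae of a vessel)
  pass the thresholds and bias the fit at the 0.01–1 cm/s level — a real
  limitation of stationary-tissue fitting, visible in the phantom too.
* *Temporal reconstruction* resamples each voxel-component to `n_out`
  uniform phases (default 40, the analysis convention for 14–22 acquired
  phases) by periodic linear interpolation in cycle time. When output
  times align with input times this is the identity. Label masks are
  resampled by cyclic nearest-neighbor (labels are categorical).

## Synthetic data

The generators exist so that every stage has ground truth; their defaults
are the study conditions they emulate: venc 100 cm/s, isotropic 2–3 mm
voxels, ~20 acquired phases reconstructed to 40, RR 1000 ms.

* **Plug-flow box** and **Poiseuille pipe** have closed-form KE
  (½ρV v² and ½ρ(v_max²/3)πR²L); the pipe's voxelized sum converges to the
  continuum value under grid refinement and is within 3% at 1 mm spacing.
* The **ventricle phantom** is a measurement-chain target, not a flow
  solution: an ellipsoid (long/short axis 1.2) scaled isotropically to
  follow a smooth one-minimum volume curve (end-systole at 38% of the
  cycle), carrying two spatially disjoint axial Gaussian jet lobes —
  outflow in one x-half-space during systole, inflow in the other during
  diastole, with a cosine handover of KE share across ±2 phases around
  end-systole. Each phase's lobe amplitude is solved so the ROI-summed KE
  equals the requested cycle template *exactly*; the velocities extend
  over the full end-diastolic support so per-voxel time series stay
  continuous as the contracting ROI sheds boundary voxels (temporal
  unwrapping depends on that). Template peaks sit on sample indices, so
  the sampled maxima equal the nominal peak values. The plateau template
  holds mid-late diastole at 97% of the early-diastolic peak (within the
  ±7.5%-for-≥25%-of-diastole definition adopted for the qualitative
  "diastolic plateau").
* **Corruption injectors** apply the inverse of each correction: a static
  first-order velocity plane; venc wrapping v ↦ ((v+venc) mod 2venc) −
  venc restricted to out-of-range values (so in-range data are untouched
  bit-for-bit, and injection is idempotent on its output); i.i.d. Gaussian
  velocity noise.
* The **cohort simulator** draws per-subject peak systolic/diastolic
  KE/SV, EDVI, EF, BSA, heart rate and APC fraction from group
  distributions (redrawing, then clipping, infeasible values; everything
  derives from one seed via spawned generators). Reference parameters
  mirror the published single-ventricle study: Fontan-LV peak KE/SV
  0.022 ± 0.004 / 0.033 ± 0.007 mJ/ml vs control-LV 0.048 ± 0.012 /
  0.058 ± 0.010 (RV-morphology parameter sets are also provided). Each
  subject's phantom realizes the drawn KE/SV against its *voxelized*
  stroke volume, so the chain's recovery error is attributable to the
  corruptions (noise default 1 cm/s ≈ 1% of venc, a typical in-vivo
  level; random eddy planes; aliasing wherever speeds exceed venc), not to
  discretization. Default cohort grid 36³ at 3 mm keeps the largest
  control ventricles on-grid; the single-phantom default is 32³
  (seconds per subject on one CPU).

What the phantoms do **not** emulate: MR signal formation (k-space,
partial-volume, phase noise correlated with magnitude), myocardial and
valve-plane motion, real intraventricular vortex flow, respiratory
variation, and segmentation error beyond nearest-neighbor mask timing.
Passing tests therefore validate the measurement chain's arithmetic and
its corruption recovery, not in-vivo accuracy.

## Statistics

Group differences use the two-sided Mann–Whitney U test: exact
(enumeration-based null, via `scipy.stats.mannwhitneyu(method="exact")`,
two-sided p = 2 × one-sided tail capped at 1) when samples are small
(min n ≤ 8 or n₁·n₂ ≤ 200) and tie-free; otherwise the normal
approximation with midranks and tie correction. Exact mode refuses tied
data explicitly instead of silently approximating. The test suite checks
the exact p against an independent brute-force enumeration of all rank
assignments for every n₁+n₂ ≤ 12. Pearson r uses the t transform with
n−2 df. Cohen's kappa is unweighted, computed from the cross-tabulation
with observed and expected agreement reported. Interobserver variability
is the paired relative difference 100·(a−b)/((a+b)/2), mean ± SD.
Comparisons between subgroups below n = 5 per group are suppressed with a
notice instead of a p-value — small-subgroup testing is declined, not
under-powered.

APC flow is reference − caval volume with the reference (aortic SV, or
total pulmonary venous return when aortic flow is missing) also serving
as the fraction denominator; negative estimates (possible under noise)
are floored at zero with a warning; significance is **strictly** > 25% of
SV. Vessel KE is indexed to the time-averaged vessel-segment volume,
which is stable when contours are traced per phase.

## Numerical and design notes

* Exactness claims (eddy recovery ≤ 1e-8 relative, clean-chain identity
  ≤ 1e-9) hold on fields whose static tissue is exactly polynomial (the
  analytic phantoms); see the static-tissue caveat above.
* Unwrapping round trips differ from the original by at most one ULP of
  2·venc arithmetic; tests assert to 1e-9 cm/s.
* Landmark ties break to the earliest phase; constant volume curves are
  rejected (no cycle).
* Reported problem sizes (100 subjects per group for cohort recovery,
  32–36³ grids, 20 acquired phases) are the package's desk-scale defaults,
  chosen so each cohort runs in a couple of minutes on one CPU.
* The single-subject runner persists its resolved configuration, and all
  randomness flows from the config seed; repeated runs are byte-identical.

## Known limitations

* Stationary-tissue selection is threshold-based; heavily wrapped or very
  noisy acquisitions may need relaxed thresholds, and slow-moving blood
  near region boundaries biases the eddy fit slightly (quantified above).
* Temporal-only unwrapping cannot recover wraps present already at phase
  0 or steps larger than venc between phases.
* The KE/CI index divides a per-beat energy by a flow index, as
  conventionally tabulated; it is reported as-is without dimensional
  reinterpretation.
* Masks are treated as given inputs; no contouring or registration is
  performed.
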