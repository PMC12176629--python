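# Methods

`rimpet` implements a quantitative pipeline for phenotyping chronic
inflammatory white-matter lesions on TSPO PET, together with the
histological and clinical analyses that anchor the imaging phenotype:
rim morphometry on stained sections and EDSS-based progression labels.
Everything is exercised on synthetic phantoms and cohorts with known
ground truth; no patient data are required.

## Kinetic quantification

Specific tracer binding is expressed as the distribution volume ratio
(DVR) estimated by reference-region Logan graphical analysis.  For a
target curve C_T(t) and reference curve C_ref(t),

    ∫₀ᵗ C_T dτ / C_T(t) = DVR · [∫₀ᵗ C_ref dτ + C_ref(t)/k2′] / C_T(t) + b

becomes linear for t ≥ t*; the slope is DVR = BP_ND + 1.  Integrals are
trapezoidal from t = 0 (activity taken as 0 at t = 0 when the first frame
is later).  The C_ref/k2′ term needs the reference efflux rate k2′, which
is generally unknown for clinical data; `logan_reference_dvr` therefore
omits it by default and accepts `k2_ref` when it is known (for simulated
data it always is).  Omitting the term biases the slope downward for
slowly equilibrating regions — about −0.01 at BP_ND = 0.5 and −0.15 at
BP_ND = 2 under the default simulation kinetics — which is why the
recovery tests pass the known k2′ while a separate test documents the
accuracy of the omitted-term default at moderate binding.

Defaults: t* = 20 min on a 60-min acquisition (leaves 5 late frames on
the default framing), voxel TACs that are non-positive anywhere at
t ≥ t* map to a NaN sentinel rather than aborting a parametric map.

The forward simulator is the simplified reference tissue model (SRTM),
C_T = R1·C_ref + (k2 − R1·k2a)·(C_ref ⊗ e^(−k2a·t)), k2a = k2/(1+BP_ND),
evaluated with an exponential-integrator recursion on a 0.01-min grid.
A stiff-ODE integration of the equivalent differential system is kept as
an independent oracle in the tests (agreement to 1e-4 relative).
Simulation defaults: gamma-variate reference input peaking at 8 min,
R1 = 1, k2 = 0.1 /min — ordinary bolus kinetics for a reversible
myeloid-targeted tracer.

## Perilesional shell geometry

Lesions are 26-connected components, labelled in decreasing volume order,
and only lesions strictly larger than 50 mm³ are phenotyped.  Perilesional
shells are defined in physical millimetres on anisotropic grids: band k is
the set of voxels whose centre lies within (k·step, (k+1)·step] mm of the
lesion boundary, with step = 2 mm out to 4 mm, minus every lesion's voxels,
clipped to the brain domain mask when one is given.

The distance is measured to the lesion *boundary surface*, discretised as
the midpoints of faces separating lesion from background voxels — the
0.5-level surface of the mask.  A plain distance transform to lesion voxel
centres would place the surface half a voxel too deep and shrink a 2-mm
shell around a 4-mm sphere by ≈ 23% in volume; the boundary convention
reproduces the closed-form annulus volume to ~1% (voxel-centred sphere).
The transform is computed exactly (verified against a brute-force oracle)
by running the EDT on a factor-2 supersampled lattice where face midpoints
are grid points.  Shells of distinct lesions may overlap (each lesion is
phenotyped independently), but no shell ever contains any lesion's voxels.
Interval edges are half-open, (0, 2] and (2, 4], so the perilesional band
is partitioned without gaps or double counting.

## Lesion phenotyping rules

A voxel is **active** when its DVR strictly exceeds the activity
threshold.  The threshold ships as 1.3624 (healthy-control white-matter
mean + 1 s.d.); `calibrate_threshold` recomputes mean + 1 sample s.d.
(n−1 denominator) from control voxel values when they are available.
Equality with the threshold is always inactive/LOW.

Activity class, from the active-voxel percentage in the lesion core
(the full lesion mask) and in the 0–2 mm shell:

* **inactive** — 0% active voxels in both;
* **rim-active** — core 5–20% (inclusive) with rim ≥ 2× core, or
  core < 5% with rim ≥ core + 5 percentage points;
* **overall-active** — everything else.

Independently, each 2-mm shell is labelled HIGH when its *mean* DVR
strictly exceeds the threshold, and a lesion with the HIGH–HIGH pattern is
a radiological broad-rim lesion (rBRL).  The two taxonomies overlap by
design; an rBRL may carry any activity class.  An empty shell (lesion at
the domain edge) is labelled LOW with a logged warning.

## Histological morphometry

Rim width follows the interedge procedure: the outer myeloid edge is
resampled every 100 µm of arc length (starting at its first vertex, for
reproducibility) and, at each sample, the shortest Euclidean distance to
the inner myelin edge is taken point-to-segment against the inner
polyline.  Samples flagged as unassignable may be excluded through a
validity mask and are dropped from the mean.  A histological BRL is a
*mixed* active/inactive lesion whose **mean** rim width is ≥ 1 mm; the
mean is used because reported rim sizes are averages, and a minimum-width
criterion would be hypersensitive to contour noise (median and
fraction-above summaries are available as options).

Scores: remyelination 0–3 with boundaries at 10%/50%, "complete"
operationalised as ≥ 99% of the lesion area to tolerate pixelation;
spinal demyelination 0–5 with 0 reserved for exactly no demyelination and
positive fractions binned in half-open 20% intervals, (0, 0.2] → 1 …
(0.8, 1.0] → 5.  Cortical lesions are a per-block rate (lesions per tissue
block with visible cortex); brain-stem lesion load is an area fraction.
Cell densities are means over ≥ 10 square visual fields (default 500 µm)
placed uniformly at random, seeded, with all corners inside the ROI.

## Progression and cohort analysis

The progression call is made against the EDSS at PET imaging (last
assessment at or before the imaging date): an increase of > 1.5 when the
baseline is 0, > 1.0 for baselines 1–5.5, and > 0.5 for baselines ≥ 6,
confirmed by a later assessment ≥ 6 months after the qualifying visit
that still exceeds the same fixed baseline by the same margin.  The
published strata leave EDSS 6.0 unassigned; it is placed in the 0.5-point
stratum for contiguity.  Progressor speed over the disease course: fast =
EDSS ≥ 4 within 12 years of onset, slow = all assessments after 12 years
below 2 (with at least one such assessment), else intermediate.  The
milestone comparator (≥ by default) is configurable because "reaching" a
milestone and "exceeding" it are both defensible readings.

Patients partition into rBRL / non-rBRL rim-active / neither (in that
precedence).  Group comparisons use Fisher's exact test — full
enumeration of 2×2 and 2×3 tables with fixed margins, summing
probabilities no larger than the observed table's (cross-checked against
an independent hypergeometric oracle and scipy's 2×2 implementation) —
plus Mann–Whitney U and Spearman rank correlation via scipy.

## Synthetic data: what it does and does not emulate

* **TACs** — noiseless (optionally Gaussian-noised) SRTM curves from a
  gamma-variate reference.  No scanner noise model, no decay correction
  issues, no motion.
* **DVR phantoms** — spherical or ellipsoidal lesions painted by
  *continuous* signed distance from the lesion surface (exact for
  spheres; bisection point-to-ellipsoid projection otherwise), so the
  generator's geometry is an independent oracle rather than a reuse of
  the pipeline's transform.  Default levels (background 1.0, LOW 1.2,
  HIGH 1.6) straddle the 1.3624 threshold with ≥ 0.15 margin so that
  voxelisation cannot flip a rim-mean label.  One pattern is genuinely
  unforceable at voxel resolution: an inactive core and inactive inner
  rim with an active outer rim, where the exact-0% inactive rule depends
  on sub-voxel contamination across the 2-mm line; the ground-truth table
  flags it (`activity_forced = False`) and the random suite substitutes
  an active core there while keeping all four HH/HL/LH/LL rim patterns.
  No partial-volume blurring or scanner PSF is modelled, so passing the
  recovery tests shows rule- and geometry-correctness, not robustness to
  resolution effects.
* **Histology phantoms** — circular lesions with annular rims of exact
  width (360-vertex polygons; chord error ≪ 1 µm) and homogeneous Poisson
  cell point processes per compartment.  Real rims are neither circular
  nor uniform.
* **Cohorts** — default 100 patients, rBRL prevalence 0.342, baseline
  fast-progression probability 0.25, planted odds ratio 5, assessments
  every 6 months for 16 years, imaging at year 5.  EDSS trajectories are
  monotone step curves consistent with the drawn status; real EDSS
  timelines fluctuate and can improve.

## Numerical choices and degenerate inputs

Strict inequalities at every rule threshold put boundary cases in the
lower class, matching the convention that only values *above* the
reference level are aberrant.  Half-open interval conventions are stated
with each rule above.  Lesions touching the domain boundary keep clipped
shells and log a warning rather than erroring.  Logan fits require ≥ 3
late-time points; parametric maps sentinel individual bad voxels.  All
generators are pure functions of (spec, seed); Fisher enumeration uses
log-gamma arithmetic with a 1e-9 relative tie tolerance.

## Problem sizes in the shipped checks

The test-suite and acceptance computations use phantom grids ≤ ~32³
voxels at 1 mm, 200-lesion phantom suites, 100-patient cohorts with
50 (effect) and 200 (null) replicates, and 120–200-pixel section masks.
These sizes give stable statistics for every check while keeping the
whole suite in the tens of seconds on a single CPU.

## Known limitations

The rim geometry assumes a single fixed grid per study (no resampling or
registration).  The Logan implementation is reference-region only; no
plasma-input variant.  No longitudinal lesion tracking.  The BRL call's
1-mm criterion is applied to the mean width; if the underlying criterion
were a minimum width, calls on irregular rims would differ.  The Fisher
2×3 enumeration is exact but quadratic in cohort size; it is intended for
cohorts up to a few hundred patients.
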