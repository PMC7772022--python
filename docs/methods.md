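# Methods

`femfall` reimplements, as one reproducible pipeline, a DXA-based
biomechanical workflow for hip-fracture risk: patient-specific 2D
finite-element simulation of a sideways fall, reduction of the result to
a fixed 39-attribute vector, two-step feature selection, and benchmarking
of standard classifiers on the fractured/control labels.  Because the
original clinical scans are not redistributable, the package ships a
synthetic-cohort generator whose statistical structure matches the
published study population; everything downstream operates identically on
real segmented scans supplied through `pipeline.ingest_external`.

## Synthetic cohort

The generator emulates a cohort of 137 postmenopausal women (89 with a
fall-related hip fracture, 48 controls).  Clinical covariates (age,
height, weight, total areal BMD) and seven femur morphometrics (NW, HAL,
NSA, SAL, ITW, STW, FA) are drawn per group from truncated Gaussians at
the published group means and SDs (±4 SD, floored at physical minima;
NSA confined to 108–145° because the 2D silhouette degenerates outside
that range).  BMI is always *derived* from height and weight so the
exact BMI→STH→FAT chain holds in every record.  Attributes are sampled
independently except for three mutual-consistency rejections: widths
must be positive, the calcar overhang may not swallow the greater
trochanter, and the drawn femur area must be renderable by the
silhouette family given the six linear measurements.  Because those
rejections bias the accepted marginals slightly, the proposal means
carry small fixed offsets (calibrated once at n = 20 000 per group) so
accepted means land within Monte-Carlo error of the published targets.

Each subject receives a rendered scan: a parametric proximal-femur
silhouette (shaft → intertrochanteric trapezoid → oblique neck strip →
head disc, plus optional trochanteric crest and diaphyseal waist)
rasterised at the DXA pixel pitch of 0.6 mm × 1.05 mm onto a 256×192
canvas.  A single monotone *bulk* parameter drives the four features not
pinned by any measurement — head radius, medial/lateral waist bites,
waist width, crest height — and is bisected until the polygon area
matches the sampled FA.  Two geometric guards keep the morphometry
well-posed: the head disc is capped so it clears the trochanter and
never dips below the intertrochanteric line in projection, and the neck
strip is clipped at the trochanteric flank.  The intertrochanteric
width is realised as `max(0.4·ITW, (NW/2)/cos(180°−NSA)) + lateral
extent`, because the oblique inferior neck cortex (calcar) crosses the
intertrochanteric chord with half-span `(NW/2)/cosθ` and forms the
medial boundary there.

The BMD map is a two-level profile — a cortical rim (thickness
2 mm × BMD/0.75, clamped to 0.8–3.5 mm) at 1.55 g/cm² and a trabecular
interior at 0.64 g/cm², in pre-rescale areal units — plus white pixel
noise (SD 0.05 g/cm²), rescaled so the mask-mean areal BMD equals the
subject's total BMD exactly.  Group separation in all downstream tissue
and FE attributes emerges only from the lower BMD and thinner rim of the
fractured group; no FE-level quantity is injected directly.

What the generator does *not* emulate: DXA physics (scatter, beam
hardening), realistic cortical-thickness spatial variation, anatomical
inter-attribute correlations beyond the consistency constraints, and
male anatomy.  Passing tests therefore demonstrate that the pipeline
recovers what the generator encodes — primarily BMD-driven group
structure — not that it would reach the same accuracy on clinical data.

## Morphometry

All landmarks come from the mask alone.  The shaft axis is fitted in two
passes (horizontal band centroids, then chord centres perpendicular to
the first-pass axis) over the distal 40% of the mask; pose
standardisation rotates the scan in the physical mm frame until the
shaft sits 10° from vertical.  The head centre is the peak of the
in-mask Euclidean distance transform on the medial side, with a
most-medial-cluster tie-break for small heads; the neck axis joins the
head centre to the midpoint of the narrowest neck chord and is refined
twice.  SAL is measured from the distal axis entry to the intersection
of shaft and neck axes (a landmark construction that is stable at the
±1% level); ITW extrapolates the rising breadth profile of the
intertrochanteric flare to its peak (compensating the half-row raster
bias), on a working mask with the head disc scrubbed out; STW is the
breadth at 25% of SAL; HAL is the mask chord along the neck axis.  These
constructions replace a "semiautomatic" manual protocol and are
deterministic by design; the round-trip against the generator recovers
every parameter within 5% (NSA within 2°) for ≥90% of random femurs.

Regions of interest: the neck ROI is a 15 mm band perpendicular to the
neck axis centred on the narrowest section; the trochanteric ROI lies
between the subtrochanteric level and the junction, lateral of the shaft
axis, minus the neck band.  The trochanteric PMMA pad hugs the lateral
contour over b = 0.8·ITW with a flat outer face (so the applied pressure
integrates exactly); the head pad is an annular cap on the medial head
contour.  The out-of-plane thickness is t = 0.3837·NW: with the
published group-mean FP and HP values, both groups independently give
t ≈ 11.3 mm ≈ 0.3837·NW, so this single coefficient is fixed by that
calibration and then frozen.

## Fall model

STH = 2.3451·BMI − 33.444 (mm, female regression; clamped at 1 mm with a
warning), FAT = 71·STH (N), FP = FPK − FAT, HP = FP/(b·t) (MPa).  FPK
comes from a single-degree-of-freedom mass-spring impact:
v = √(2 g h), FPK = v·√(k·m_eff), with h a fraction of body height and
m_eff a fraction of body mass.  Only the product of the two fractions is
identifiable from group-mean data, and the two group targets imply
slightly different products (0.2003 vs 0.2025), so an exact joint fit
does not exist; the pelvis stiffness is fixed at the literature-standard
71 kN/m, the mass fraction at 0.5, and the hip-height fraction at
0.40294 (the geometric-mean fit), reproducing both group-mean peak
forces within ±0.3%.  Negative FP is flagged, not fatal.

## Finite-element model

Plane-strain, linear-elastic, constant-strain triangles.  The femur
contour (marching squares on the mask) and the two pad polygons are
meshed together by Delaunay triangulation over boundary points (every
polygon vertex plus per-edge subdivision) and a hexagonally packed
interior grid; triangles are kept when their centroid lies inside the
domain union and tagged femur > trochanteric pad > head pad.  The desk
default is 6 000 elements; the study-scale 60 000 is a config value.
Femur elements sample the BMD map bilinearly at their centroid; apparent
density is ρ = BMD/t_ref with t_ref = 1 cm, and E = 6850·ρ^1.49 MPa
(floored at 10 MPa), which places mean trabecular/cortical moduli at the
published 3.6/11 GPa scale.  (A larger t_ref would push every pixel
below the 1.0 g/cm³ cortical threshold and empty the cortical class, so
1 cm is the only consistent choice at this BMD scale.)  Pads are PMMA
(E = 1.5 GPa, ν = 0.37); bone ν = 0.3.

Boundary conditions: the distal 2.5 mm of the shaft is fully fixed and
the outer arc of the head pad is fixed in x (medial direction) only.
The hip pressure loads the flat lateral face of the trochanteric pad,
lumped so the resultant equals HP·b·t exactly.  Assembly is vectorised;
the reduced system is solved with a sparse direct factorisation.
Post-processing per element: in-plane principal stresses/strains,
σ_zz = ν(σ_xx+σ_yy), the 3D von Mises stress including σ_zz (the
plane-strain-consistent choice), and SED = ½ σ:ε reported in J/m³.
Verification: exact patch test, von Mises = 0.889σ for uniaxial plane
strain at ν = 0.3, equilibrium residual < 1e-6, tip-loaded cantilever
within 10% of Euler–Bernoulli with E/(1−ν²), rigid-translation
objectivity, and exact linearity in the load.

## Attributes

Cortical bone is apparent density strictly greater than 1.0 g/cm³; TB
and CT are area percentages (closing to 100 exactly) and TBE/CTE
area-weighted mean moduli.  Regional attributes are area-weighted means
over the neck and trochanteric element sets; MPStress/MPStrain take the
largest-magnitude principal value with its sign (their published
magnitudes track the compressive principal components).  FRI is the
area-weighted mean of von Mises over yield stress, with yield stress
E·ε_y and a uniform compressive yield strain ε_y = 7 300 µε (a standard
bone value; config-exposed, as no yield constants are published for this
workflow).  LSR grows a region greedily from the peak
|compressive-strain|/ε_y element through edge-adjacent neighbours until
9 mm², taking the minimum ratio inside; by the bottleneck property this
equals the optimum over all connected peak-containing regions of that
area, which the test suite verifies against an independent
threshold-component oracle (itself validated by exhaustive subset
enumeration on a tiny mesh).  FS = FP/LSR by linearity.

## Feature selection

z-score normalisation, PCA by SVD, and a relative loading floor (10% of
each component's largest absolute loading, first three components)
define the PCA contributors.  Pearson and mid-rank Spearman matrices are
combined into a joint |r| ≥ 0.9 mask.  Augmentation admits non-selected
attributes with ≥4 masked links to other non-selected attributes, then
reduces redundancy by greedy set cover; coverage ties prefer the more
routinely collected attribute group and, within a group, the most
downstream (composite) attribute — the preference that also motivates
the final pruning step, where FAT, STH (exact functions of BMI) and CT
(= 100 − TB) are removed in favour of their proxies.  On the reference
link audit this reproduces the published operating point: augmentation
{HP, S3_N, FRI_N, FRI_T} and the final eight {BMI, FPK, FP, HP, TB,
S3_N, FRI_N, FRI_T}; the 12-feature set appends NW, NSA, FA, SAL.  On
full-rank synthetic tables the z-scored PCA spreads loadings widely and
the contributor floor retains most attributes — the near-degenerate
loading pattern of the original data (33 components with ≈0% variance)
is not reproducible from summary statistics — so benchmarking uses the
fixed reference sets, while the data-driven path still prunes FAT, STH
and CT deterministically (their generating relations are exact).

## Classification

Stratified 70/30 splits (per-class floor), SMOTE oversampling of the
training set to 200 + 200 (synthetic point = x + u·(x_nn − x), u ~ U[0,1],
k = 5 same-class neighbours in standardised feature space; never applied
to test data), then: logistic regression; SVMs with linear, sigmoid and
Gaussian kernels, each optionally with Platt-calibrated posterior
thresholding ("PPR", implemented as sigmoid-calibrated decision values);
a Gaussian-process classifier with a squared-exponential kernel as the
Bayesian kernel machine; a Gini decision tree; and a random forest of
1 000 trees with depth cap 12.  SVM C = 1 with the scale gamma
heuristic (no values are published); the decision threshold defaults to
0.5.  Each stochastic model reports mean/SD/best of sensitivity,
specificity and accuracy over repeated seeded runs (default 1 000); the
random forest is evaluated on a single seeded run, since its internal
ensemble already averages over resamples.

## Problem sizes and reproducibility

The shipped defaults run the full 137-subject cohort at 6 000-element
meshes (≈0.5 s/subject); tests use 1 200–3 000-element meshes and
reduced run counts, and the parameter-recovery experiment uses three
cohorts at the default size with five RF splits per separation level.
A single global seed derives all stage randomness, so a fixed
configuration reproduces byte-identical attribute tables and reports;
`run_all` writes a manifest with the configuration hash (output
location excluded) and per-stage timings.

## Known limitations

* The silhouette family is a stylised 2D femur; cortical thickness is
  spatially uniform per subject, and trabecular anisotropy is absent.
* Classifier accuracies on synthetic cohorts reflect the generator's
  BMD-driven separation, not clinical performance.
* The male soft-tissue regression is unavailable; male records are
  rejected.
* Neck versus trochanteric fracture subtypes are not modelled.
* The FE model is static and linear: the load is the peak impact force,
  and failure measures (LSR, FRI, FS) are linear extrapolations, not
  post-yield mechanics.
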