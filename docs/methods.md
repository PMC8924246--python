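# Methods

This note documents the models, parameter choices and numerical decisions
behind each analysis stage, in the order data flows through the package.

## Data model

Localisations are 2D continuous positions in nanometres with a per-molecule
precision and a channel label; there is no pixel indexing anywhere (SMLM
renders are a display artifact, not the data model). Each table row is
treated as one molecule: repeated-blink merging (detection grouping) is
assumed to have happened upstream in the acquisition software. Regions of
interest are simple polygons; boundary points count as inside, a
deterministic convention applied uniformly by the clipper and by every
spatial statistic. Trajectories are 2D/3D positions in µm with strictly
increasing frames per track; when no absolute time column is present,
t = frame × Δt with Δt = 0.032 s by default (the frame interval of the
multifocal tracking acquisitions this is designed around).

## Ripley's K and L(r) − r

The estimator is the standard unbiased form with the ROI area A and
ordered-pair weights. Edge correction defaults to isotropic Ripley
weighting: each pair (i, j) is up-weighted by the inverse of the fraction
of the circle of radius d_ij centred on i lying inside the ROI.
Uncorrected K is biased low near boundaries, and the calibration property
that L(r) − r averages to zero under complete spatial randomness only
holds cleanly when corrected; an uncorrected mode is kept for brute-force
oracle tests. For axis-aligned rectangles the weight has a closed form
(for r up to half the shorter extent, which the precondition enforces, a
circle can cross at most two adjacent edges; the exterior arc is
2β₁ + 2β₂ − max(0, β₁ + β₂ − π/2) with β = arccos(e/d) for each sub-radius
edge distance e). General polygons use numerical arc sampling (256 angles
per pair) through shapely; this path is intended for the small tables
irregular nuclear ROIs produce, while the rectangle fast path carries the
large calibration runs.

The default radii grid is 10–500 nm in 10 nm steps, spanning the 120–200 nm
clustering peaks typical of nuclear MVI/RNAPII patterns with margin. The
peak radius is the argmax of L(r) − r with ties broken toward the smallest
radius; a curve that never rises above zero is flagged "no peak" (NaN)
rather than returning a meaningless argmax.

## Density-based cluster detection

DBSCAN with the SMLM parameterisation: ε defaults to the mean localisation
precision of the dye (20 nm for Alexa-647-class, 30 nm for
Alexa-488-class tables), MinPts = 3 with the neighbour count *excluding*
the query point (three other molecules in the search area), and
density-connected groups below 10 localisations revert to noise. The
labelling is implemented directly over cKDTree region queries so the
border-point rule is explicit: points are scanned in index order and a
border point joins the first core cluster whose expansion reaches it,
making labels deterministic for a given row order (shuffling rows permutes
cluster ids but never changes memberships). An alternative ε policy —
assigning the Ripley peak radius r_max as ε — is available as
`epsilon_from="ripley"` and is recorded in every pipeline report, because
both conventions exist in practice and they can differ several-fold.

Cluster area is the area of the iso-density contour of a Gaussian
kernel-density surface with 7 nm bandwidth, taken at the level that
encloses all member localisations and integrated on a 5 nm grid. Groups of
3–4 members fall back to the convex hull; collinear or smaller groups are
flagged degenerate with area 0. The contour choice reflects that the
smoothing bandwidth is part of the cluster-map generation; whether
published "cluster areas" from comparable tools are contour, hull or
occupied-pixel areas is generally unstated, so the convention here is
documented rather than asserted as canonical.

## Degree of colocalisation

For each molecule, same- and other-channel neighbour counts are
accumulated at radii r_step, 2·r_step, …, r_max (defaults 20 nm and
500 nm), normalised by the count at r_max and by r² to form density
gradients; the score is the Spearman rank correlation of the two gradient
vectors (average-rank ties — ties are common on discrete counts and
average ranks keep the identity case at exactly 1), damped by
exp(−d/r_max) with d the nearest-other-channel distance. Coincident points
are legal: d = 0 gives damping 1. Cross-channel counts exclude
exactly-coincident molecules, mirroring the self-exclusion of the
same-channel count; for continuous coordinates this is a measure-zero
convention, and it makes a channel scored against its own copy return
exactly 1 everywhere the gradient is defined. Degenerate gradient vectors
(no neighbour at r_max, or zero variance) score 0 and are flagged rather
than returning NaN, keeping percentage denominators well defined.

Molecules above the 0.4 threshold are colocalised; a cluster is
colocalised when at least 5 of its members are (both parameters exposed —
the 5-member convention follows common practice in coordinate-based
colocalisation tools and is not asserted as a measured fact).

## Trajectory analysis

Time-averaged MSD uses all overlapping frame pairs; gaps contribute no
pairs at the lags they span. The anomalous model is fitted as a straight
line in log-log space over the first 25% of available lags (clamped to
3–10): the slope is α and the intercept log(2·d·D) gives D, with d = 3
when a z column is present and 2 otherwise. The log-log linear fit is
deterministic (no initial-guess sensitivity) and exact in the noiseless
limit; no localisation-error offset term is included by default: at the 20 nm
error and 32 ms frame interval these data are acquired with, the offset
(2·d·σ² ≈ 0.002 µm²) is small against the first-lag MSD of tracks near the
static/diffusive boundary and above, and an optional constant-offset
variant covers slower regimes. Classification is a pure
function of D: static below 0.1 µm² s⁻¹, diffusive up to 5, hypermobile
above, with boundary values (exactly 0.1 or 5) classed diffusive since the
defining inequalities are strict and leave the boundaries open.
Hypermobile tracks are counted in the static/mobile fractions but excluded
from mean-D summaries.

The optional linker is greedy nearest-neighbour between consecutive
frames, shortest candidate link first, with no link beyond 0.4 µm and
tracks below 10 frames discarded. It honours only those stated
constraints; it does not reproduce any particular tracking package's cost
function.

## Enzyme kinetics and CD

The ATPase model Rate = V₀ + k_cat·[A]/(K_actin + [A]) is fitted by
bounded trust-region least squares with all parameters constrained
non-negative (rates and binding constants are physical; unbounded fits on
noisy titrations wander negative). Initial guesses: V₀ = minimum rate,
k_cat = rate range, K_actin = concentration nearest the half-rise.
Tolerances are tightened to 1e−14 so noiseless data recover parameters to
better than 1e−6 relative. Units are fixed (µM, s⁻¹); conversions belong
at the I/O boundary. Mean residue ellipticity is the direct formula
(MW/(n−1))·θ / (l·c·10).

## Synthetic data: what it emulates, and what it does not

Clustered patterns are Thomas processes — uniform cluster centres, Poisson
per-cluster counts, isotropic Gaussian offsets — plus uniform background
and Gaussian localisation jitter. Defaults target the measured regime of
nuclear myosin VI (504 clusters of ≈64 molecules in a 10 µm square ROI,
20 nm spread, 19% background to match 81% of molecules clustered, 20 nm
precision). The non-clustered background fraction of real nuclear data is
not directly measured, so it is a free parameter rather than an asserted
value. Two-channel patterns share a controllable fraction of cluster
centres, displaced by Gaussian noise; the shared fraction is recorded as
ground truth. Anomalous tracks are fractional Brownian motion with Hurst
exponent α/2, scaled so the ensemble MSD is 2·d·D·τ^α; fBm is the standard
stationary-increment process with exactly the fitted power-law MSD.
Default track settings (200 tracks × 100 frames, Δt 32 ms, 20 nm
localisation error, D = 0.4 µm² s⁻¹) mirror the live-cell regime; the
kinetics defaults use the wild-type k_cat of 5.5 s⁻¹ and, since no fitted
K_actin is reported for these constructs, K_actin = 10 µM from the
physiological range for actin-activated myosins.

Deliberately not emulated: fluorophore photophysics (blinking, repeated
localisations of one molecule), camera noise, drift, 3D point patterns for
the STORM arm, and particle-detection errors. Tests passing on these
simulations therefore demonstrate that the estimators recover the
statistical structure they model — not that they are robust to blinking
artefacts or detection failures, which upstream processing is assumed to
have handled.

All generators draw from named, seed-derived random streams, so adding a
consumer of randomness never perturbs existing draws, and ground truth is
returned on outputs separate from the data tables so analysis code cannot
consume it.

## Statistics and orchestration

Condition comparisons use a two-sided two-sample t test with pooled
variance (Welch by flag), treating each cell ROI as one observation; no
multiple-testing correction is applied by default (Holm available), since
per-comparison significance is the convention in the imaging literature
this targets. Identical zero-variance groups report p = 1 with a flag.
Pipeline outputs are written with a fixed float format and the resolved
configuration (including the ε policy) is serialised alongside, so a rerun
with the same config and seed is byte-identical.

## Problem sizes used in the test suite

The conformance suite runs at the scales it states: 20 CSR replicates of
5,000 points for the L(r) − r calibration; 20 seeds of 250-cluster Thomas
patterns (~16,500 points each) for cluster recovery; 200 tracks × 100
frames for the tracking arm; 100 replicate titrations for kinetics; 100
random instances per brute-force oracle comparison at ≤ 120 points or
≤ 50 frames, where exhaustive enumeration is exact and fast. These sizes
make the whole suite complete in well under a minute while keeping every
statistical tolerance at its stated value.

## Known limitations

- The isotropic correction's polygon path is O(pairs × angles) and meant
  for modest tables; very large patterns in irregular ROIs should use a
  bounding rectangle or the uncorrected mode.
- DoC percentages depend on labelling density in both channels;
  cross-condition comparisons should hold acquisition settings fixed.
- The greedy linker is order-dependent in dense fields and is not a
  substitute for global-assignment tracking; it exists to honour the
  stated displacement/length constraints on pre-detected positions.
- log-log MSD fitting is biased when localisation error dominates the
  first lags (very slow tracks at short Δt); the constant-offset variant
  of the model is the appropriate tool there.
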