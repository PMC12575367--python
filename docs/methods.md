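# Methods

`radialign` quantifies three readouts of an equibiaxial cell-stretching
experiment on a radially micropatterned elastic membrane: the planar
deformation field of the membrane (from embedded fiducial beads), the
alignment of cells to the radial topography, and the persistence of cell
migration under combined mechanical and topographic stimulation.  Because
such experiments rarely ship with raw imaging data, the package pairs every
estimator with a synthetic scene generator that produces the same data types
with exact analytic ground truth; all tests are parameter-recovery tests
against that truth.

## Conventions

All angles are reported in degrees, counter-clockwise positive, measured
from the +x axis in the usual mathematical sense.  Positions are stored in
micrometres in image coordinates (x along columns, y along rows, y grows
downward); the single y-flip between the two conventions lives in
`angles.polar_angle_deg`, and every other function goes through it.
Orientations of elongated objects (nuclei, actin texture, pattern stripes)
are *axial* — defined modulo 180°, with differences wrapped to [-90°, 90°).
Step headings and turning angles are *directional*, wrapped to (-180°, 180°].
A pixel index i covers the interval [i, i+1) pixels, so its centre sits at
(i + 0.5) · pixel_size µm; rendering and measurement share this convention.

Randomness: one root seed per scene; each component (bead placement,
localization noise, cell placement, migration, rendering) draws from an
independent child stream derived from it, so adding noise to one component
never perturbs another.

## Synthetic scenes

**Geometry.** Defaults are a 512×512 px field of view at 1.3 µm/px (10×
objective scale), a 300 µm-radius deformation pillar centred in the image,
and a 1 min frame interval.  Bead movies span 11 frames (deformation onset
to 10 min), migration movies 60 frames (a one-hour observation window).

**Radial micropattern.** Alternating ridges and grooves run radially; the
local pattern orientation at a point is, exactly, the polar angle of the
point about the pattern centre modulo 180°.  Keeping stripe arc widths
inside the fabricated bounds (ridges at most 5 µm, grooves at least 2 µm)
over a growing radius requires subdividing: the number of stripes per full
circle doubles at radii R_k = m_k · w_max / 2π, so the arc width of any
stripe stays in [w_max/2, w_max].  This rule is feasible precisely when
w_max ≥ 2 · w_groove_min, which the 5 µm / 2 µm bounds satisfy; the exact
subdivision geometry of the physical mask is not dimensioned beyond those
bounds, so this is one admissible realization, and it is the one the
generator and the tests use.  Alternating equal-angle stripes cover exactly
half the annulus area, which the rasterization test cross-checks.

**Deformation fields.** Two kinds are prescribed (not solved from membrane
mechanics — a deliberate non-goal): an affine field u(p) = (A − I)(p − c),
and an axisymmetric radial profile u(p) = g(r) r̂ with g(0) = 0 and g
monotone.  For the radial profile the analytic deformation gradient in the
local polar frame is diag(1 + g′(r), 1 + g(r)/r) (radial, tangential), with
the limit (1 + g′(0)) I at the centre.  The built-in profiles are
g(r) = s·r (uniform equibiaxial strain s) and g(r) = ε r²/R, whose strain
grows linearly from centre to rim — the gradient-from-centre behaviour seen
on a membrane stretched over a pillar.  A linear per-frame ramp models the
pressure ramp to a held plateau; ε = 0.1 gives the ~10 % physiological
strain scale at the rim.  Beads are advected materially (Lagrangian), with
i.i.d. Gaussian localization noise per frame (default 0.1 µm, a realistic
sub-pixel centroid accuracy).

**Migration.** Persistent random walks: per-step speeds are lognormal,
turning angles von Mises with concentration κ about the previous heading
(κ = 0 is an uncorrelated walk, κ → ∞ a straight line).  Two optional
biases reproduce the qualitative phenomenology of the four experimental
conditions: a common drift direction (collective motion of unstimulated
monolayers) and an axial pull toward the local radial direction (stretch
guidance).  The presets are

| condition            | κ   | (log-mean, log-sd) speed | bias            |
|----------------------|-----|--------------------------|-----------------|
| flat undeformed      | 0.3 | (ln 0.40, 0.40)          | drift 35°, w=0.35 |
| patterned undeformed | 0.3 | (ln 0.45, 0.38)          | drift 35°, w=0.35 |
| flat deformed        | 1.5 | (ln 0.55, 0.30)          | radial, w=0.15  |
| patterned deformed   | 3.0 | (ln 0.65, 0.20)          | radial, w=0.30  |

The orderings are the structural content — deformed conditions are more
persistent than undeformed ones, and deformation on the pattern gives the
highest persistence and the highest, narrowest speed distribution; the
specific numbers are fixed once at scales typical for slow-moving
cardiomyocyte-like cells (~0.5 µm/min, about one cell body per hour).
Boundaries reflect (positions and headings), avoiding the truncation bias
that absorbing or disappearing tracks would introduce at this field size.

**Rendering.** Beads become Gaussian spots of configurable σ; nuclei become
filled ellipses.  Noise is Poisson shot noise plus Gaussian read noise; the
spot amplitude is solved from a peak-SNR specification
SNR = A/sqrt(A + B + σ_read²).  Rendering is deliberately simple — no PSF
tails, no photobleaching, no background structure — so round-trip tests
exercise the detectors, not a microscope model.  What passing tests show is
therefore that the estimators are correct and well-calibrated on data obeying
their model assumptions; they do not certify performance on real micrographs
with debris, uneven illumination or overlapping cells.

## Deformation-field reconstruction

Spots are detected as local maxima of the scale-normalized
Laplacian-of-Gaussian response above a threshold (default: median + 5 MAD of
the response) and refined to sub-pixel by an intensity-weighted centroid in
a (4σ)² window.  Linking is the classic two-step scheme: globally
cost-ordered greedy nearest-neighbour assignment between consecutive frames
under a displacement gate, then gap closing that joins segment ends across
up to `max_gap` missing frames within `max_disp · gap`.  Cost ties resolve
deterministically by lowest index pair.  Greedy assignment (rather than a
full linear assignment problem) is an accuracy/complexity trade-off that is
exact whenever inter-bead spacing exceeds the per-frame displacement, which
the bead experiments satisfy by design.

The displacement field between a reference and a target frame uses only
tracks present in both; fewer than three is refused as underdetermined.
The deformation gradient F = ∂x/∂X (reference configuration) is estimated on
a square grid clipped to the pillar disc (spacing R/20 by default) by
weighted least squares of the local affine model
u_i ≈ a + (F − I)(p_i − node), with Gaussian kernel weights of bandwidth
half the neighborhood radius.  The default neighborhood radius adapts to
bead density, max(1.5·spacing, R·sqrt(10/n)) — about ten beads of support —
so the smoothing scale, and with it the curvature bias of the affine model
where the true field bends (strongest near the pillar centre, where the
radial field is non-smooth), shrinks as beads densify.  Nodes with fewer
than three beads or collinear support are masked, never extrapolated; each
node reports its support count and RMS residual so low-quality regions can
be filtered downstream.

The right polar decomposition F = R·U (scipy's polar) separates rotation
from pure stretch: reported are the rotation angle, principal stretches
λ1 ≥ λ2, maximum shear (λ1 − λ2)/2, the off-diagonal magnitude of F itself,
and the equibiaxiality index λ2/λ1.  A perfectly working equibiaxial
stretcher gives rotation ≈ 0, off-diagonals ≈ 0 and λ2/λ1 ≈ 1; an injected
rigid rotation is recovered quantitatively, which serves as the negative
control.  Strain is summarized as (λ1 + λ2)/2 − 1 and band-averaged over
equal-width annuli (three by default) to expose the radial gradient.
Displacement magnitude maps use inverse-distance-weighted interpolation,
masked outside the convex hull of the beads.

## Alignment statistics

The pillar is partitioned into 10° θ-sectors (36 of them); a point exactly
on a boundary belongs to the higher-index sector.  The angular alignment of
an object is γ = orientation − sector orientation, wrapped axially to
[-90°, 90°), where the sector orientation is the axial angle of the sector's
bisecting radius.  Because γ is measured against the bisector rather than
the exact local radius, it carries the within-sector spread of the pattern
orientation on top of any biological noise: for sector width w and cell
noise s, sd(γ) = sqrt(s² + w²/12) (≈ 2.9° extra at w = 10°).  The tests use
this corrected expectation as their oracle.

Two orientation estimators are provided: per-object second-moment ellipse
orientation from a label image (primary for nuclei; near-circular objects
with axis ratio < 1.05 are flagged unreliable and excluded, as are
border-touching objects), and a tile-level structure-tensor orientation
histogram whose smoothed mode is the dominant orientation (primary for
actin texture; tiles with gradient-energy-weighted mean coherence below 0.5
are flagged isotropic).  Both are exposed for either kind.

γ is summarized by a maximum-likelihood normal fit on the raw angles
(primary) and a least-squares Gaussian fit to the binned histogram (reported
for parity with histogram-level workflows), plus a wrapped (angle-doubled
circular) sd as a cross-check; for σ ≤ 20° the wrapping correction is
negligible.  Per-sector axial circular means (computed by angle doubling)
regress on sector orientation by OLS; a pattern-following population gives
slope ≈ 1 and intercept ≈ 0, a pattern-ignoring one slope ≈ 0.  The mod-180
sector mean is moved to the sector's branch (± 180°) only when it lies
within 45° of the sector orientation — this lets aligned populations regress
linearly across the 0°/180° seam without forcing a unit slope onto arbitrary
data.  Sectors need at least 5 objects (n_min, a choice) and a
non-degenerate circular mean.  The whole γ pipeline repeats within annular
r-bands (three equal-width bands by default) to test whether the radial
strain gradient perturbs alignment; bands with fewer than 10 records are
reported as insufficient rather than fitted.

## Migration statistics

Step directions are atan2 angles of frame-to-frame displacements; steps
shorter than a configurable floor (stationary frames at the localization
noise scale) are excluded from angle statistics.  Turning angles are wrapped
differences of consecutive step directions; a track with k usable steps
contributes k − 1 of them.  Persistence is the mean resultant length of the
turning angles (1 for straight motion, → 0 for uncorrelated walks).  Rose
diagrams bin per-step directions by default — per-track net directions are
available by flag, and outputs record which mode was used, since the two
emphasize different things and the field uses both.  Per-track mean speeds
(path length / elapsed time) get a lognormal fit — the MLE is the normal
MLE on log speeds — and the reported headline speed is the pdf peak (mode)
exp(µ_log − σ_log²).

Condition comparisons use the two-sample Kuiper statistic
V = D⁺ + D⁻ = max(F₁ − F₂) + max(F₂ − F₁) on the circle, the
rotation-invariant circular analogue of Kolmogorov–Smirnov.  The running
ECDF difference is accumulated in integer arithmetic and evaluated only
after each run of tied pooled values, which makes V *bitwise* invariant
under a common rotation of both samples and exactly zero for identical
samples.  The primary p-value is a label-permutation p,
(1 + #{V_perm ≥ V_obs})/(1 + B), valid at any sample size; the asymptotic
tail formula with effective size n₁n₂/(n₁+n₂) is reported alongside when
both groups have n ≥ 20.  Because V is discrete at small n, the
tie-inclusive permutation p is conservative — at n = 30 per group the
realized type-I error at α = 0.05 is about 3.5 % rather than 5 % — which is
the standard, validity-preserving behaviour.  Pairwise condition tests are
Holm–Bonferroni adjusted (statsmodels).

## Morphology and viability

Cell area and aspect ratio come from global thresholding (Otsu by default),
connected components, and moment-ellipse axes; aspect ratio doubles as the
polarity readout.  Touching cells merge into one record — a documented
limitation of global thresholding — and the interface accepts externally
produced label images so segmentations from learned classifiers can be
plugged in; no classifier is bundled, since none is specifiable from
first principles.  Live/dead counting thresholds the calcein (green) and
propidium-iodide (red) channels separately and counts components;
double-positive objects count as dead, because PI positivity dominates
interpretation.  Percentages are normalized to the total counted.
Group tests are one-way ANOVA and Kruskal–Wallis (tie-corrected), with
Holm-adjusted pairwise Mann–Whitney post-hocs, refusing groups with n < 3.

## Problem sizes and numerical choices

Test and demo problem sizes are chosen so each estimator operates in its
designed regime: 300–500 random beads for noisy-field recovery (≈ 10 beads
per estimation neighborhood), a 6 µm regular bead lattice for the
sharp-tolerance noiseless checks (symmetric support cancels the
leading-order curvature bias of the local affine fit), 500 cells per
alignment population (≈ 14 per sector), 20-seed replication wherever a
tolerance is placed on an average, 40 walkers × 60 min per migration
condition, and 100–200 seeds with 199–499 permutations for power and
calibration studies.  Degenerate inputs are flagged rather than silently
fitted: zero-variance γ or speeds, non-positive det(F), empty strain bands,
blank images, isotropic tiles.

## Known limitations

Everything is 2-D: out-of-plane displacement is excluded by design, matching
what in-plane imaging of the stretched membrane can validate.  The greedy
linker degrades when per-frame motion approaches the inter-object spacing
(a LAP linker would be the upgrade path).  The γ statistic inherits the
sector-width spread described above; reducing the sector width trades it
against per-sector counts.  The synthetic scenes make no attempt at
photorealism, and parameter-recovery results transfer to real data only to
the extent that detection and segmentation upstream perform as well as they
do on the rendered fixtures.
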