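# Methods

This note documents the models, conventions and numerical choices behind
`detkit`, and what the synthetic benchmarks do and do not demonstrate.

## Lattice comparison

**G6 embedding.** A cell (a, b, c, α, β, γ) is represented as
g = (a², b², c², 2bc·cos α, 2ac·cos β, 2ab·cos γ), all components in Å².
All inter-cell distances are measured in this space, which makes them
dimensionally consistent with the dendrogram-cut threshold (Å²). The
Euclidean option therefore also operates on reduced G6 vectors, not on raw
(a, b, c, α, β, γ) tuples, whose components carry mixed units.

**Niggli reduction** is performed with gemmi's `GruberVector`
(Krivý–Gruber steps with epsilon-stabilized comparisons and change-of-basis
tracking; iteration cap 100). The returned change of basis M is an integer
matrix with det ±1 satisfying `Mᵀ G_original M = G_reduced`. Reduction
terminates on a *tight* stability epsilon of 1e-9 relative to the largest
squared cell edge. This tightness matters: with a looser epsilon (e.g. 1e-5
relative, ≈0.02 Å² for a 47 Å cell) the reduction can stop one boundary
step short of the canonical form, so that two bases of the same lattice
reduce to *different* near-reduced cells — we observed same-lattice
distances of ~16 Å² in exactly this situation. Tolerance belongs in
*comparing* cells (the metrics, the clustering threshold), not in the
reduction itself. `is_niggli_reduced(cell, tol=1e-5)` provides an
independent check of the standard main + special Niggli conditions at a
user tolerance.

**Symmetry-aware distance (`ncdist`).** Near the boundary of the Niggli
cone, one lattice has several almost-reduced descriptions, and the plain
Euclidean G6 distance between two such descriptions can be large. `ncdist`
compensates by minimizing the reduced-G6 Euclidean distance over a fixed
set of lattice-preserving transforms applied to either operand: the 24
distinct metric actions of the 48 signed axis permutations, the 7
Krivý–Gruber boundary shears (both shear signs plus the face/body-diagonal
transform), and all two-way compositions of the two families (286 distinct
actions after deduplication; M and −M act identically on a metric tensor).
This is a deliberate finite-transform stand-in for the full
Andrews–Bernstein manifold-embedding NCDist algorithm, which is out of
scope here. Its guarantees, enforced by tests: never exceeds the Euclidean
distance (the identity is in the set), symmetric by construction (both
directions evaluated), and zero (≤1e-6 Å²) for any two parameterizations of
the same lattice — verified against a brute-force oracle that enumerates
all 3×3 integer matrices with entries in {−1, 0, 1} and det ±1 (3 480
transforms). The finite set is not guaranteed to find the globally shortest
symmetry-aware path for lattices many boundary steps apart; for such pairs
`ncdist` is an upper bound that still improves on the Euclidean distance.

## Clustering

Single-linkage hierarchical clustering (SciPy) on the condensed distance
matrix; merge heights are non-decreasing by construction and are asserted.
The dendrogram cut is **strict**: flat clusters are connected components of
merges with height *strictly below* the threshold (default 5000 Å²), so a
merge exactly at the threshold does not join. Cluster labels are ordered by
descending member count, ties broken by smallest member frame index;
singletons are reported separately from non-singleton clusters rather than
folded into the cluster count. Summaries give the component-wise median and
median absolute deviation of the *Niggli-reduced* member cells; the median
cell is the suggested re-indexing target. The Newick export writes branch
lengths as height differences (leaves at height 0), so leaf-to-leaf path
lengths equal twice the cophenetic distance.

## Orientation analysis

**Lab frame (fixed convention).** Beam = +z, up = +y, right (looking along
the beam) = +x, right-handed. Latitude = asin(v_y), longitude =
atan2(v_x, v_z), in degrees; (0, 0) is along the beam. Readers with a
different beamline convention remap before plotting.

Real axes come from the reciprocal orientation matrix (rows a*, b*, c* in
Å⁻¹) via duality (a = (b*×c*)/V*, etc.) and are normalized. Crystal axes
are directions without sign, so **both antipodes** are emitted and plotted;
the density and the Bingham statistic are computed on sign-invariant
quantities, so the choice to plot both is purely presentational.

**Density.** A von Mises–Fisher kernel,
f(u) = N⁻¹ Σᵢ c(κ) exp(κ u·vᵢ), c(κ) = κ/(4π sinh κ), evaluated on a 2°
lat/long grid, computed in a numerically stable exp(κ(t−1)) form. Default
κ = 50, chosen so the kernel FWHM is ≈20° — wide enough to smooth
individual frames, narrow enough to show goniometer-style bias. The
density integrates to 1 over the sphere (equal-area quadrature, verified to
1%).

**Uniformity test.** Bingham's test on the orientation tensor
T = N⁻¹ Σ vᵢvᵢᵀ: S = (15N/2)(tr T² − 1/3), asymptotically χ² with 5 df
under uniformity, p-value from the upper tail. The statistic is invariant
under v → −v (axial data) and under global rotations. Requires N ≥ 10. The
null is simulated with uniform directions from normalized Gaussians;
uniform random *rotations* are generated from normalized 4-component
Gaussian quaternions.

## Pseudo-Wilson intensity statistics

Per frame, OLS of y = ln I_partial on x = (sin θ/λ)² = hᵀG⁻¹h/4 (G the
real-space metric tensor): slope = −2B (Å²), intercept = ln G. Natural
logarithms throughout — B is invariant to the log base only if the slope is
rescaled, so the base is fixed and documented; the intercept is reported
both as ln G and G. Standard errors are the usual OLS ones; the histograms
cover per-frame gradients and the standard errors of both slope and
intercept (the per-frame "standard error" being ambiguous, both are
emitted). Reflections with I_partial ≤ 0 are dropped (log undefined) and
counted, never offset-shifted, which would bias the slope. Frames with
fewer than 10 positive reflections (or zero spread in x) are refused and
excluded from aggregates with a logged count — not errors. No
multiplicity/epsilon normalization or partiality correction is applied:
the statistics are deliberately computed on raw partial intensities.

**Outlier filter.** A frame is flagged iff its gradient *or* intercept has
robust z-score |x − median|/(1.4826·MAD) > 3.5 across the dataset. If a
column's MAD is zero with non-identical values, flagging falls back to
exact mismatch with the median (logged).

## Synthetic data

The generator emulates the statistical structure of a two-form goniometer
XFEL dataset, with ground truth for every frame. Defaults:

| parameter | default | rationale |
|---|---|---|
| population medians | (69, 169, 288) and (69, 146, 170) Å, all 90° | the two orthorhombic forms of the reference experiment |
| population weights | 249/318, 69/318 | observed cluster sizes of those forms |
| cell jitter | σ = 0.5 Å per edge, 0.1° per angle, on reduced parameters | magnitude of per-image indexing scatter |
| orientation model | vMF(κ = 5) about lab +y for the a axis, uniform spin about it | loop-mounted crystals preferring an "up" axis |
| B per frame | Normal(15, 2²) Å² | typical cryo macromolecular range |
| ln G per frame | Normal(ln 100, 0.3²) | arbitrary detector units, realistic frame-to-frame scale spread |
| reflections/frame | 150 (s² uniform on [0.001, 0.0625] Å⁻², d ≈ 15.8–2 Å) | typical still-image counts and resolution range |
| partiality | uniform [0.1, 1] | partialities of still images, uncorrected downstream |
| noise | multiplicative lognormal, σ = 0.3 | counting + integration error on partials |
| mis-indexed fraction | 0.1 | the contamination level the filter is specified against |

Miller indices are sampled by snapping random points of the
|q| = 2√s² sphere to the lattice, so the requested s² range is covered with
genuine integer hkl. **Mis-indexed frames** record a scrambled cell (drawn
from the other population, axes randomly non-identity-permuted) and their
recorded indices are decoupled from the intensities (the per-frame pairing
is permuted): a wrong lattice solution assigns indices that bear no
relation to the spots actually integrated, so downstream s² values are
uncorrelated with intensity and the fitted slope collapses towards zero.
Because a permuted orthorhombic cell Niggli-reduces to the same reduced
cell, the truth table carries both the recorded-cell population
(`population`, what clustering can recover) and the intensity-generating
one (`population_true`).

Everything is driven by one integer seed and regeneration is bit-identical.

**What the generator does not emulate:** spot shapes, detector noise
models, absorption, resolution-dependent completeness, correlated cell
drift within a sample, or indexing ambiguities subtler than a scrambled
cell. Passing benchmarks therefore demonstrate correctness of the
*statistical machinery* under the stated models, not performance on any
particular real instrument's pathology.

## Verification problem sizes

The test suite and `scripts/acceptance.py` use: 100 GL(3,ℤ) reduction
round trips; 200 same-lattice pairs against the brute-force transform
oracle plus 1000 random pairs for the metric axioms; 1000 random linkage
instances with n ≤ 20 against a naive O(n³) re-scan; 318-frame two-form
recovery; 500 noisy frames (200 reflections, σ = 0.3) for pseudo-Wilson
calibration; 1000 null and 500 vMF(κ=5) simulations at N = 100 for the
Bingham test; 100 replicates of 100 frames at 10% contamination for the
mis-indexing filter. These sizes give comfortable Monte-Carlo margins for
the quantities checked while keeping a full verification run in well under
a minute of CPU for each stage.

## Known limitations

* `ncdist` is a bounded approximation (see above); pathological lattices
  far from reduced form in many boundary steps may be over-estimated.
* The Bingham test is asymptotic (χ²₅); at N barely above the minimum of 10
  its type-I error is only approximately nominal.
* Orientation analysis assumes the stream/JSON orientation matrices are in
  the documented lab frame; no geometry refinement is attempted.
* The CrystFEL stream reader supports a documented subset (cell, reciprocal
  axes, h k l I σ(I) columns); panel geometry and per-peak records are
  ignored.
* Negative partial intensities are dropped, not modelled; heavily
  background-dominated frames will lose reflections and may be refused.
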