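# Methods

## Growth model

Cell counts per biosphere are modelled as exponential,
`n(t) = n0·exp((t−t0)/τ)` with τ the e-folding (proliferation) time in
days; the doubling time is `τ·ln 2` and both are always reported, since
"doubling time" in the literature sometimes denotes τ itself.  With a
characteristic single-cell volume `v_c`, total spheroid volume is
`V(t) = v_c·n(t) = V0·exp((t−t0)/τ)`; assuming the structure stays a
sphere of diameter d, `V = (π/6)d³` gives

    d(t) = d0·exp((t−t0)/(3τ)),   A(t) = A0·exp(2(t−t0)/(3τ)).

τ is fitted by ordinary least squares of `ln(count)` on time.  Log-scale
OLS matches the multiplicative (constant-CV) noise of cell counting;
nonlinear least squares on raw counts would be dominated by the largest
counts.  The "exponential phase" is located by exhaustive search over
contiguous sub-windows with at least `min_points` points (default 4) and
positive slope, maximising log-scale r²; among windows tying within
1e-9, the widest and then the earliest wins.  The selected window is
always part of the output.

**Compactness.**  `d0/A0` are anchored to the *median* of the earliest
imaging time (robust to segmentation outliers), τ comes from the count
fit, and `κ(t) = observed median area / A(t)`.  A culture is "compact"
iff `κ(t) ∈ [1/κ*, κ*]` at every later time; κ* defaults to 1.5 and the
full κ trajectory is always reported so users can apply their own
criterion.  The observed-vs-predicted area quartiles are emitted
alongside for plotting.

## Morphometry

Circularity is `4πA/P²`, sphericity is
`Ψ = π^{1/3}(6V)^{2/3}/S` — the surface of the volume-equivalent
sphere over the measured surface.  Both are clipped at 1.0 for
reporting (the raw value is retained): estimator bias can push the raw
ratio a few per mille above the isoperimetric ceiling.

- Area/volume are pure pixel/voxel counts times the pixel/voxel volume;
  no sub-pixel correction (documented in output metadata).
- The default perimeter estimator is the 4-direction Crofton intercept
  approximation.  Naive boundary-pixel counting overestimates the
  perimeter of smooth outlines by up to 8/π and would bias circularity
  low.  A marching-squares sub-pixel contour length is selectable
  (`estimator="contour"`); it carries a ~5% overestimation bias on
  smooth outlines, and the estimator name is recorded on every row.
  Note that Crofton error does not converge to zero with pixel size: it
  plateaus at a small (<1%) directional bias, which bounds the accuracy
  of any circularity value.
- 3D surface area: the binary field is zero-padded, Gaussian-smoothed
  with sigma = 1 voxel, and triangulated by marching cubes at the 0.5
  level.  Smoothing is essential, not cosmetic: the isosurface of a raw
  binary field is a staircase whose area overestimates any smooth
  surface by a near-constant ≈9% regardless of resolution, which would
  bias every sphericity value down by the same amount.  One voxel of
  smoothing removes the staircase while preserving features larger than
  a voxel (ball of radius 20 voxels: surface error < 1%).  `sigma=0`
  restores the raw staircase surface.  For objects with surface texture
  near the voxel scale (the rough cohort tumours below) the smoothing
  removes genuine area and measured sphericity runs ~10% *above* the
  continuous-surface truth; the bias is common to all tumours measured
  at the same relative resolution, so group comparisons are unaffected.
- "Diameter" is the area-equivalent diameter `2√(A/π)`, consistent with
  the spherical growth law; the maximum Feret (caliper) diameter is also
  emitted as a diagnostic since imaging studies often annotate it.
- Connectivity is 8 in 2D and 26 in 3D; segmentation drops components
  touching the image border (their perimeter is undefined) and smaller
  than `min_area`.

## Statistics

**Levene quadratic test.**  Each observation is replaced by its squared
deviation from the group mean, `z_ij = (x_ij − x̄_i)²`, and the one-way
ANOVA F statistic of the z values is referred to F(k−1, N−k).  The
classical absolute-deviation (`abs-mean`) and Brown–Forsythe
(`abs-median`) variants are available behind a flag; the quadratic
transform is the default.  Degenerate inputs: no between-group spread of
the z values gives W=0, p=1; zero within-group spread with positive
between-group spread gives W=∞, p=0.  Under a normal null (n=50 per
group) the F approximation is well calibrated (measured type-I rate
0.042 at nominal 0.05, 2000 simulations).

**Mann–Whitney.**  U is computed from midrank sums.  The exact null
distribution is enumerated by dynamic programming when n1+n2 ≤ 20 and
the data have no ties; otherwise the normal approximation with
continuity and tie correction is used (an exact null with midranks is
not attempted).  Two-sided p-values are the default, as twice the
smaller tail, capped at 1.

**Stratification.**  Small/large groups split at the sample median;
median-valued observations go to "small" — an arbitrary but
deterministic and documented tie rule.  The circularity analysis
stratifies pooled per-culture measurements by median area and applies
the Levene test to the circularity of the two strata.

## Synthetic data

The generator defines the study conditions; every default is surfaced in
`RunConfig`.

**Spheroids.**  The boundary is a random-phase Fourier perturbation of a
circle, `r(θ) = r0(1 + ε·Σ_k a_k cos(kθ + φ_k))`, modes k = 2..8,
amplitudes ∝ 1/k, L1-normalised so the total perturbation never exceeds
the irregularity amplitude ε ∈ [0, 1) and the boundary cannot
self-intersect.  Ground-truth area/perimeter/circularity come from
shoelace/arc-length integration of the continuous boundary sampled at
4096 vertices; the polygon is rescaled so the truth area equals that of
a disk of the requested equivalent diameter exactly.  Rasterisation is a
radial inside test at pixel centres (0.5 µm/pixel default).

**Timecourses.**  Each spheroid draws `d0 ~ N(40, 8) µm` and grows as
`d(t) = d0·exp(g(t−t0)/(3τ))`, where the coupling g ≤ 1 lets a culture's
structures lag the count-derived prediction (g = 0.5 for the
proneural-like default, i.e. volumetric growth at half the count rate —
loose, diffusive clustering).  Irregularity grows linearly in
log2(area ratio).  The slope is drawn per spheroid from
Uniform(0, 2·slope): the biological signature being emulated is that
large irregular-subtype structures *diversify* in shape, and a
deterministic slope provably cannot produce it — pooling time points
makes the drifting mean circularity inflate the small- and
large-stratum variances equally, leaving the variance test blind.
Heterogeneous slopes concentrate extra variance in the large stratum.
Fourier phases are drawn once per spheroid, so an object keeps its shape
identity while its amplitude evolves.

Default profiles: mesenchymal-like τ = 2.5 d, base irregularity 0.10,
slope 0, g = 1, imaged days {3, 8, 16}; proneural-like τ = 5 d, base
0.15, slope 0.15 per area doubling, g = 0.5, imaged days {1, 7, 14, 18}.
Proliferation times and imaging days follow the reported culture
behaviour (mesenchymal roughly twice as fast; three to four imaging
sessions over 2–3 weeks); irregularity amplitudes were chosen once to
place truth circularity in the observed 0.7–1.0 range.

**Cell counts.**  `n(t) = n0·exp((t−t0)/τ)` times unit-mean lognormal
noise with CV 0.05 (no noise magnitude is reported for the assay; 5%
is a typical haemocytometer-scale figure, exposed in config), rounded
to integers with floor 1.  Default n0 = 4×10⁴ cells per biosphere, the
reported optimal seeding density; counts sampled every 2 days over 2
weeks, 3 replicates.

**Tumour volumes.**  A ball radially perturbed by a band-limited random
field on the sphere: real spherical harmonics, degrees 2..l_max,
Gaussian coefficients ∝ l^(−p), max-normalised.  Truth volume and
surface come from quadrature on a 257×513 (θ, φ) grid with
finite-difference derivatives; the radius is rescaled so the continuous
volume equals the target exactly.  Rasterisation tests each voxel
centre against the interpolated radius.  Single-volume default
l_max = 6, p = 1 (smooth lobed shapes, truth-vs-measured agreement
<1%).  The cohort uses l_max = 16, p = 0.5 — rougher surfaces whose
truth sphericity at the default base irregularity 0.55 is ≈0.58,
matching the regime reported for MRI-segmented gliomas.  Cohort
volumes are lognormal with median 29.09 cm³ (the reported median-split
threshold) and log-SD 0.9; irregularity rises with
log2(volume/median) at slope 0.12, so a positive coupling makes
sphericity fall with volume.  Voxel size is chosen per tumour to keep
it ≈40 voxels across (clipped to 0.5–2 mm, the MRI range).

**What the generator does not emulate:** cell-scale texture, intensity
gradients, touching/overlapping spheroids, segmentation ambiguity,
imaging artefacts, or any mechanistic cell behaviour (adhesion,
migration, hypoxia).  Passing closed-loop tests therefore demonstrates
that the measurement and inference chain is correct under the stated
generative model, not that segmentation of real micrographs is solved.

## Problem sizes

Defaults: 200 spheroids per imaging day per culture and a 100-tumour
cohort.  The seed-stability sweep (20 seeds) and the null-calibration
sweep (100 cohorts at zero coupling) run at 100 spheroids/culture and
24 tumours at ≈28 voxels across respectively — sizes at which each
sweep completes in a few minutes while leaving the tested effects far
from their detection floor.

## Known limitations

- Crofton circularity has a small non-vanishing bias (<1%); circularity
  comparisons are robust to it, absolute values inherit it.
- Measured sphericity of voxel-scale-rough surfaces is biased up ~10%
  relative to the continuous truth (smoothing removes sub-voxel area);
  rankings and group tests are unaffected.
- The exact Mann–Whitney null is not computed in the presence of ties.
- No per-spheroid tracking across time points: all growth comparisons
  are distribution-level, as in the underlying assay design.
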