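# Methods

## Model

The package renders a 3-D scalar intensity field `I(x)` through a 1-D RGBA
preset and lets the user re-target the preset locally instead of globally.
An edit is the tuple (reference voxel `x₀`, brush-stroke centers defining
the region Ω, sensitivity `α`, pointer radius `β`, feature metric). The
per-voxel input shift is

    Δ(x) = (I(x₀) − I(x)) · f_F(d_F) · f_E(d_E)
    f_F(d_F) = exp(−α d_F),          f_E(d_E) = 1 / (1 + exp(d_E − β))

and the rendered color is `TF_preset(clamp(I(x) + Δ(x)))`. The design
satisfies three constraints by construction: voxels with `I(x) = I(x₀)`
are exactly unchanged (the leading factor is zero in floating point, not
merely small); voxels whose features match the reference inside Ω take on
the reference appearance (`g = f_F·f_E → 1` gives `I + Δ = I(x₀)`
exactly); and the sigmoid confines the edit spatially — at
`d_E = β + 20` the weight is below 2·10⁻⁹, so a rendered pixel whose ray
stays that far from every stroke center is unchanged at 8-bit precision.
`f_E` is evaluated as `expit(β − d_E)`, which is the same function without
overflow for distant voxels.

## Shape features

Features come from the Hessian of the intensity, estimated by separable
sampled-Gaussian kernels (default scale σ = 1 voxel) whose discrete
moments are corrected so that constants map to exactly zero and
quadratics are differentiated exactly; entries below 1e-14 are snapped to
zero so structureless voxels carry no spurious curvature. Derivatives are
taken in voxel index space: microscopy stacks are strongly anisotropic in
z, and resampling to isotropic physical units would both blur the data
and change the meaning of the printed parameter regimes, so anisotropy is
left to the spacing metadata.

Eigenvalues are sorted ascending by signed value, `λ₁ ≤ λ₂ ≤ λ₃` (the
branch conditions of the tube measure require signed ordering, not
magnitude ordering). The tube measure is

    λ_ratio = λ₂/λ₁ − λ₃/λ₁   if λ₁ ≤ λ₂ ≤ λ₃ ≤ 0
            = λ₂/λ₁           if λ₁ ≤ λ₂ ≤ 0 < λ₃
            = 0               otherwise (including λ₁ = 0)

which lies in [0, 1], is invariant to positive scaling of the
eigenvalues, is ≈1 on bright tube axes (two strong negative transverse
curvatures, none axially) and ≈0 on isotropic blobs. The axis vector
`e₃′` is the `λ₃` eigenvector kept only where `λ₁ < 0 ∧ λ₂ ≤ 0`; the
strict inequality on `λ₁` sends the exactly-flat case to the zero vector,
so constant regions and voxels darker than their surroundings carry no
orientation. Downstream, a zero `e₃′` maps to maximal orientation
dissimilarity (`d_F = 1`): suppressed voxels are never pulled toward the
reference appearance.

Metric context is estimated over all voxels of the volume: `σ` is the
population standard deviation of `λ_ratio`, and the Mahalanobis
covariance `V` of the configured channels (default
`(λ_ratio, e₃′ₓ, e₃′ᵧ, e₃′_z)`) is regularised by adding
`ε = 10⁻⁶·trace(V)/k` to the diagonal (escalating tenfold) until it is
invertible and well-conditioned. The inner-product metric presumes unit
feature vectors, so channel vectors are normalised before use (zero
vectors stay zero → maximal dissimilarity).

## Distances, parameters, units

`d_E` is the minimum over stroke centers of the Euclidean distance with
each axis weighted by `spacing/spacing_x`, i.e. measured in x-voxel
units. A single center reduces to the plain pointer distance; a stroke is
a swept union of spheres. `β` therefore keeps its voxel-scale meaning
(useful values 1–20: β = 1 is almost a point probe, β = 6 a working
pointer, β = 20 a search light) on anisotropic grids. `α` spans roughly
1–100: α = 1 admits nearly any feature, α = 10 separates 90°-crossing
fibre families cleanly under the orientation metric, α = 100 admits
almost nothing. Multiple saved edits combine by voxelwise sum, clamped
only at TF evaluation — combination is linear and order-independent, and
each edit keeps its own equal-intensity identity.

## Rendering and picking

The renderer is an orthographic CPU ray caster: one ray per pixel along
the view direction, trilinear interpolation of both `I` and `Δ` at a
fixed step (default 0.5 voxels), per-sample RGBA through the shifted
preset, and front-to-back emission–absorption compositing with opacity
correction `a′ = 1 − (1−a)^(step/reference_step)` and early termination
at accumulated opacity 0.99. Axis-aligned views use a cyclic in-plane
basis so pixel (px, py) of a ∓z view sits exactly over voxel column
(x = px, y = py); rays march in index space, which makes rendering
equivariant under cyclic axis permutation. This ray caster is the CPU
formulation of the interactive GPU texture-slicing renderer such a tool
would use in production; the composited images agree with a dense
per-pixel reference evaluation to float precision, and halving the step
changes smooth-phantom pixels by under 2/255.

Picking marches the clicked pixel's ray at the renderer's step, summing
the raw per-sample opacities of the *shifted* TF, and returns the first
sample (rounded to the nearest voxel) at which the running sum reaches
`α_th` (default 0.3 — the threshold is deliberately exposed, since "how
much accumulated opacity counts as a surface" is a user preference). The
plain sum, rather than transmittance-weighted compositing, is used on
purpose: it makes "enough opaque material seen" independent of the
background and cheap to reason about. Because the opacities include Δ,
structures visible only through an edit are pickable, which closes the
pick → edit → render loop.

## Synthetic scenes

`make_crossing_scene` emulates the geometry this method targets: two
families of straight tubes in the xy plane, crossing at 90°
((1,1,0) vs (1,−1,0)), with Gaussian radial profiles (radius 2 voxels —
the point-spread blur that makes Hessian features well-posed), peaks 0.9
(bright family) and 0.45 (low-contrast family), a central box whose
intensities are multiplied by 0.4 before noise (the shadow cast by an
overlying blood vessel), and additive Gaussian noise of sd 0.02 clipped
to [0, 1] — contrast ratios chosen to mimic the published two-photon
renderings at a desk-scale 96³ grid. Tube offsets and noise derive from
one recorded seed; identical seeds give bit-identical scenes. Every voxel
carries the id of its argmax tube (ties to the lowest id) within that
tube's 2-radius mask, which is what makes selectivity measurable: on the
default scene, thresholding orientation dissimilarity at 0.5 against a
family-A axis voxel separates the families' axis voxels with well under
5% error.

What the phantoms do *not* model: depth-dependent scattering and
excitation falloff, Poisson photon statistics, curved or branching
fibres, and densely packed somata. Passing tests therefore demonstrate
the mathematics and the selectivity mechanism, not robustness to every
artefact of real acquisitions; on real stacks the median filter (default
radius 1, 3³ kernel, replicate edges, applied in 3-D before feature
computation) carries more of the burden, and the feature scale should be
matched to the fibre radius.

## Numerical choices and edge cases

* Intensities are normalised to [0, 1] (affine min–max) before features
  and shifts, making TF domains and Δ comparable across inputs; constant
  volumes are rejected rather than silently mapped.
* `I(x₀)` and all feature values are read from the filtered, normalised
  volume — the same field the renderer samples.
* TF lookups clamp to the intensity domain; control points are strictly
  increasing, at least two.
* Shift fields persist losslessly through NRRD (float64 raw); TIFF
  round-trips at float32.
* Picks on empty rays report a miss (not an error); clicks outside the
  image and non-positive thresholds are contract errors.
* The 60°-cone check treats `|d_F − 0.5| ≤ 1e-12` as the analytic
  boundary: `1 − |cos θ|` at θ = 60° differs from 0.5 by one ulp after
  degree→radian conversion.

## Known limitations

Single-scale Hessian features (no Frangi/Sato scale maximisation): tubes
much thicker or thinner than the chosen scale score poorly. Orthographic
views only. The CPU renderer is seconds-per-frame at 96³, not
interactive — the mathematics, not the frame rate, is what it reproduces.
Feature statistics (V, σ) are estimated over the whole volume including
background, which is the deterministic, mask-free choice but lets a large
empty background dominate σ on sparse scenes.
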