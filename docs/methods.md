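# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic experiments do and do not
demonstrate about real buccal-cytology data.

## Chromatin autocorrelation model

Chromatin mass density ρ(r) (g/mL) is modelled as a stationary Gaussian
random field with isotropic autocorrelation

```
B(r) = A                                  r < r_min
B(r) = A (r / r_min)^(D_b − 3)            r_min ≤ r ≤ r_max
B(r) = B(r_max) exp(−3 (r − r_max)/r_max) r > r_max
```

with fractal-regime bounds `r_min = 23 nm`, `r_max = 334 nm` (the
instrument's length-scale sensitivity window for NA 0.6/0.8) and shape
parameter `D_b ∈ (1, 3]`.  Packing scaling is
`D = 3 + ∂log B/∂log r`, evaluated by central differences in log r (step
1e−3) at the geometric mean of the bounds, where the pure power law makes D
scale-independent; inside the regime D ≡ D_b.

**Realizability.** This piecewise composite is not exactly positive-definite
in 3-D: its radial Fourier transform P(q) = (4π/q)∫B(r) sin(qr) r dr rings
below zero at high frequency, most severely as D_b → 3 where B approaches a
top-hat ball.  The realizable surrogate used everywhere is the clipped
spectral density P₊(q) = max(P(q), 0).  Both the field sampler and the
analytic Σ map are driven by the same P₊, which is what keeps the forward
simulation and the inversion mutually consistent; within the fractal regime
the ACF implied by P₊ matches B(r) closely (the sampled-field log–log slope
recovers D_b − 3 to ±0.15, tested).

**Family normalization.** The one-parameter family traced by the Σ → D_b
lookup (and used by the spectral cohort generator) holds the mass-density
contrast at the domain scale fixed: B(r_max) is pinned while D_b varies, so
the plateau amplitude scales as A(D_b) ∝ (r_max/r_min)^(−D_b).  This is the
outer-scale normalization of Whittle–Matérn-type continuous-random-media
models.  It makes Σ strictly monotone (decreasing) in D_b with
|∂lnΣ/∂D_b| ≈ 0.5–2.3 across [5/3, 3].  Pinning the plateau instead (fixed
point variance) leaves Σ nearly flat and non-monotone in the instrument's
wavenumber band, and no per-pixel inversion is then possible — the choice is
structural, not cosmetic.  The default template amplitude is
A = 0.001 (g/mL)² at D_b = 2 (density fluctuations of ~3 % of water density),
keeping the whole family deep in the first-Born regime (|s| ≪ r_ref).

## Forward optical model and Σ

Per transverse pixel, the simulator computes the reflectance spectrum

```
I(k) = | r_cell + s(k) |²,
s(k) = i k_m Σ_z δn_blur(z) exp(2 i k_m z) w(z) Δz
```

where `k_m = 2π n₀/λ` is the wavenumber in the cell (n₀ the mean cell RI
from n = n_media + α ρ, α = 0.18 mL/g, n_media = 1.364 for 95 % ethanol,
mean crowding 0.2 g/mL), `r_cell` the Fresnel coefficient of the glass–cell
interface, `δn_blur` the RI fluctuation field blurred transversely by a
Gaussian of FWHM 458 nm (the transverse coherence length), and `w(z)` a
Gaussian depth-of-field window (FWHM 2874 nm) centred mid-cell.  The cube is
normalized by the blank-region reference |r_blank|², and Σ is the per-pixel
sample standard deviation (n−1) over the 84-wavelength grid (450–700 nm,
3 nm steps).  A homogeneous cell gives a flat spectrum and Σ = 0 exactly.

The analytic map Σ(D_b) is the *expected value of that same statistic*, not
a separate phenomenology: the covariance of Re s across wavenumbers follows
in closed form from P₊ weighted by the coherence-volume Gaussians, the
interferometric sampling factor cos((k+k′)u), and the window-centre phase
cos(2 z_c (k−k′)); the spectral-mean subtraction of the sample variance is
applied exactly through the quadratic form, and the small-sample bias of the
sample standard deviation (few effective spectral degrees of freedom) is
corrected by moment-matching the sample variance to a gamma distribution.
Every constant — including the overall scale (2 r_cell/r_blank²)² — is
derived from the instrument configuration; nothing is fitted.

Quadratures are fixed-grid trapezoid rules at resolutions (r-grid 0.5 nm,
q-tables ≥ 1024 nodes, 700-node spectral smoothing grid) verified to be
converged far below the round-trip error budget.  The lookup tabulates Σ on
129 D_b nodes spanning exactly [5/3, 3], refuses non-monotone
configurations, and inverts by piecewise-linear interpolation; out-of-range
Σ clamps to the nearest endpoint with a flag (clamp-don't-fail), and the
clamped fraction is reported per image.

**Estimators.** Per-pixel inversion (`sigma_image_to_d_image`) renders D
images.  The cell-level estimate (`recover_cell_d`) inverts the mean in-mask
Σ: per-pixel Σ carries ~20–40 % spectral-sampling noise (≈ 2–10 effective
degrees of freedom per spectrum), and pushing that noise through the curved
lookup before averaging would bias the cell mean; averaging Σ first removes
the bias at no information cost because the map is monotone and smooth.
End-to-end, cells simulated at D_true ∈ {1.8, 2.1, 2.4, 2.7} on the default
synthesis grid are recovered with |bias| ≤ 0.05 and seed-to-seed SD ≤ 0.1.

**Synthesis grid.** The default single-cell grid is 192×192×448 voxels at
11 nm: voxels resolve r_min; the axial extent covers the depth-of-field
window to ±2σ; the transverse extent sets the reciprocal-lattice spacing,
which controls how faithfully the simulated Σ matches the continuum map
(verified by convergence runs at 128/192/256; 192 keeps the residual well
inside the recovery budget at ~8 s per cell on one CPU).

## Synthetic cohort generator

Patient model: `true_mean_D = 2.0 + ΔD·[case] − 0.006·(age − 59) +
N(0, σ_p²)`, truncated-normal (not clipped) to [5/3, 3].  Demographics
follow the Site-1 cohort table: ages 59 ± 11 (controls) vs 67 ± 12 (cases)
— deliberately offset so age-confounding analyses are meaningful —
pack-years 35 ± 26 vs 37 ± 30 (truncated at 0), 49 %/56 % female, 80 %
Caucasian.  Defaults: ΔD = 0.2 and σ_p = 0.12, chosen so the default cohort
reproduces the published univariate performance (average-nuclear-D AUC
≈ 0.76–0.78) and the published violin-plot spread of normalized D; with the
age structure above, these imply an age-confounding loss of ≈ 0.05 D and an
age-induced per-group spread of ≈ 0.066 D, so a "zero-effect" cohort still
carries a weak, genuine group signal through age.  Between-cell SD defaults
to 0.08, giving a 30-cell 95 % CI on a patient mean of ≈ 1.4 % of mean D.

Cell images: an elliptical nucleus (radius 22 ± 2.5 px at 250 nm/px ⇒
~11 µm diameter, axis ratio ≥ 0.7, random orientation, border margin) on a
960×720 canvas.  In-mask D = cell mean + correlated Gaussian texture
(correlation length 750 nm, SD 0.06) + a centred compound-Poisson
packing-domain field: per-pixel event counts are Poisson with a rate that
grows linearly with D (1 /px at D = 2.25), event weights scale with domain
volume (radii lognormal with mean 80 nm, SD 20 nm — sub-pixel, so domains
modulate local texture rather than appear as resolved blobs), and the
per-event amplitude also grows linearly with D (denser domain cores at
higher packing scaling).  Values are truncated to [5/3, 3]; background is
NaN.  Because every nucleus is min–max normalized before feature
extraction, the *absolute* D level is invisible downstream; the
D-dependent domain rate and contrast — higher D ⇒ heavier, more skewed
sub-nuclear texture — are the generator's physically motivated carrier of
group signal through that normalization.  The pixel size (250 nm, near the
diffraction limit) is a documented convention; it is not printed in the
source material.

What the generator does **not** emulate: shipment/fixation artifacts,
optical aberrations and focus errors, cytoplasm and debris, site batch
effects, segmentation errors of a human operator, or any coupling between
demographics and image texture other than through D.  Passing tests
therefore demonstrate the internal consistency and statistical calibration
of the pipeline under its stated assumptions — not clinical performance.
The published clinical AUCs are computed on undeposited patient data and
are intentionally out of scope.

## Feature extraction and MIL aggregation

Nuclei are cropped to the mask bounding box, min–max normalized to [0, 1]
(constant nuclei map to 0.5), background-filled with 0 and resized
bilinearly to 224×224.  The backbone is a VGG16-layout stack (13 3×3
convolutions in five blocks, ReLU, 2×2 max pooling) with per-channel global
average pooling at the final convolution of blocks 2–5, giving
k = 128+256+512+512 = 1408 features per cell at full width; grayscale D
images are replicated across the three input channels.  Two documented
departures from a plain frozen-VGG16 recipe:

* **Masked pooling (default).** The per-channel average is taken over the
  nucleus support (downsampled to each tap resolution) rather than the full
  frame, removing nuisance variance from the nucleus fill factor (ellipse
  shape/orientation).  Frame-wide pooling remains available
  (`pooling="gap"`).
* **Random biases.** In `seeded_random` mode, kernels are He-initialized
  and per-channel biases are drawn at scale 0.5 (`bias_scale=0` restores a
  zero-bias stack).  Biases act as soft activation thresholds, making
  pooled channel means sensitive to the quantiles and skew of the intensity
  distribution rather than only its first two moments — without them the
  features are nearly blind to the texture-shape signal that survives
  min–max normalization.

`pretrained` mode loads user-supplied kernels/biases from an .npz archive
and is clearly labelled as requiring external weights; it is never needed by
the tests.  `width_scale` shrinks all block widths proportionally for cheap
runs (the layout and tap points are fixed).  Patient vectors are the
elementwise mean and sample standard deviation (n−1) of the cell vectors,
concatenated — length exactly 2k, permutation-invariant, requiring ≥ 2
kept cells.

## Selection, tuning and evaluation protocol

Recursive feature elimination fits a random forest and drops the
lowest-importance 20 % of surviving features per round until 40 remain
(panel size and drop fraction configurable).  Grid search (trees
{100, 300, 500} × depth {∞, 8} × min-leaf {1, 3} by default) is scored by
inner-CV AUC with ties broken by listed order.  Evaluation is stratified
4-fold × 5 repeats at the patient level; selection and tuning are nested
inside each training fold (a flagged `pooled_selection` mode reproduces the
leakage-prone alternative of selecting on all data).  AUC is the rank
(Mann–Whitney) statistic with ties credited 0.5, cross-checked against an
O(n²) oracle.  Sensitivity/specificity are taken at the Youden-optimal
threshold of the training patients' *out-of-bag* forest scores — in-sample
forest probabilities are overfit toward 0/1 and systematically misplace the
operating point.  Summaries are mean ± SD (ddof = 1) over the 20
evaluations; the ± convention is recorded in the output metadata.

## Cohort statistics

"Normalized by control" is implemented as division by the control-group
mean of patient average D, per site when a site column is present (mean, not
median — a documented convention).  ANCOVA is a linear model with
treatment-coded categoricals and type-II F tests; rank deficiency raises an
error naming the collinear terms.  Age adjustment subtracts the fitted
control-group slope times (age − control mean age).  Pack-year strata
(< 20 vs ≥ 20, the LDCT eligibility cut) are compared by two-sided
Wilcoxon rank-sum, using the exact null when min(n₁, n₀) ≤ 10 and there are
no ties; empty strata are reported as not computable rather than failing.

## Degenerate inputs and tie-breaks

Zero-amplitude chromatin ⇒ zero fluctuation field, flat spectra, Σ = 0,
fully clamped D images (flagged).  Constant nuclei preprocess to 0.5.
Youden ties resolve to the lowest threshold; grid-search ties to the
first-listed parameter set.  All random stages consume explicit seeds
(numpy `default_rng` / scikit-learn `random_state`); identical seeds give
bit-identical artifacts, including across output directories (manifests
store relative paths; config snapshots exclude the output location).

## Known limitations

* The Born scattering model is scalar and axial per pixel; NA-dependent
  angular effects enter only through the two printed coherence lengths
  (458 nm, 2874 nm), which are treated as given constants because neither
  follows uniquely from the printed NAs and wavelength range.  Cell
  thickness, CVC, Fresnel transmission factors and genomic length are
  exposed as optional model fields but default to unused.
* The clipped spectrum P₊ deviates from the nominal B(r) outside (and, for
  D_b ≳ 2.5, partially inside) the probed wavenumber band; consistency
  between simulator and inversion is preserved by construction, but the
  ACF family itself should be read as "realizable surrogate of" the
  piecewise power law.
* Per-pixel D images carry irreducible spectral-sampling noise (~0.1–0.5 D
  at the extremes of the range); quantitative cell comparisons should use
  the cell-level estimator.
* Random-feature backbones are a stand-in for transfer-learned weights;
  with `pretrained` weights the feature panel would differ, though the MIL
  and evaluation contracts are unchanged.
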