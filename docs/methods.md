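# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.

## Forward optical model

A specimen stretched into a film is modeled as a single homogeneous,
non-dispersive layer of thickness *t* (nm) and real refractive index *n*,
illuminated at normal incidence. Reflectance is computed with the transfer
matrix method (characteristic matrix of the layer, ambient index 1.0) on a
400–800 nm grid in 1 nm steps. Two stack configurations exist:

* **air** (default): the film is surrounded by air on both sides. This
  emulates a film suspended over a substrate that is almost perfectly
  absorbing, which is the configuration the color tables are built from.
* **tabulated substrate**: the film sits on a half space whose complex index
  n − ik is interpolated from a bundled CSV. A coarse, literature-typical
  crystalline-silicon table (400–800 nm) ships with the package; its values
  are approximate (±few % in n, larger in k) and are intended for
  qualitative silicon-substrate scenarios such as metamer studies, not for
  quantitative ellipsometry.

The closed-form Airy reflectance (two Fresnel coefficients plus the
geometric series) is implemented independently and used purely as a test
oracle; the two paths agree to < 10⁻¹⁰ over the full grid.

Limitations: single layer only, normal incidence only (no objective-NA
cone), no dispersion of the film index, no scattering or roughness.

## Colorimetry

Spectra are integrated against the CIE 1931 2° observer CMFs. Because no
colorimetric data package is available as a dependency, the bundled CMF
table is generated from the Wyman–Sloan–Shirley multi-lobe Gaussian analytic
fit, accurate to about 1% of peak; all quantitative tests in this package
compare recovery against truth generated through the *same* curves, so this
approximation does not bias them, but absolute triplets may differ by a few
8-bit code values from tables computed with the official CIE data.

The pipeline after integration follows the conventional camera chain:
XYZ → linear RGB with the standard sRGB/D65 matrix; gamut handling scales
the triplet so its maximum is 1.0 (only when it exceeds 1) and then clips
negatives to 0; gamma encoding is the pure power law c^(1/2.2) (not the
piecewise sRGB curve); quantization rounds half away from zero to the
2^B − 1 code range. The illuminant is flat (equal energy) by default —
reflectance is integrated directly — and the tristimulus is normalized so a
perfect reflector has luminance component exactly 1. Pixel-value
instability is modeled as independent per-channel integer jitter, uniform on
[−v, +v], clipped to the code range: the least-informative bounded model for
an instability quoted "in units of bits".

Camera-specific CMF sets can live in "rgb" space (curves map spectra
directly to linear channel values; no matrix, no luminance normalization);
learned CMFs use this mode.

## CMF learning

Channel responses are linear in the spectrum once the gamma encoding is
inverted, so each sensitivity curve is expanded on K Gaussian radial basis
functions (default K = 24, centers even over 400–800 nm, width 1.5× the
center spacing, ridge 10⁻⁶) and fitted per channel by least squares in
linearized channel space. Non-negativity (physical sensitivities) is
enforced by an exact NNLS solve on the ridge-augmented system; unconstrained
fits are available and may return signed curves, which is required when the
training data embed a matrix-mixed observer (effective curves have negative
lobes). With 65 noiseless synthetic calibration films (thickness 50–1000 nm,
index 1.45–1.50, silicon substrate — emulating a spin-coated polymer wafer
series) the known curves are recovered to ≪ 5% relative L2 error per
channel. "Noiseless" calibration uses a 16-bit camera so quantization does
not dominate the fit; 8-bit quantization adds ~0.2% channel noise.

## Inversion

The lookup table stores the jitter-free quantized triplet at every node of
the (t, n) grid (defaults 0–1200 nm step 1 nm, 1.33–1.55 step 10⁻³;
1201 × 221 nodes) with a provenance fingerprint of the stack/camera
configuration. Building the default table takes a few seconds.

**Clustering.** k-means on raw RGB triplets (10 restarts, fixed seed),
k grown from 1 until the across-cluster average of each cluster's mean
relative deviation — 100·‖pixel − centroid‖/‖centroid‖ — drops below the
threshold (default 2%, cap k = 100). Both the average and the maximum
per-cluster deviation are logged. A cluster is background when all three
centroid channels are below 5% of full scale in code values; background
clusters are excluded from the deviation criterion and from recovery. The
cutoff acts on code values rather than decoded luminance deliberately: the
peak reflectance of a free-standing biological film is ~15%, so every
attainable film color has decoded luminance below 0.05 and a luminance
cutoff would classify the whole specimen as background.

**Cost maps and minima.** The per-pixel cost is MSE(t, n) =
(1/3)Σᵢ(Xᵢ − X̂ᵢ)². Quantization makes cost maps piecewise constant, so
minima are detected as *basins*: the map is smoothed with a 3×3 mean,
thresholded at 4× its smoothed global minimum, and each 8-connected
component yields one candidate (its lowest raw-MSE node, plateau ties
resolved toward the plateau center). Candidate probabilities are
inverse-MSE weights, (1/(mₖ + ε))/Σⱼ(1/(mⱼ + ε)) with ε = 10⁻¹²: a clean
pooled map yields one basin with probability 1, a genuinely ambiguous pixel
(color between two metamers) two comparable candidates.

**Pooling and assignment.** Cluster pooling averages the cost maps of up to
1000 pixels sampled without replacement. The averaged map is computed in a
single table pass from the first and second moments of the sampled pixel
values, which is algebraically identical to averaging per-pixel maps. The
assigned (t, n) is chosen from the exact-tie plateau of the pooled minimum:
all tied nodes share one quantized triplet and are indistinguishable from
the data, so the deterministic representative is the plateau node nearest
the tie set's center of mass — the median/mode-optimal choice under a
uniform posterior over the plateau. (A corner tie-break, e.g. always the
smallest thickness, would bias the estimate by the full plateau width.)

**Identifiability floor.** At 8 bits the plateau around a typical film node
spans a few nm × a few 10⁻³: for the 567 nm / 1.41 phantom, 13 nodes share
the triplet and the plateau center sits at (566 nm, 1.412), so the recovery
error is 1 nm / 2×10⁻³ regardless of how many pixels are pooled. This is a
property of the quantized forward map, not of the estimator; finer recovery
requires more bits (see the sensitivity analysis). For the same reason
"exact" round-trip recovery of noiseless phantoms holds only on grids coarse
enough that every node has a unique triplet, and gradient specimens are
recovered at cluster granularity (one (t, n) per color cluster), i.e. with
errors of order the thickness spread inside a 2%-deviation cluster (a few
nm), not per-pixel nanometer accuracy.

**Metamer disambiguation.** For the classic metameric pair — 588 nm/1.41
vs 356 nm/1.49 on silicon, whose 8-bit triplets differ by at most 15 code
values under the bundled CMFs — pooling 100 jittered pixels selects the
imaged member's basin in 50/50 seeded trials, because the pooled mean
triplet concentrates at the true color with O(v/√N) error while the rival
basin stays several codes away.

## Sensitivity analysis

The resolution along an axis (thickness or RI) at bit depth B and
instability v is the smallest probed separation δ such that *every*
reference structure — thicknesses {300, 450, 600, 750} nm crossed with 21
indices over [1.33, 1.55] — changes by more than v code values in at least
one channel when shifted by +δ. Probes ascend a logarithmic ladder (10 per
decade; 10⁻⁶–0.1 RIU, 0.01–100 nm), and the ladder ceiling is returned when
nothing qualifies. Worst-case aggregation over references is used; the
per-reference thresholds themselves are asymmetric under ±δ at the scale of
single rounding boundaries (up to ~3× in δ), so symmetry is only meaningful
one ladder step above the worst-case limit, where both signs resolve every
reference. With the default air stack the sweep gives ~3×10⁻⁵ RIU at 16
bits and ~0.04 nm at 14 bits (v = 0), and resolutions are monotone in both
bit depth and v.

## Phantoms

Phantoms emulate the measurement scene, not cell biology: a bright film
region (square, ellipse, or uniform patch) over a near-black background
(~1% of full scale, emulating a substrate reflecting < 2% of visible
light), optional dark circular occlusions where support pillars show
through, and the camera's integer jitter. Pixel pitch is nominally
0.1 µm/px so a ~30 µm specimen spans ~300 px. Gradient phantoms rescale
their thickness/index fields so the extrema equal the requested range ends
exactly, then snap to the recovery grid. Metamer phantoms verify their pair
is actually metameric (max channel distance ≤ a configurable bound, default
12) before rendering. All generators are deterministic in their seed.

What phantom tests do *not* show: robustness to defocus blur, specimen
folding, spatially varying illumination, demosaicing artifacts, or CMF
mismatch between the table and the real camera — all of which affect real
micrographs.

## Known limitations

* Color uniqueness across thicknesses is not absolute: at 8 bits the
  450 nm and 600 nm loci (n ∈ [1.33, 1.55]) share exact triplets in this
  model — quantization metamers of exactly the kind the pooled inversion is
  designed to resolve. Gamut clipping (negative red channel → 0) is the main
  mechanism collapsing distinct colors.
* The recovered maps are cluster-constant; no sub-grid interpolation is
  attempted.
* The silicon optical constants and the analytic CMF fit are approximations;
  absolute simulated triplets carry a few-code uncertainty at 8 bits.
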