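# Methods

## What the package measures

`memcrowd` quantifies the mesoscale organization of membrane proteins on
glass-adhered membrane sheets from two-channel fluorescence images. The
motivating system is the SNARE pair syntaxin 1A / SNAP25: syntaxin
concentrates in tight clusters (~80 nm apparent diameter at roughly 11 per
µm² in STED-scale imagery), SNAP25 in larger diffuse crowds (~160 nm), and
the interesting biology is whether and how the clusters reorganize the
crowds. The package implements the measurement chain end to end and pairs it
with a generative forward model so every stage can be validated against
known ground truth.

## Measurement chain

**Maxima detection.** Spots are local intensity maxima with topographic
prominence at least a noise tolerance: a maximum must rise above the highest
saddle connecting it to any higher region. This is the same semantics as the
ImageJ "Find Maxima" tool. We implement it as a persistence sweep (pixels
activated in order of decreasing intensity, merged with union-find; the
lower of two merging peaks dies at the saddle). Plateaus of tied pixels
yield a single point at the plateau centroid; of two equal peaks joined by a
valley, one carries on and the other is emitted with prominence measured at
their mutual saddle (deterministic tie-break by descent order). The noise
tolerance defaults to 5× a robust noise scale, 1.4826 × MAD of the
median-filter residual inside the ROI; it is scale-adaptive and can be
overridden. Noisy crowd-like channels are pre-smoothed with a σ = 0.5 px
Gaussian *for detection only*.

**Sizing.** Each maximum is sized by fitting
`a·exp(−(x−µ)²/(2σ²)) + c` to horizontal and vertical 31 × 3 px linescans
(averaged across the 3-px width) on the raw image, so the detection blur
cannot inflate sizes. The size is FWHM = 2√(2 ln 2)·σ of the
better-fitting orientation (higher R²). Quality control rejects fits with
R² < 0.8 or a centre outside the middle third of the profile (µ ∉ [10, 20]
on a 31-sample axis, inclusive). The fit includes a constant offset and is
initialized at the profile maximum (amplitude = max−min, µ = argmax, σ = 3
px, offset = min); initializing µ at the scan centre instead makes genuinely
off-centre peaks fail to converge, which would mask the "non-centred peak"
QC verdict behind a fit failure. R² is computed on the 31-sample averaged
profile, not the 93 raw pixels.

**Intensity statistics.** Per-ROI mean, sample (n−1) SD, and the rSDM
(relative standard deviation of the mean, SD/mean) as the clustering degree.
Background is a scalar per image (mean of an off-sheet region); corrected
pixels may go negative and are not clipped, keeping means unbiased. By
default the rSDM is computed on background-subtracted pixels; a switch
(`subtract_background_for_rsdm=False`) relates the corrected SD to the raw
mean instead, since either convention is defensible.

**Colocalization.** Pearson correlation of paired pixels inside the ROI;
zero variance raises rather than silently returning 0. The chance-overlap
control rotates the full second channel by 180° (vertical + horizontal flip
composed) before applying the unchanged ROI mask. Which channel is flipped
is a convention; we flip channel B.

**Sheet segmentation (epifluorescence scale).** Blur the reference channel
(σ = 3 px) to define outlines, threshold (Otsu by default — scale-invariant
and parameter-free; a fixed absolute threshold can be supplied),
8-connected labelling, discard components below 4 µm² (debris), and measure
per-sheet means on the *raw* channels. Border-touching sheets are kept but
flagged. The confocal plasma-membrane fraction uses three nested ROIs:
pm = outer − inner, cyto = inner − nucleus, fraction = pm/(pm + cyto).

**Distance statistics.** Nearest-neighbour distances (same- and cross-type),
radial cross-counts per annulus, and the pair distribution g(r) =
observed / expected annulus counts, all with minus-sampling border
correction: reference points closer than a margin to the window edge are
excluded while neighbours may lie anywhere. The margin defaults to the
largest analyzed distance (max bin edge), the standard unbiased choice. Bins
are half-open [lo, hi) with default width 25 nm (one pixel). The null model
is the ideal gas / complete spatial randomness (CSR): closed-form
nearest-neighbour law p(r) = 2πλr·exp(−πλr²), plus a Monte-Carlo reference
that redraws the observed point count uniformly in the observed window
(exact-count binomial matching — lower variance than a Poisson redraw) and
returns pointwise mean and 2.5/97.5% envelopes, seeded. Patterns from
different sheets are analyzed per sheet and pooled at the histogram level
(weighting sheets by reference-point count), never merged into one pattern.

**Regression and ratios.** Ordinary least squares for per-sheet
intensity–intensity plots (free intercept); slopes compared with a
Welch-style t-test, t = Δslope/√(se₁² + se₂²) with Welch–Satterthwaite
degrees of freedom on per-fit df = n − 2 (no equal-variance assumption
across conditions). The clustering-degree-vs-intensity relation is fitted
as y = (a − b)e^(−d·x) + b by unweighted nonlinear least squares,
initialized from the endpoint values and a log-linearized first pass; a
constant response is reported with d flagged unidentifiable. Ratio helpers
propagate a baseline copy-number ratio through fold changes and
plasma-membrane fractions, and compute offset-corrected staining ratios
((pct_a − offset)/(pct_b − offset)). Rounding conventions (one decimal for
fold ratios, integers for "-fold" phrasing) live in the reporting layer;
stored values are unrounded.

## Forward model (synthetic scenes)

Cluster centres follow a Thomas-type process: CSR parents at
`cluster_density` (default 11 /µm²) each spawning `molecules_per_cluster`
(50) offspring with isotropic Gaussian spread `cluster_sigma_nm` (20 nm, so
that after convolution with the 65 nm FWHM PSF the rendered blob is ~80 nm).
Offspring falling outside the window are discarded, as in an imaged
sub-field; realized densities are reported. Crowds are rendered as Gaussian
blobs of `crowd_sigma_nm` (60 nm → ~160 nm apparent) at 15 /µm², each
carrying the integrated intensity of `molecules_per_crowd` (100) molecules —
crowd-forming SNAP25 is severalfold more abundant than syntaxin. A
molecule-resolved mode exists where quenching physics needs individual
emitters. Recruitment coupling: each crowd is, with probability
`coupling_p`, placed at `binding_distance_nm` (40 nm, uniform angle) from a
uniformly chosen cluster centre, otherwise uniformly in the window.

Rendering samples the normalized Gaussian PSF (FWHM 65 nm, combined in
quadrature with any blob width) at pixel centres on a 25 nm grid. Midpoint
sampling rather than box integration is deliberate: integrating over the
pixel aperture convolves the profile with a 25 nm box and inflates a 60 nm
FWHM spot by ~5%, whereas the sampled profile stays exactly Gaussian and
total intensity is conserved to better than 1e−6 at these widths. Noise is
Poisson photon statistics (100 photons per intensity unit) on signal plus a
constant autofluorescence background (5 intensity units — real recordings
are never background-free, and the robust noise estimate degenerates on a
strictly zero background), followed by Gaussian read noise (SD 2) and
clipping at zero. All generators are bit-reproducible under a fixed seed.

Two label-physics distortions are available for property studies:
self-quenching multiplies the intensity of any molecule with a neighbour
within `quench_radius_nm` (5 nm) by 1 − q, and epitope shielding removes
labels within `shield_radius_nm` of a cluster centre with probability
`shield_p`. Their magnitudes are free parameters: synthetic runs demonstrate
directions and monotonicity, not measured effect sizes.

## What the generator does and does not emulate

It reproduces the morphological statistics that the measurement chain
consumes — cluster/crowd densities, sizes, recruitment coupling, PSF width,
photon/read noise — and therefore supports round-trip validation of
detection, sizing, density, rSDM, PCC and distance statistics. It does not
model photophysics over time (blinking, bleaching), vectorial or 3-D PSFs,
membrane topography, antibody size/stoichiometry, or cell-to-cell
variability. Passing tests show the *pipeline* is correct and the readouts
respond in the expected directions; they do not certify effect sizes on real
membrane sheets.

## Numerical and design choices

- Blur uses reflective padding (intensity-conserving, deterministic).
- All statistics in float64 regardless of integer input depth.
- Detection coordinates are pixel centres, (index + 0.5) × pixel size, in
  the image frame.
- Orientation choice in sizing: best R² first, then QC on the chosen fit
  (mirrors "size from the better fit, then exclusion").
- Maxima on ROI borders are kept but flagged; downstream distance
  statistics apply their own minus-sampling margin.
- Exact-count CSR matching; seeds recorded in all stochastic outputs.
- Sheets touching the image border are kept (flagged); minimum sheet area
  4 µm².
- Problem sizes in the validation suite (windows of 3–6 µm at 25 nm pixels,
  ~10⁴-point CSR samples, 2000-replicate null calibration) are chosen so the
  whole suite completes in a few minutes on one core while keeping Monte-
  Carlo error well inside the asserted tolerances.

## Known limitations

- Prominence detection merges spots closer than roughly twice the rendered
  spot σ — physically unavoidable at the image level; planted-count
  recovery is therefore validated at low density (≤ 5 /µm²), and detected
  densities at 11 /µm² undercount by several percent while molecule-level
  substructure can overcount on bright clusters.
- The rSDM depends on ROI size relative to the correlation length of the
  pattern; comparisons are only meaningful at matched ROI geometry.
- The Welch slope test treats per-sheet means as independent; nested
  (sheet-within-experiment) designs should aggregate per experiment first,
  as the paired mode of `condition_compare` does.
- g(r) envelopes use pointwise (not simultaneous) percentiles.
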