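# Methods

## Signal model of the synthetic whole-mount field

A field is a pair of same-shape intensity planes. Before noise,

```
red   = bg + Σ follicle blobs
green = bg + α · Σ follicle blobs + Σ GFP spots
```

* **Follicles** are radially decaying (parabolic) disks of radius
  12–20 px and peak 800–1600 intensity units, placed on a jittered
  hexagonal grid with a hard minimum centre separation of 2.5× the largest
  radius. Murine follicles are quasi-regular; a uniform-random layout at
  320 per field would produce merged blobs that real whole-mount fields do
  not show. Placement is retried a bounded number of times and raises a
  `PlacementError` if infeasible.
* **Melanocytes** are isotropic Gaussian spots (σ = 2 px, peak 900–1800)
  whose per-field count is Poisson(n_follicles × mcsc_rate) and whose
  positions are uniform over the field (spots may fall on follicle
  footprints, as epidermal GFP signal does above follicle openings).
  Spatial statistics beyond the per-follicle rate are not modelled.
* **Bleed-through** is optical: the green channel receives α times the
  *noise-free* follicle signal (α ∈ [0, 1), default 0.25), applied before
  detector noise. Consequently `green − α·red` is spatially constant
  (= bg·(1−α)) wherever there is no spot — the identity the unmixing stage
  exploits, and an exact generator invariant under zero noise.
* **Noise** is additive Gaussian (default σ = 15 on a background of 100),
  clipped at zero; optional Poisson shot noise is available behind a flag.
  No acquisition noise characterization exists for the modelled system, so
  the default was fixed once at a mid-range SNR (follicle peak ≈ 50σ,
  spot peak ≈ 60σ) and is not treated as a tunable study condition.

Defaults (2048×2048 px at 1 µm/px, 320 follicles/field, 20 fields/mouse)
reproduce the stated acquisition geometry: ~320 follicles per image and
6400–8000 follicles per animal. The pixel dimensions themselves are a
package choice — they put 320 follicles at a realistic visual density while
keeping one field tractable on a laptop core.

Section pairs paint a DAPI mask as the top-q fraction of a smoothed
Gaussian random field and the stain mask as the top-p fraction of the
*same* field (p ≤ q), so the stain region is a nested subset and both areas
are exact pixel counts by construction. Cell mode swaps the stain channel
for n disjoint disks (radius 5 px, separation ≥ 4 radii). Colocalization
pairs place reference spots far apart (≥ 10 matching radii), give
`round(n·f)` of them a partner at the requested offset, and keep distractor
spots ≥ 5 matching radii from every reference spot, so the truth fraction
is unambiguous.

Every generator takes an explicit seed; identical parameters give
bit-identical images and truth. What the generator does **not** emulate:
hair-shaft streaks, depth-dependent blur, uneven illumination,
photobleaching, or spatial clustering of melanocytes near follicles.
Passing tests therefore demonstrate correctness of the measurement chain
under the stated signal model, not robustness to every artifact of real
whole-mount microscopy; the QC overlay export exists precisely so a human
can audit detections on real data.

## Detection chain

**Follicles** (red channel): subtract the 25th-percentile background,
smooth with a Gaussian at follicle scale (σ = 4 px), threshold (Otsu by
default; fixed-quantile and absolute overrides), open with a radius-2 disk,
label 8-connected components, and keep components with area in
[30, 20000] px. Components touching the border count when their centroid is
inside the field (the unbiased choice when fields tile a larger specimen);
an exclude-border option exists. A flat image (1–99 percentile span < 1
intensity unit) yields zero detections with a `low_contrast` flag rather
than an error.

**Bleed coefficient**: Theil–Sen slope (LAD via IRLS as an alternative) of
green versus red over the dilated follicle footprint (3 px dilation),
deterministically stride-subsampled to ≤ 1000 pixels. The robust fit is the
reason rare GFP spots inside the mask cannot bias α; 1000 pixels put the
slope's sampling error near 0.003 at default SNR, an order of magnitude
inside the ±0.02 recovery tolerance, at a few hundredths of a second per
field. A fitted slope ≥ 1 is physically impossible for crosstalk and flags
the field (`implausible_alpha`) — the typical cause is a swapped channel
map. Unmixing is `max(green − α·red − intercept, 0)`.

**Spots** (corrected green): scale-normalised negative-LoG responses at 4
scales, σ ∈ [1, 4] px. Each scale's response is divided by
`σ_bg · ‖filter‖₂` — its exact standard deviation under iid noise — where
σ_bg is estimated as (p90 − p50)/1.2816 of the corrected image. That
estimator reads the upper half-spread, so it is immune both to the
zero-censoring that rectification imposes on the lower tail and to the rare
bright spots in the upper 10%; a plain MAD collapses on a half-zero image
and is not usable here. The multiscale maximum is then a z-score and the
default threshold k = 5 means five robust sigmas at every scale alike
(measured false positives: 0 per default field over 20 spotless seeds;
≲0.3 expected from Gaussian tail area). Local maxima closer than
min_separation (8 px = 2× the largest detection scale) are suppressed to
the brighter one, ties broken row-major (y, x); centroids are refined by
centre of mass in a 3×3 response window. On a noise-free image σ_bg is
zero; any strictly positive response then counts as signal, preserving
exactness.

All detection is deterministic given its configuration; no RNG exists in
the quantification modules. Coordinates are 0-based (x = column, y = row)
with pixel centres at integers.

## Statistics

Per-mouse aggregation is the pooled-counts ratio ΣMcSC/Σfollicles, which
equals the follicle-weighted mean of per-field rates (asserted as an
algebraic property test); an unweighted per-field mean is deliberately not
the default, since the displayed-formula reading of the measurement pools
counts. Mice backed by fewer than 6000 follicles are flagged, not rejected.

Normalization divides by a positive per-mouse scalar: the Cox-2 scheme
takes the animal's Cox-2 immunofluorescence area ratio (any user-supplied
positive level is accepted — how the original expression level was measured
is not stated, so the section area ratio is this package's documented
choice); the littermate scheme takes the matched control's migration rate,
making control-over-control exactly 1. A non-positive normalizer is an
error, never a silent infinity.

`compare_groups` wraps scipy: Welch t (unequal-variance, two-sided), paired
t (zero-variance differences yield a `degenerate_variance` flag with NaN
statistics rather than a fabricated p), and Mann–Whitney U — exact
enumeration when both n ≤ 8 without ties, otherwise the tie-corrected
normal approximation. The "Mann–Whitney t test" named in figure-legend
conventions is implemented as the standard two-sided Mann–Whitney U
(Wilcoxon rank-sum). SEM = sd/√n is reported per group everywhere; no
multiple-testing correction is applied by default (a Benjamini–Hochberg
helper exists but is opt-in).

Tests verify Welch p-values against the closed-form Welch–Satterthwaite
formula to 1e-10 and exact Mann–Whitney p-values against full
rank-assignment enumeration; type-I error of the Welch comparison on
Poisson-derived per-mouse rates (6400 follicles/mouse, 5 vs 5) is
calibrated to 0.05 ± 0.02 over 2000 replicates.

## Problem sizes in the test suite

Full-geometry runs (2048 px fields) are reserved for the checks whose
subject *is* the geometry: the per-field ~320 count, the 20-field 6400
basis, and noise-free exactness. Parameter-recovery sweeps use
density-matched smaller fields — identical follicle density
(7.6×10⁻⁵ px⁻²), intensities and noise, hence identical per-object SNR —
at 512 px (20 follicles) for the bleed sweep and 724 px (40 follicles) for
the rate sweep. Rate recovery is asserted on the mean of 10 replicate mice
per rate (≥ 8000 pooled follicles per rate), sized a priori so the Poisson
sampling error of that mean (≈ 0.0035 at rate 0.1) sits 3σ inside the
±0.01 band. Type-I calibration simulates per-mouse rates at the count
level (Poisson counts over 6400 follicles) because its subject is the test
statistic, not image processing.

## Known limitations

* The bleed model is a single global coefficient; spatially varying
  crosstalk (e.g. depth-dependent) is out of scope.
* Otsu thresholding misbehaves on foreground-free noisy images (it will
  split the noise); zero-stain frames are only exact in the noise-free
  case, and absolute thresholds are the escape hatch on real data.
* Colocalization is centroid-proximity (default radius 3 px ≈ one nuclear
  radius), not pixel-overlap, and matching is one-to-many; both choices
  suit point-like nuclear signals and would be wrong for extended objects.
* Manual "correction by eye" is intentionally absent: the pipeline exports
  QC overlays for audit but never lets a human edit counts.
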