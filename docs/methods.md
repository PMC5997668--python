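# Methods

## Scope and model overview

`colocq` implements two analysis chains for single-aggregate fluorescence
data, plus the synthetic-data generators used to validate them end to end.

1. **SAVE imaging analysis.** A TIRF movie of ThT-active aggregates is
   averaged over its frames, a smooth background is subtracted, species are
   detected by thresholding at *k* standard deviations above the mean image
   intensity (default *k* = 5), and each detection is fit to a 2D
   elliptical Gaussian
   `B + A·exp(−(a·dx² + 2b·dx·dy + c·dy²))`, with the quadratic form
   parameterized by (σ_major, σ_minor, θ). Reported quantities are the
   major/minor FWHM (2.3548·σ), orientation, amplitude, and integrated
   intensity 2π·A·σ_major·σ_minor.

2. **Two-colour localization co-localization.** Per-channel localization
   tables are filtered (precision ≤ 50 nm; DBSCAN at eps = 135 nm, one
   camera pixel, retaining clusters of strictly more than 20
   localizations), optionally rendered and scored for resolution by
   Fourier ring correlation (threshold 1/7), and finally compared across
   channels: an aggregate-channel record is *coincident* when some
   marker-channel record lies within the sum of the two fitting
   precisions. The association quotient `Q = (C − E)/(A − E)` corrects the
   coincident count C by the chance count E, estimated by replaying the
   identical coincidence analysis against density-matched uniform
   simulations of the marker channel.

## Key parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `pixel_nm` | 160 | nm | camera pixel edge (EMCCD TIRF geometry) |
| `counts_per_photon` | 250 | ADU/photon | camera gain calibration |
| `em_gain_e_per_adu` | 11.5 | e−/ADU | electron-multiplying calibration (metadata; the excess-noise factor is not simulated) |
| `k_sd` | 5 | — | detection threshold in SDs above mean intensity |
| `kernel_px` | 21 | px | median-filter background kernel (≫ PSF) |
| `window_px` | 15 | px | Gaussian-fit window; grown to 1.5× the candidate extent for elongated species |
| `max_precision_nm` | 50 | nm | localization precision cutoff (inclusive) |
| `eps_nm` | 135 | nm | DBSCAN neighbourhood radius (one pixel) |
| `min_cluster_size` | 20 | — | clusters must exceed this size (strict >) |
| `min_samples` | 5 | — | DBSCAN core-point parameter, distinct from the size rule |
| `render_pixel_nm` | 10 | nm | super-resolved render pixel for FRC |
| `frc threshold` | 1/7 | — | first-crossing criterion on the smoothed curve |
| `n_reps` | 100 | — | replicates of the chance simulation (E ± SD) |

## Numerical and design choices

* **Background subtraction.** The estimator is a sliding median, robust to
  sparse bright species. It is computed with a histogram-based rank filter
  on an affine 10-bit quantization of the image; the quantization step
  (dynamic range / 1023) is far below camera noise, and a constant image
  subtracts to exactly zero.
* **Detection.** Threshold statistics are computed on the
  background-subtracted averaged image. Above-threshold regions use
  8-connectivity; a region with several local maxima farther apart than
  3 px yields one candidate per maximum, so a fibril does not swallow a
  nearby oligomer. A constant image (SD = 0) yields no candidates.
* **Fitting.** Least squares (trust-region reflective) with moment-based
  initialization; bounds σ ∈ [0.5 px, window/2], A ≥ 0, centroid inside
  the window; tolerances 1e−14. Axes are canonicalized (major ≥ minor,
  θ ∈ [0, π), θ = 0 for circular spots with |σ_maj − σ_min| < 1e−3 px).
  A fit is rejected (flagged, never raised) when the window is degenerate
  or smaller than 7×7, the optimizer fails, or a parameter sits on a
  bound — a σ at the 0.5 px floor is the signature of a single-pixel noise
  spike. `analyze_stack` additionally rejects fits whose amplitude falls
  below the detection threshold: the candidate was then a sub-threshold
  fluctuation, not a resolvable species. This keeps the false-positive
  rate on pure-noise fields below the raw 5-SD pixel exceedance rate
  (≈ 2.9e−7 × 512² ≈ 0.076/image) at essentially zero cost in recall.
* **Coincidence counting.** KD-tree neighbourhood queries with radius
  `prec_b + max(prec_a)` followed by the exact per-pair test
  `d ≤ prec_a + prec_b` (boundary inclusive); contract-equal to all-pairs
  evaluation, which the tests verify against a brute-force oracle. Each
  A record counts at most once; B records may serve many A records.
* **Chance null.** Channel B is the simulated one. Each replicate draws
  |B| uniform positions in the ROI with precisions resampled from the real
  B channel, preserving both density and the precision distribution. The
  uniform null ignores the spatial clustering of real marker channels — a
  documented limitation of the method as defined. E is reported with its
  replicate SD; `Q` is flagged undefined (NaN) when |A − E| falls below
  tolerance.
* **FRC.** Seeded uniform random half-split (frame-block splitting would
  be an alternative; it is not the default), both halves rendered on the
  same square grid, ring correlation of the FFTs with integer-rounded
  radial binning, smoothing by a centred 7-bin moving average, resolution
  = 1 / (first frequency below threshold, DC ring excluded). Tables with
  fewer than 100 records, or curves that never cross, yield an undefined
  resolution rather than an error.
* **"Noise threshold".** The upstream peak-fitting software's noise
  threshold is exposed as an approximate pass-through minimum-amplitude
  filter (photons ≥ threshold × per-frame noise estimate); it is not part
  of the default chain because the tables this package consumes are
  post-fit.

## The synthetic-data generators

* **Scenes and movies.** Point emitters model diffraction-limited
  oligomers; fibrils (up to ~5 µm, the scale seen in mature aggregation
  reactions) are chains of emitters spaced FWHM/4 along a segment. The
  PSF is an isotropic Gaussian (σ = FWHM/2.3548) integrated exactly over
  pixels via the error function with a ±5σ support window (truncation
  < 0.01% of the photon budget). Noise is Poisson on photons, then linear
  ADU conversion, then additive Gaussian read noise, clipped at zero.
  The EMCCD excess-noise factor and pixel cross-talk are *not* modelled:
  the generator exists to exercise the fitting and detection code, not to
  emulate camera physics. Emitters whose PSF leaves the field are clipped
  silently.
* **Two-channel tables.** `round(coloc_fraction × n_a)` A records,
  chosen at random, receive a B partner; the rest of channel B is a
  uniform Poisson background of density `density_b` (default 50/µm² in a
  10×10 µm ROI with 2000 A records and 15 ± 3 nm precisions — chosen for
  test power; real acquisitions reach >5×10⁵ localizations per channel
  over whole cells, and no per-µm² density is published to match).
  **Partner placement:** the partner is displaced from the *observed* A
  position by an isotropic Gaussian of SD `partner_offset_nm` (default
  10 nm), i.e. the paired record's localization error is folded into the
  net offset, as the field name "SD of true-pair displacement" states.
  This is deliberate: if both partners were instead jittered
  independently by their own precisions, the observed pair distance would
  be Rayleigh with scale √(p_a² + p_b² + offset²) against a coincidence
  radius of p_a + p_b, capping the capture probability of a *true* pair
  at 1 − e⁻¹ ≈ 0.63 for any precision scale — the association quotient
  could then never approach 1 and would not estimate the associated
  fraction. With the net-offset convention, Q at full association reaches
  ≈ 0.98 (the residual 2% is the Rayleigh tail of the offset relative to
  the smallest precision sums), and mean Q tracks the generating fraction
  within ±0.02 across the sweep.
* **What passing tests do and do not show.** Recovery of the generating
  fraction on these tables validates the estimator's chance correction
  under spatially uniform backgrounds. Real marker channels are clustered
  (organelle-shaped), which inflates E's variance and can bias Q on small
  ROIs; published Q values from real data are therefore not reproduced
  here, and none are asserted.

## Problem sizes

Test and driver problem sizes are chosen so the whole suite runs in a few
minutes on one core: 512² detection fields (100 seeds for calibration),
200-repeat Poisson fit recovery, 50-seed × 5-fraction Q sweeps with
25-replicate chance nulls, 10⁴-localization FRC tables. The acceptance
script uses 10-seed sweeps and 20/40 detection fields; all of its
quantities are stable to well within their acceptance bands across seeds.

## Known limitations

* No drift correction, chromatic registration, 3D/astigmatic PSF, or
  multi-emitter fitting.
* The chance null is uniform; organelle-shaped nulls (mask-constrained
  placement) are configurable future work (`estimate_chance` accepts any
  rectangular ROI today).
* Fibrils are summarized by their fitted major-axis FWHM, which for
  strongly elongated species underestimates the end-to-end length and may
  split one fibril into several fits; skeleton-based length measures are
  out of scope.
* Localization precision is treated as exact; uncertainty in the
  precision estimate itself propagates directly into the coincidence
  radius.
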