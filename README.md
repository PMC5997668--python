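# colocq

Quantitative image analysis for single-aggregate biology: detection and
shape quantification of individual ThT-active protein aggregates in TIRF
movies ("SAVE" imaging), and two-colour single-molecule-localization
co-localization analysis culminating in the **association quotient**

```
Q = (C − E) / (A − E)
```

where *A* is the number of aggregate-channel localizations, *C* the number
of them coincident with the marker channel (two localizations are
coincident when their distance does not exceed the **sum of their fitting
precisions**), and *E* the expected number of *chance* coincidences,
estimated by rerunning the identical analysis against simulated marker
channels with the same localization density and precision distribution
placed uniformly in the region of interest. Q is a chance-corrected
associated fraction: 0 for independent channels, 1 for full association.

The package is aimed at single-molecule microscopists who need a tested,
scriptable reimplementation of this analysis chain — for example to
quantify how much aggregated α-synuclein sits on mitochondrial membrane
proteins — without the original acquisition-side software.

## What is implemented

* **`colocq.synthgen`** — ground-truth scenes (diffraction-limited puncta
  and micron-scale fibrils), EMCCD-like movie rendering (Gaussian PSF,
  Poisson photon noise, ADU conversion, read noise), and two-channel
  localization tables with a known association fraction.
* **`colocq.save_imaging`** — the SAVE chain: frame averaging, median
  background subtraction, detection at 5 SD above the mean intensity, 2D
  elliptical Gaussian fitting (major/minor FWHM, orientation, integrated
  intensity 2πAσ<sub>maj</sub>σ<sub>min</sub>), histogram summaries.
* **`colocq.paint_locs`** — localization-table post-processing: precision
  cutoff (≤ 50 nm), DBSCAN at eps = 135 nm retaining clusters of > 20
  localizations, super-resolved rendering, Fourier ring correlation
  resolution at the 1/7 threshold.
* **`colocq.coincidence`** — precision-radius coincidence counting
  (KD-tree backed, exactly equivalent to all-pairs evaluation), the
  simulated chance null, Q and percent co-localization.
* **`colocq.io` / `colocq.pipeline` / `colocq.cli`** — TIFF and
  localization-CSV formats, YAML-configured end-to-end runs with a
  provenance log, and the `colocq` command-line tool
  (`simulate stack|coloc`, `save-detect`, `paint-filter`, `frc`, `coloc`,
  `run`).

The `analysis/` directory holds numbered driver scripts that run the whole
study on synthetic data and write their tables under `results/`.

## Worked example

Recover the association fraction from simulated two-channel data
(10×10 µm ROI, 2000 aggregate localizations, 50 marker localizations/µm²,
15 nm mean precision):

```python
from colocq import ColocConfig, generate_coloc_tables, coincidence_analysis

cfg = ColocConfig(coloc_fraction=0.5)
table_a, table_b, truth = generate_coloc_tables(cfg, seed=1)
res = coincidence_analysis(table_a, table_b, roi=cfg.roi, n_reps=25, seed=1001)
print(f"A={res.A} C={res.C} E={res.E:.0f} Q={res.Q:.3f} "
      f"raw={res.percent_coloc:.1f}%")
```

```
A=2000 C=1135 E=317 Q=0.486 raw=56.8%
```

Half of the 2000 aggregate localizations were generated with a true marker
partner, yet 57% are coincident — at this marker density roughly 13% of
records are coincident by chance alone. The chance correction removes the
excess: Q ≈ 0.49 recovers the generating fraction. Running the full sweep
(`python analysis/05_association_quotient.py`) gives mean Q of 0.006,
0.244, 0.489, 0.733 and 0.979 for generating fractions 0, 0.25, 0.5, 0.75
and 1 (10 seeds each).

The SAVE side is exercised the same way
(`python analysis/01_simulate_save_stack.py` then `02_detect_aggregates.py`):
simulated oligomer fields are recovered detection-for-detection with
major-axis FWHM ≈ 335–350 nm, while 5 µm fibrils fit to elongated
ellipses with FWHM in the micron range.

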