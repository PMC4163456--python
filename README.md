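# ramandx

Raman-spectroscopy analysis pipeline for discriminating tumor from normal
tissue: spectral preprocessing, per-wavenumber differential statistics with a
permutation-based false discovery rate, L2-penalized logistic tumor-probability
prediction under leave-group-out cross-validation, PCA cluster visualization,
and band-intensity chemical imaging — together with a synthetic spectrum
generator that emulates the acquisition designs the pipeline targets, so every
stage is testable without measured data.

## Modules

| module | what it does |
| --- | --- |
| `ramandx.spectra_io` | plain-text I/O (two-column ASCII, matrix CSV, metadata CSV, band table), core `Spectrum`/`SpectrumSet`/`BandTable` objects |
| `ramandx.synthetic_data` | pseudo-Voigt band model with baseline, noise, cosmic spikes, per-sample amplitude jitter; default cell (58 tumor / 40 normal spectra), tissue (123 spectra / 6 mice) and 12 × 22 map designs |
| `ramandx.preprocess` | despiking, background subtraction (reference / iterative polynomial / ALS), phenylalanine-band normalization, fingerprint (580–1800 cm⁻¹) filter, resampling, standardization |
| `ramandx.bandstats` | pooled/Welch t per wavenumber, label-permutation FDR (exhaustive or sampled), band-window summaries |
| `ramandx.classify` | ridge logistic regression (IRLS, reduced-space solve when p ≫ n), leave-one-out penalty selection, leave-group-out CV, confusion metrics |
| `ramandx.decompose` | SVD-based PCA, per-cluster 3D covariance ellipsoids |
| `ramandx.imaging` | trapezoidal band integration, chemical maps from stage coordinates, Otsu/quantile thresholding with pixel metrics |

## CLI

Every stage is exposed as a `ramandx` subcommand operating on directories of
matrix-CSV + metadata-CSV pairs:

```bash
ramandx simulate --design cell --tumor-effect 2.0 --seed 1 --out runs/raw
ramandx preprocess --in runs/raw --out runs/clean
ramandx diff --in runs/clean --permutations 1000 --seed 1 --out runs/diff.csv
ramandx classify --in runs/clean --grid 1e-4:1e4:25 --out runs/preds.csv
ramandx pca --in runs/clean --components 3 --out runs/scores.csv
ramandx simulate --design map --seed 1 --out runs/rawmap
ramandx map --in runs/rawmap --band 1440:1460 --out runs/map.csv
```

`diff` writes per-wavenumber `wavenumber,t,p,q` plus a band-window summary;
`classify` writes per-spectrum out-of-fold probabilities plus a metrics JSON
(sensitivity/specificity as one-decimal percentages); `map` writes the ny × nx
intensity grid plus pixel metrics when ground truth is present.

## Notes

- All exchange formats are plain text; vendor binary formats are out of scope.
- The wavenumber axis is treated as data (stored ascending; windows are closed
  intervals in cm⁻¹).
- Synthetic effect sizes are free parameters chosen so recovery properties are
  testable; they are not estimates of real tissue biochemistry.
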