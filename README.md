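# irchemo

Chemometric analysis of ATR-FTIR absorbance spectra: derivative /
normalisation preprocessing, PCA / PCA-LDA / RBF-SVM classification with
per-class quality parameters, PCA-loadings biomarker peak-picking, and
Ward/Euclidean hierarchical clustering of class-mean spectra — plus a
ground-truth synthetic spectra generator so every stage can be exercised
without instrument data.

## Library tour

- `irchemo.spectra_io` — `SpectrumSet` (descending wavenumber grid,
  absorbance matrix, per-spectrum metadata), readers for wide CSV/TSV/XLSX
  tables and directories of two-column text exports, exact-round-trip
  writer, and a taxon synonym normaliser for the 16-class herbarium panel.
- `irchemo.preprocess` — fingerprint cut (1800–900 cm⁻¹), Savitzky-Golay
  second derivative (window 9 / polyorder 2 by default, configurable),
  vector normalisation, training-mean centring, rubber-band baseline
  correction. The chain is invariant to per-spectrum thickness gain.
- `irchemo.chemometrics` — stratified 70/30 split, venetian-blinds folds
  (`i mod k`), PCA, PCA-LDA (10 PCs default), RBF-SVM tuned over a
  cost × gamma grid by venetian-blinds CV, and one-vs-rest
  accuracy/sensitivity/specificity tables with macro averages.
- `irchemo.biomarkers` — loading peak-picking (|loading| extrema, greedy
  20 cm⁻¹ minimum separation), assignment against a packaged
  wavenumber→compound lookup, band-intensity ratios on rubber-band-corrected
  class means, and horizontal peak-shift detection.
- `irchemo.clustering` — Ward/Euclidean HCA of group means in fingerprint
  mode (average → derivative → normalise) and loadings mode (derivative →
  normalise → select wavenumbers → average), with ultrametric Newick export.
- `irchemo.synthetic` — Gaussian-band class libraries with surface /
  location / concentration effects, polynomial baselines, noise and
  log-normal thickness gain; presets `study_scale` (1580 spectra, 16
  classes), `two_variety` (planted 2× marker band near 1034 cm⁻¹) and
  `env_vs_taxon` (environment-vs-taxon clustering contrast).

## CLI

```bash
irchemo simulate --preset study_scale --seed 1 --out spectra.csv
irchemo preprocess --table spectra.csv --meta spectra_meta.csv --out processed.csv
irchemo classify --table spectra.csv --meta spectra_meta.csv \
    --model svm --model pcalda --out-dir results/
irchemo biomarkers --table spectra.csv --meta spectra_meta.csv \
    --class-a var_invasive --class-b var_dwarf --out-dir results/
irchemo hca --table spectra.csv --meta spectra_meta.csv \
    --mode fingerprint --mode loadings --out-dir results/
irchemo run --config run.yaml --out-dir results/ --seed 1
```

`irchemo run` executes a YAML-configured pipeline (one of
`simulate`/`input`, then optional `preprocess`, `classify`, `biomarkers`,
`hca` sections) and writes metrics/confusion CSVs, a peak table, Newick
trees and a JSON run report that embeds the config and seeds needed to
reproduce every artefact exactly.

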