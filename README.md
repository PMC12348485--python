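# seedmsi

A MALDI mass spectrometry imaging (MSI) metabolomics toolkit for seed
sections: adduct-aware accurate-mass annotation of MSI peaks against a
compound library, blank-control and peak-shape filtering, k-means tissue
segmentation, and per-tissue semi-quantitative metabolite tables — plus a
synthetic seed phantom with full ground truth so the entire pipeline is
testable offline.

## What it does

- **chem** — molecular-formula parsing, monoisotopic masses (fixed
  IUPAC/CODATA table), adduct m/z arithmetic with electron-mass correction,
  and a sorted ion index over a compound library
  (`[M+H]+ [M+Na]+ [M+K]+ [M-H]- [M+Cl]- [M+HCOO]-` by default,
  configurable via YAML). A mini-library of named seed metabolites ships in
  `src/seedmsi/data/minilib.csv`.
- **msio** — imzML 1.1 + ibd reading/writing (continuous and processed
  binary modes), ion images.
- **preprocess** — per-spectrum RMS normalization, mean spectrum, peak
  picking with MAD-based SNR and Gaussian shape scoring, top-N (default
  1020) selection.
- **annotate** — ppm-tolerance matching against the ion index (binary
  search; isomers kept as groups), blank-control exclusion (blank/tissue
  intensity ratio), peak-shape exclusion (Gaussian-fit R²), class summaries.
- **spatial** — k-means segmentation (default k = 10) of peak-intensity
  features, cluster→tissue mapping (explicit or majority-vote), ROI label
  matrix I/O.
- **semiquant** — per-tissue mean-intensity tables, presence calls,
  per-tissue counts and class composition, row-scaled heatmap matrix.
- **phantom** — synthetic seed phantom: concentric pericarp / seed-coat /
  cotyledon / plumule regions with a cavity and off-tissue matrix
  background, planted library ions with region-specific abundances,
  ppm-scale mass error, lognormal intensity noise, matrix-only background
  ions, and a ground-truth manifest with precision/recall and ARI scoring.

## CLI

```sh
# render a phantom (imzML + ibd + manifest.json + ROI labels)
seedmsi make-phantom --out scratch/phantom --seed 42

# full pipeline from a YAML config (flags override config keys)
seedmsi run --config run.yaml --seed 42 --tol-ppm 5 --k 10

# individual stages
seedmsi annotate --peaks peaks.csv --polarity negative --out hits.csv
seedmsi segment --imzml scratch/phantom/phantom.imzML --k 10 --out seg.tsv
seedmsi report --run-dir results/
```

A minimal run config:

```yaml
imzml: scratch/phantom/phantom.imzML
roi_labels: scratch/phantom/roi_labels.tsv
roi_palette: scratch/phantom/roi_palette.yaml
out_dir: results/run1
tol_ppm: 5.0     # matching tolerance
tau: 0.5         # blank-ratio exclusion threshold
r2_min: 0.8      # peak-shape exclusion threshold
n_top: 1020      # peaks kept per polarity
k: 10            # k-means clusters
beta: 0.10       # presence: fraction of max tissue mean
gamma: 3.0       # presence: multiple of background mean
seed: 42
```

Outputs: `peaks.csv`, `annotation.csv`, `segmentation.tsv`,
`intensity_table.csv`, `presence.csv`, `heatmap_matrix.csv`,
`summary.json` (including compounds in the library that were *not*
detected) and `run.log` with full provenance. Re-running with the same
config and seed reproduces the CSVs byte for byte.

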