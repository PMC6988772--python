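# mscmorph

Morphology-to-function profiling of cultured human bone-marrow stromal
cells (BM-MSCs), built as a fully synthetic, testable reimplementation of a
high-content-screening analysis: can a handful of single-cell morphology
parameters measured on undifferentiated cultures predict how well a donor's
cells will proliferate and differentiate into osteoblasts or adipocytes?

BM-MSC cultures are strikingly heterogeneous between donors, which is a
problem for cell-therapy trials: two "identical" preparations can differ in
growth and bone-forming capacity. The analysis implemented here takes
multi-channel fluorescence fields (DAPI nuclei, actin and α-tubulin
cytoskeleton), segments nuclei and cells, extracts per-cell morphometry
(area, width, length, width-to-length ratio, roundness) and SER texture
features (Spot, Edge, Ridge, Saddle, Valley, Hole, Bright, Dark from
Gaussian-derivative responses at a 1 px scale), aggregates ≥1,000 cells
into per-donor profiles, and relates those profiles to functional assay
panels. Because no cohort data are deposited, the package ships a
first-class synthetic-data module that generates donor cohorts with known
latent traits and planted effect sizes, plus a field renderer with
pixel-exact ground truth, so every downstream stage is testable end to end.

## The statistics at the core

* **Bivariate screen.** For each (feature, outcome) pair, outliers are
  removed by the ROUT procedure (robust straight-line fit with Lorentzian
  loss; residuals scaled by the RSDR, the 68.27th percentile of
  |residuals| × n/(n−K); a step-up false-discovery test at maximum FDR
  Q = 1%), then the two-tailed Spearman rank correlation r_s is reported
  (exact permutation p for n ≤ 9).
* **Functional readouts.** Proliferation as the trapezoidal area under the
  15-day growth curve (AU) and the population doubling time
  PDT = 120 h · log 2 / log(N_day6 / N_day1); osteogenic outcome as
  alizarin-red intensity (AU) and ALP activity per viability unit;
  adipogenic outcome as Oil-Red-O lipid-droplet area (%); donors split into
  high-OB / high-AD groups by a strict median split on both outcomes.
* **Group contrasts.** Unpaired pooled-variance t-test and the rank-based
  ROC AUC with a DeLong confidence interval (97.5% level by default).
* **Multivariable analysis.** Stability selection: the Lasso is fitted to
  50 random half-subsamples, the first q variables to enter the
  regularization path are recorded per subsample, and each variable's
  selection probability π_j is its relative frequency. The stable set is
  {j : π_j ≥ θ} with θ = 0.75, and q is the largest integer satisfying the
  per-family error bound q² / ((2θ−1)·p) ≤ PFER with PFER = 2 expected
  false selections. Model quality is compared on an AIC ladder
  (AIC = n·ln(RSS/n) + 2k) across m0 (intercept), m1 (top stable
  variable), and m2 (top four variables).

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic cohort and write their tables to `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_render_and_extract.py
python analysis/03_bivariate_screen.py
python analysis/04_stability_selection.py
```

`01` simulates 56 donors (1,000 cells each) and prints the cohort summary —
mean cell area 8,344 µm² with inter-donor CV 0.33, mean PDT 74.2 h,
CD146+ 60 ± 27% — and a naive check of the planted correlations. `02`
renders 8 fields with ground truth and validates the imaging chain
(53/53 interior cells recovered, mean |area error| 1.4%, median IoU 0.981).
`03` reproduces the screening table; on seed 0 it reports, e.g.:

```
nucleus_wl_ratio_mean vs osteo_au           r_s = -0.62, p = 0.0000, n = 56
cell_area_mean        vs proliferation_auc  r_s = -0.46, p = 0.0006, n = 52
nucleus w/l: t = -2.41, p = 0.0245; oriented AUC = 0.78
```

i.e. donors whose cells carry elongated (low width/length) nuclei show
stronger osteogenic differentiation, and large-celled cultures proliferate
more slowly — the planted biology, recovered through the full screen
including outlier removal. `04` runs stability selection; for the
osteogenic outcome the nucleus width/length ratio is selected with
π = 1.00 (the only stable variable at θ = 0.75), and the AIC ladder
improves from m0 = 326.5 to m1 = 300.7 with no further gain at m2 — the
single-predictor model is the best description. The adipogenic outcome is
null in the default configuration and correctly yields no stable
predictors.

A `mscmorph` command-line interface wraps the same stages
(`simulate`, `extract`, `analyze`, `run-all`, `report`) for YAML-configured
runs; `mscmorph run-all --seed 5 --out runs/demo` produces an immutable run
directory with every table, a manifest, and a plain-text report.

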