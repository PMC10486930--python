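# gliaquant

Quantification of axonal mitochondria incorporation into optic nerve head
astrocytes, with a fully synthetic ground-truth test bed.

The package implements, as reusable, tested components:

- **`gliaquant.mitoquant`** — 3D image analysis of two-channel confocal
  stacks (green = astrocyte cytoplasm reporter, red = retrogradely labeled
  mitochondria): binarization (fixed or Otsu threshold), per-slice 3×3
  median filtering, 3D connected-component labeling (6/18/26
  connectivity), the *enclosure* test (a red component counts only when
  surrounded in all three dimensions by green signal > 100), per-stack
  astrocyte/mitochondria volumes and the incorporation fraction, and
  per-astrocyte incorporation categories with cohort summaries.
- **`gliaquant.scqpcr`** — single-cell qPCR workflow: control-gene QC
  (cells with both Gapdh and Oaz1 at Ct > 32 are dropped), ΔCt and
  2^(−ΔCt) expression, whole-population fold changes with Bonferroni
  corrected t-tests, pooled z-normalization of ΔCt, and per-gene
  up/down calls from the 95% t-interval of the treated cells' mean z.
- **`gliaquant.stats`** — cumulative IOP (trapezoidal area under the
  IOP-vs-time curve), Shapiro–Wilk-gated two-group tests (exact Wilcoxon
  rank-sum by full enumeration for combined n ≤ 20), one-way ANOVA with
  Tukey–Kramer post hoc comparisons, and OLS regression with pointwise
  confidence bands.
- **`gliaquant.rgc`** — nuclei counting in retinal fields (blur → Otsu →
  components → area filter → optional watershed split) and per-retina
  ganglion-cell densities.
- **`gliaquant.synth`** — seeded generators for every input type with
  known ground truth: astrocyte-shaped volumes with planted
  enclosed/external/border mitochondria, Ct tables with a reactive
  subpopulation mixture, IOP curves peaking at day 7, and Poisson-placed
  nuclei fields.
- **`gliaquant.pipeline` / `gliaquant.cli`** — end-to-end orchestration
  with a YAML config, deterministic seeded reports (JSON + CSV).

## CLI

```sh
gliaquant synth --out data/ --seed 1            # demo dataset with truth
gliaquant mitoquant --stacks data/ --green-th 100 --red-th otsu \
    --connectivity 26 --out results/
gliaquant scqpcr --ct data/ct_table.csv --out results/
gliaquant stats --iop data/iop.csv --out results/
gliaquant rgc --fields fields/ --area-mm2 0.1 --out results/
gliaquant run --seed 1 --out results/           # full synthetic pipeline
```

Stacks are read/written as paired 8-bit multi-page TIFFs
(`<name>_green.tif` / `<name>_red.tif`, one page per z-slice) with JSON
sidecars for voxel size and planted truth.  Ct tables are CSV with header
`cell_id,group,<gene>...`; blank entries mean undetected (censored at
Ct 40).

## Configuration

All analysis constants (green threshold 100, Ct cutoff 32, ceiling 40,
0.4 µm voxels, 3×3 median kernel, α = 0.05, category bins 0/1–5/6–20/>20,
19-gene panel) live in `gliaquant.config.RunConfig`, round-trippable to
YAML via `RunConfig.to_yaml` / `from_yaml`.
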