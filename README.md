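# mitomorph

Quantitative analysis of mitochondrial **form** (network morphology from
fluorescence micrographs) and **function** (respiration from extracellular-flux
"Mito Stress Test" traces), with a fully synthetic data generator that carries
exact ground truth — so every stage of the pipeline can be validated end to
end against known answers.

The scientific setting is dose–response studies in cultured vascular cells,
where a treatment fragments the mitochondrial network (shorter branches at
constant mitochondrial mass), depolarizes the inner membrane (lower TMRM
contrast), and suppresses respiration (lower ATP-linked, maximal, and spare
OCR). The package simulates such studies, analyzes them (or real TIFFs/trace
CSVs of the same shape), and tests group differences.

## What it computes

**Imaging** (`imgproc`, `morphometrics`): each single-cell image is sharpened
(unsharp mask), median-filtered, Otsu-thresholded and binarized. The mask
gives the *mitochondrial footprint* (foreground area, µm²) and, on the raw
TMRM image, the *membrane potential proxy* Δ = mean(foreground) −
mean(background). The mask is thinned to a 1-pixel skeleton and converted to
a graph (endpoints, junctions, branches); per cell the package reports

- **mean branch length** — Σ branch lengths / number of branches (µm),
- **mean summed branch length** (mean network size) — mean over networks of
  the per-network total branch length; a *network* is a connected structure
  with ≥1 junction, the rest are *individuals*,
- counts of networks and individuals.

**Respirometry** (`respirometry`): each well's oxygen-consumption-rate (OCR)
trace over the basal → oligomycin → FCCP → rotenone/antimycin A protocol is
partitioned into non-mitochondrial, proton-leak, ATP-linked, basal, maximal,
and spare respiration.

**Statistics** (`stats`): one-way ANOVA and Tukey HSD across dose groups.
Both the ANOVA sums of squares and the studentized-range tail probability
(a numerical double integral) are implemented here and cross-checked in the
test suite against scipy and statsmodels.

**Synthesis** (`synthgen`): generates cells as disjoint branched structures
with exactly known branch lengths, junction/endpoint counts and contrast
(orientations quantized to 45° so polyline truth length equals the raster
path length exactly), renders them through a Gaussian PSF + noise model, and
generates OCR traces from known respiratory components.

## Worked example

Simulate and analyze a three-dose imaging study (10 cells/dose here):

```python
from mitomorph.pipeline import RunConfig, run_imaging_study

cfg = RunConfig(seed=42)
cfg.imaging.cells_per_dose = 10
report = run_imaging_study(cfg)
print(report.summary())
```

Output (abridged — fragmentation and depolarization are detected, footprint
is correctly *not* significant because the dose model conserves mass):

```
endpoint: mean_branch_length
one-way ANOVA: F = 84.41, p = 2.419e-12
Tukey HSD (alpha = 0.05):
  control vs zn5: diff = +0.2585, p_adj = 2.914e-05 *
  control vs zn50: diff = +0.6177, p_adj = 1.296e-12 *
  zn5 vs zn50: diff = +0.3592, p_adj = 1.275e-07 *

endpoint: footprint_um2
one-way ANOVA: F = 2.512, p = 0.0999

endpoint: membrane_potential
one-way ANOVA: F = 237.7, p = 7.222e-18
```

The respirometry side, with the default three-group well plate:

```python
from mitomorph.pipeline import RunConfig, run_respirometry_study

report = run_respirometry_study(RunConfig(seed=42))
print(report.group_summary[["basal_mean", "atp_linked_mean",
                            "maximal_mean", "spare_mean", "n"]].round(1))
```

```
         basal_mean  atp_linked_mean  maximal_mean  spare_mean  n
group
control        92.4             66.8         134.4        42.0  6
zn5            86.9             57.6         127.4        40.5  6
zn50           78.5             47.9         108.4        29.9  6
```

The same pipelines run from the command line on simulated or on-disk data:

```sh
mitomorph simulate-images --seed 1 --out images/     # TIFFs + truth JSON
mitomorph analyze-images  --images images/ --out results/imaging/
mitomorph simulate-traces --seed 1 --out traces.csv
mitomorph analyze-traces  --traces traces.csv --out results/resp/
mitomorph run-all --seed 1 --out results/            # both, simulated
```

`analyze-images` expects single-cell grayscale TIFFs named
`<group>_<id>.tif`; `analyze-traces` expects a long-format CSV with columns
`well, group, cell_count, time_min, phase, ocr, ecar`.

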