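# Methods

This note records the measurement model, the default parameters (and why),
the synthetic generator's realism and limits, and the numerical choices.

## 1. Imaging model and measurement chain

A single-cell image is a 2-D array of fluorescence intensities (DN) with a
physical pixel pitch (µm/pixel) and a bit depth (8 or 16). The analysis
chain per cell is:

1. **Unsharp mask.** `out = (img − w·G_σ(img)) / (1 − w)`, clipped to the
   valid range, where `G_σ` is a Gaussian blur with edge replication. This is
   the renormalized form used by the common ImageJ/Fiji operator. Presets:
   `rasmc` (σ=1 px, w=0.8, median radius 1) for flat, spread smooth-muscle
   cells; `raendo` (σ=3 px, w=0.9, radius 1) for the higher-background
   endothelial morphology.
2. **Median filter.** Square (2r+1)×(2r+1) neighborhood by default (exactly
   reproducible by a brute-force sort; a discretized disc is available),
   edge-replicated.
3. **Otsu threshold** on the preprocessed image; **binarize** as strictly
   `pixel > threshold`.
4. **Mitochondrial footprint** = foreground pixel count × pixel area (µm²).
5. **Membrane potential proxy** Δ = mean(foreground) − mean(background),
   computed *on the raw image* with a mask from Otsu on the raw image (the
   unsharp mask redistributes intensity and would bias the contrast;
   `tmrm_on_preprocessed=True` opts into reusing the morphology mask).
6. **Skeletonization** of the morphology mask to 1-px width, then **graph
   extraction** and the morphometrics of §2.

## 2. Skeleton graph and morphometrics

**Adjacency dialect.** Raw 8-adjacency on organic skeletons contains
triangles: a diagonal step next to an orthogonal step makes three mutually
adjacent pixels, inflating degrees and creating spurious junctions. We use a
*reduced adjacency*: a diagonal link is dropped whenever its two pixels share
an orthogonal skeleton neighbor. On ideal 1-px rasters this coincides with
plain 8-adjacency.

- **Node classification** on reduced degree: endpoint (1), junction (≥3),
  isolated pixel (0). Adjacent junction pixels are merged into one junction
  cluster. 2×2 blocks in which *every* pixel has reduced degree ≥3
  ("junction knots", which thinning can legitimately leave at dense
  junctions) are absorbed into the cluster; any other 2×2 block means the
  input was not thinned and raises an error telling the caller to run
  `skeletonize()` first.
- **Branches** are walks between nodes; length = Σ steps (1 per orthogonal,
  √2 per diagonal step) × pixel size. A connected component that is a pure
  cycle is one circular branch anchored at a designated "cycle" node.
- **Metrics** per cell: *mean branch length* = Σ lengths / n_branches;
  *mean summed branch length* (= "mean network size" in common usage) = mean
  over networks of per-network summed length, `NaN` + `no_networks` flag if
  there are none. A structure is a *network* iff it has ≥1 junction (or is a
  cycle); otherwise an *individual*.

## 3. Synthetic generator: design, realism, limits

**Geometry.** Cells are sets of disjoint branched structures. Branch
orientations are quantized to multiples of 45° and lengths to integer pixel
steps, so a branch's polyline (Euclidean) length equals the 8-connected
raster path length *exactly* — the ground truth stays exact through
rasterization, which is the generator's purpose. Arm directions at a junction
are kept pairwise ≥90° apart so rasterized arms never touch off-junction.
Structures are kept mutually separated by max(3·psf_sigma, 3 px·pitch) and
self-intersection-free; if a field cannot be populated after bounded retries
a `PlacementError` is raised rather than silently overlapping.

**Rendering.** Foreground pixels take the mitochondrial intensity,
background pixels the background intensity; the field is blurred by a
Gaussian PSF, additive Gaussian noise is applied, and intensities are
rounded and clipped to the bit depth. Same seed ⇒ bit-identical images.

**Defaults (study conditions).** pixel 0.1 µm, PSF σ 0.1 µm, noise 3 DN,
160×160 px field, 8 structures/cell, branch lengths lognormal(µ=log 1.5,
σ=0.35) µm with a 0.5 µm floor, junctions per structure ~ (0.4, 0.4, 0.2)
for 0/1/2, mitochondrial intensity 150 DN over background 30 DN. The noise
default reflects that the unsharp step (w=0.8) amplifies noise ≈5×: much
noisier inputs would make Otsu segment noise — a genuine failure mode of the
thresholding method, not of this implementation. The density default keeps
the foreground fraction (~2–5%) inside Otsu's reliable regime.

**Dose model.** `DoseEffectSpec` scales branch lengths by
`branch_length_scale` (default 1.0/0.8/0.6 for control/zn5/zn50) and
contrast by `potential_scale` (1.0/0.85/0.7). Fragmentation conserves
mitochondrial mass: the number of structures scales as 1/branch_length_scale,
so total skeleton length and footprint are approximately dose-invariant while
mean branch length falls.

**Known limits.**
- Additive Gaussian noise, not Poisson/EMCCD statistics; uniform intensity
  along branches; no out-of-focus light or photobleaching.
- 45° orientation quantization trades visual realism for exact truth.
- In crowded fields, placement rejection preferentially discards long
  structures, so the realized branch-length distribution is slightly biased
  below the nominal one; the nominal mean is recovered in sparse fields.
- Curvature, perinuclear clustering and genuine 3-D structure are absent.

**Respirometry generator.** `generate_ocr_trace` takes the four free
components (ATP-linked, leak, non-mitochondrial, spare); plateau levels are
basal = nonmito+leak+ATP, oligomycin = nonmito+leak, FCCP = basal+spare,
rot/AA = nonmito, with optional Gaussian noise. The basal level is derived,
never passed, so inconsistent inputs are impossible.

## 4. Respirometry partition

Phase plateaus are estimated as: basal — last measurement (most stabilized),
oligomycin — minimum, FCCP — maximum, rot/AA — mean. Components: nonmito =
rot/AA; basal = basal_raw − nonmito; leak = oligo − nonmito; ATP-linked =
basal_raw − oligo; maximal = FCCP − nonmito; spare = maximal − basal. Values
are divided by the well's cell count (default 1, i.e. well-level pmol/min).
Noise can make a component negative; it is clamped to 0 and the result is
QC-flagged rather than silently altered.

## 5. Statistics

One-way ANOVA from explicit sums of squares (F = 0, p = 1 when the
between-group SS is zero; an all-constant dataset is rejected as degenerate).
Tukey HSD uses the Tukey–Kramer statistic for unequal n. The studentized
range tail P(Q > q | k, ν) is computed here as the standard double integral
over the pooled-SD density and the normal range kernel, evaluated with
fixed-order Gauss–Legendre quadrature (240 nodes, density in log-space for
stability); it matches an independent implementation to ~1e-8 in the tested
range and satisfies the exact two-group identity q = √2·|t|. The inverse
(critical values) is found by bracketed root-finding on the tail. Calibration
simulations (vectorized) confirm the null ANOVA rejection rate ≈ α and the
Tukey familywise error ≤ α.

## 6. Validation

`tests/` contains unit, property-based (hypothesis) and oracle tests:
brute-force Otsu/median/Gaussian oracles, path-walk branch-length oracles,
scipy/statsmodels cross-checks, geometric invariance (translation/rotation),
and end-to-end ground-truth recovery. `tests/test_acceptance.py` holds the
headline checks (exact Otsu equivalence on 200 random images; filter oracle
agreement within 1 DN; exact topology and tolerance-bounded length recovery
on 100 synthetic cells; membrane-potential recovery; exact OCR partition
round-trip; statistical calibration; and ≥90% power of the default
30-cell/dose design over 200 replicate studies). `scripts/acceptance.py`
recomputes the headline quantities from a single seed.
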