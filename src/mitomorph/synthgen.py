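"""Synthetic single-cell images and respirometry traces with exact ground truth.

The generator builds mitochondrial-like structures as trees of straight
branches on the pixel lattice: branch orientations are multiples of 45°
and branch lengths integer numbers of pixel steps, so the Euclidean
length of every truth polyline equals the path length of its
8-connected rasterization in the orthogonal/diagonal (1, √2) step
metric — the ground truth stays exact all the way through rendering.
Structures with at least one junction (a degree-3 branching point) are
"networks"; unbranched segments are "individuals".  Arm directions at a
junction are kept at least 90° apart so rasterized arms never touch
each other away from the junction pixel.

Rendering rasterizes the polylines at the mitochondrial intensity over
a constant background, applies a Gaussian point-spread blur, additive
Gaussian read noise (a deliberate simplification of Poisson shot
noise), quantizes to integer grey levels and clips to the bit depth.

Mito Stress Test traces are generated in the opposite direction from
the analysis: the caller states the respiratory components (ATP-linked,
proton leak, non-mitochondrial, spare capacity) and the generator emits
the four-phase OCR time course whose plateaus encode them, so the
partition can be validated by round-trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString
from shapely.ops import unary_union
from skimage.draw import line as _draw_line

from mitomorph.imgproc import CellImage
from mitomorph.respirometry import OCRTrace, PHASES

_SQRT2 = float(np.sqrt(2.0))

# the 8 lattice directions, 45° apart, as (drow, dcol)
_DIRS = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
)
_STEP_LEN = tuple(_SQRT2 if d[0] != 0 and d[1] != 0 else 1.0 for d in _DIRS)


class PlacementError(RuntimeError):
    """Raised when disjoint structure placement fails after bounded retries."""


# --------------------------------------------------------------------------
# distribution specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchLengthDist:
    """Branch-length distribution in µm.

    ``lognormal`` with log-scale parameters (mu, sigma), ``uniform`` on
    [low, high], or ``fixed`` at ``value``.  Lengths are truncated below
    at ``minimum`` so every branch spans at least a few pixels.
    """

    kind: str = "lognormal"
    mu: float = float(np.log(1.5))
    sigma: float = 0.35
    low: float = 1.0
    high: float = 3.0
    value: float = 1.5
    minimum: float = 0.5

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "lognormal":
            x = rng.lognormal(self.mu, self.sigma, size=n)
        elif self.kind == "uniform":
            x = rng.uniform(self.low, self.high, size=n)
        elif self.kind == "fixed":
            x = np.full(n, self.value)
        else:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        return np.maximum(x, self.minimum)

    def mean(self) -> float:
        """Analytic mean (ignoring the lower truncation)."""
        if self.kind == "lognormal":
            return float(np.exp(self.mu + self.sigma**2 / 2))
        if self.kind == "uniform":
            return 0.5 * (self.low + self.high)
        return self.value

    def scaled(self, factor: float) -> "BranchLengthDist":
        """Multiply the distribution by a positive factor."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        if self.kind == "lognormal":
            return replace(self, mu=self.mu + float(np.log(factor)),
                           minimum=self.minimum * factor)
        if self.kind == "uniform":
            return replace(self, low=self.low * factor, high=self.high * factor,
                           minimum=self.minimum * factor)
        return replace(self, value=self.value * factor, minimum=self.minimum * factor)


@dataclass(frozen=True)
class JunctionDist:
    """Distribution of junction counts per structure (probability vector
    over 0, 1, 2, ... junctions)."""

    probs: tuple[float, ...] = (0.4, 0.4, 0.2)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, float)
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("junction probabilities must be >= 0 and sum to 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(len(self.probs), size=n, p=self.probs)


# --------------------------------------------------------------------------
# imaging + truth containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagingParams:
    """Virtual-microscope settings.

    ``pixel_size`` µm/pixel, ``psf_sigma`` Gaussian point-spread sigma
    in µm, ``noise_sd`` additive Gaussian noise in grey levels,
    ``bit_depth`` 8 or 16, ``image_shape`` (rows, cols) in pixels.
    """

    pixel_size: float = 0.1
    psf_sigma: float = 0.1
    noise_sd: float = 3.0
    bit_depth: int = 8
    image_shape: tuple[int, int] = (160, 160)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.psf_sigma < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma and noise_sd must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass
class StructureTruth:
    """One connected structure: a tree of straight branches.

    ``branches`` are polylines as (k, 2) arrays of (row, col) points in
    µm; ``branch_lengths`` their exact Euclidean lengths in µm.
    """

    branches: list[np.ndarray]
    branch_lengths: list[float]
    n_junctions: int
    junction_points: list[tuple[float, float]]

    @property
    def is_network(self) -> bool:
        return self.n_junctions >= 1

    @property
    def n_endpoints(self) -> int:
        return self.n_junctions + 2

    @property
    def summed_length(self) -> float:
        return float(sum(self.branch_lengths))


@dataclass
class NetworkTruth:
    """Ground-truth geometry and intensity structure of one synthetic cell."""

    structures: list[StructureTruth]
    mito_intensity_mean: float
    background_intensity_mean: float
    params: ImagingParams

    def __post_init__(self) -> None:
        if self.mito_intensity_mean <= self.background_intensity_mean:
            raise ValueError(
                "mito_intensity_mean must exceed background_intensity_mean"
            )

    @property
    def contrast(self) -> float:
        return self.mito_intensity_mean - self.background_intensity_mean

    @property
    def n_networks(self) -> int:
        return sum(s.is_network for s in self.structures)

    @property
    def n_individuals(self) -> int:
        return len(self.structures) - self.n_networks

    def all_branch_lengths(self) -> np.ndarray:
        return np.array(
            [ln for s in self.structures for ln in s.branch_lengths]
        )

    def mean_branch_length(self) -> float:
        return float(self.all_branch_lengths().mean())

    def mean_summed_branch_length(self) -> float:
        sums = [s.summed_length for s in self.structures if s.is_network]
        return float(np.mean(sums)) if sums else float("nan")

    def to_json(self, path) -> None:
        payload = {
            "pixel_size": self.params.pixel_size,
            "mito_intensity_mean": self.mito_intensity_mean,
            "background_intensity_mean": self.background_intensity_mean,
            "structures": [
                {
                    "n_junctions": s.n_junctions,
                    "branch_lengths": s.branch_lengths,
                    "branches": [b.tolist() for b in s.branches],
                }
                for s in self.structures
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# --------------------------------------------------------------------------
# geometry construction
# --------------------------------------------------------------------------

def _length_to_steps(length_um: float, direction: int, pixel_size: float) -> int:
    steps = int(round(length_um / (pixel_size * _STEP_LEN[direction])))
    return max(steps, 2)


def _admissible_triples(back: int | None, rng: np.random.Generator) -> tuple[int, ...]:
    """Pick arm directions at a junction, pairwise >= 90° apart.

    ``back`` is the direction already occupied by the incoming branch
    (None for a fresh junction, which gets three arms).
    """
    need = 3 if back is None else 2
    fixed = () if back is None else (back,)
    for _ in range(64):
        cand = tuple(rng.choice(8, size=need, replace=False))
        dirs = fixed + cand
        ok = all(
            min(abs(a - b), 8 - abs(a - b)) >= 2
            for i, a in enumerate(dirs)
            for b in dirs[i + 1 :]
        )
        if ok:
            return cand
    raise PlacementError("could not choose junction arm directions")


def _build_structure(
    n_junctions: int,
    length_dist: BranchLengthDist,
    pixel_size: float,
    rng: np.random.Generator,
    max_retries: int = 50,
) -> StructureTruth:
    """Build one structure in integer pixel coordinates around the origin.

    Returns geometry in µm.  Retries on self-collision (non-adjacent
    branches closer than 2 pixels).
    """
    for _ in range(max_retries):
        segments: list[tuple[tuple[int, int], tuple[int, int]]] = []
        junctions: list[tuple[int, int]] = []
        if n_junctions == 0:
            d = int(rng.integers(8))
            steps = _length_to_steps(length_dist.sample(1, rng)[0], d, pixel_size)
            a = (0, 0)
            b = (a[0] + steps * _DIRS[d][0], a[1] + steps * _DIRS[d][1])
            segments.append((a, b))
        else:
            # first junction with three arms, then grow degree-3 junctions
            # out of randomly chosen leaves
            leaves: list[tuple[tuple[int, int], int]] = []  # (pixel, incoming dir)
            junctions.append((0, 0))
            for d in _admissible_triples(None, rng):
                steps = _length_to_steps(length_dist.sample(1, rng)[0], d, pixel_size)
                end = (steps * _DIRS[d][0], steps * _DIRS[d][1])
                segments.append(((0, 0), end))
                leaves.append((end, d))
            for _ in range(n_junctions - 1):
                if not leaves:
                    break
                idx = int(rng.integers(len(leaves)))
                node, incoming = leaves.pop(idx)
                junctions.append(node)
                back = (incoming + 4) % 8
                for d in _admissible_triples(back, rng):
                    steps = _length_to_steps(
                        length_dist.sample(1, rng)[0], d, pixel_size
                    )
                    end = (node[0] + steps * _DIRS[d][0],
                           node[1] + steps * _DIRS[d][1])
                    segments.append((node, end))
                    leaves.append((end, d))
        if _self_collision_free(segments):
            branches = [
                np.array([a, b], dtype=float) * pixel_size for a, b in segments
            ]
            lengths = [
                float(np.hypot(b[1, 0] - b[0, 0], b[1, 1] - b[0, 1]))
                for b in branches
            ]
            return StructureTruth(
                branches=branches,
                branch_lengths=lengths,
                n_junctions=len(junctions),
                junction_points=[
                    (j[0] * pixel_size, j[1] * pixel_size) for j in junctions
                ],
            )
    raise PlacementError(
        f"could not build a self-collision-free structure with "
        f"{n_junctions} junctions after {max_retries} attempts"
    )


def _self_collision_free(
    segments: list[tuple[tuple[int, int], tuple[int, int]]],
    min_gap: float = 2.0,
) -> bool:
    """Non-adjacent segments must stay at least ``min_gap`` pixels apart."""
    lines = [LineString([a, b]) for a, b in segments]
    for i in range(len(lines)):
        ai, bi = segments[i]
        for j in range(i + 1, len(lines)):
            aj, bj = segments[j]
            shared = {ai, bi} & {aj, bj}
            if shared:
                continue  # arms meeting at a junction are allowed to touch there
            if lines[i].distance(lines[j]) < min_gap:
                return False
    return True


def generate_network(
    n_structures: int,
    branch_length_dist: BranchLengthDist | None = None,
    junctions_per_structure: JunctionDist | None = None,
    seed: int = 0,
    *,
    params: ImagingParams | None = None,
    mito_intensity_mean: float = 150.0,
    background_intensity_mean: float = 30.0,
    ensure_disjoint: bool = True,
    min_separation: float | None = None,
    max_retries: int = 200,
) -> NetworkTruth:
    """Generate a synthetic cell: disjoint branched structures with exact truth.

    ``min_separation`` (µm) between distinct structures defaults to
    ``max(3 * psf_sigma, 3 * pixel_size)`` so point-spread blur cannot
    merge neighbouring structures.  Raises :class:`PlacementError` when
    the field cannot accommodate the requested structures.
    """
    if n_structures < 0:
        raise ValueError("n_structures must be >= 0")
    params = params or ImagingParams()
    length_dist = branch_length_dist or BranchLengthDist()
    junction_dist = junctions_per_structure or JunctionDist()
    rng = np.random.default_rng(seed)
    px = params.pixel_size
    if min_separation is None:
        min_separation = max(3.0 * params.psf_sigma, 3.0 * px)

    h, w = params.image_shape
    margin = max(2, int(np.ceil(3.0 * params.psf_sigma / px)) + 1)
    n_junc = junction_dist.sample(n_structures, rng)

    placed: list[StructureTruth] = []
    placed_geoms = []
    for k in range(n_structures):
        ok = False
        for _ in range(max_retries):
            s = _build_structure(int(n_junc[k]), length_dist, px, rng)
            pts = np.vstack([b for b in s.branches]) / px  # back to pixels
            rmin, cmin = pts.min(axis=0)
            rmax, cmax = pts.max(axis=0)
            if rmax - rmin > h - 2 * margin or cmax - cmin > w - 2 * margin:
                continue  # structure too large for the field; resample
            r_off = int(rng.integers(margin - int(rmin), h - margin - int(rmax) + 1))
            c_off = int(rng.integers(margin - int(cmin), w - margin - int(cmax) + 1))
            shifted = [
                b + np.array([r_off, c_off], float) * px for b in s.branches
            ]
            geom = unary_union(
                [LineString(b / px) for b in shifted]
            )
            if ensure_disjoint and placed_geoms:
                gap_px = min_separation / px
                if any(geom.distance(g) < gap_px for g in placed_geoms):
                    continue
            placed.append(
                StructureTruth(
                    branches=shifted,
                    branch_lengths=s.branch_lengths,
                    n_junctions=s.n_junctions,
                    junction_points=[
                        (jr + r_off * px, jc + c_off * px)
                        for jr, jc in s.junction_points
                    ],
                )
            )
            placed_geoms.append(geom)
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place structure {k + 1}/{n_structures} after "
                f"{max_retries} attempts; enlarge the field or reduce "
                f"n_structures/min_separation"
            )
    return NetworkTruth(
        structures=placed,
        mito_intensity_mean=mito_intensity_mean,
        background_intensity_mean=background_intensity_mean,
        params=params,
    )


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def rasterize(truth: NetworkTruth) -> np.ndarray:
    """Boolean raster of the truth polylines (8-connected lines)."""
    h, w = truth.params.image_shape
    px = truth.params.pixel_size
    canvas = np.zeros((h, w), dtype=bool)
    for s in truth.structures:
        for b in s.branches:
            pts = np.round(b / px).astype(int)
            for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
                if not (0 <= r0 < h and 0 <= c0 < w and 0 <= r1 < h and 0 <= c1 < w):
                    raise ValueError("truth coordinates fall outside the image")
                rr, cc = _draw_line(r0, c0, r1, c1)
                canvas[rr, cc] = True
    return canvas


def render_image(
    truth: NetworkTruth,
    params: ImagingParams | None = None,
    seed: int = 0,
    *,
    cell_id: str = "",
    group_label: str = "",
    quantize: bool = True,
) -> CellImage:
    """Render a truth geometry into a noisy blurred micrograph.

    Polylines are rasterized at the mitochondrial intensity over the
    background intensity, blurred with the Gaussian PSF, degraded with
    additive Gaussian noise, then (by default) rounded to integer grey
    levels and clipped to the bit depth.  The same seed yields an
    identical image.
    """
    params = params or truth.params
    max_val = float(2**params.bit_depth - 1)
    for v in (truth.mito_intensity_mean, truth.background_intensity_mean):
        if not 0 <= v <= max_val:
            raise ValueError(
                f"intensity {v} not representable at {params.bit_depth}-bit depth"
            )
    if (params.image_shape != truth.params.image_shape
            or params.pixel_size != truth.params.pixel_size):
        raise ValueError(
            "render params must match the geometry's pixel_size and image_shape"
        )
    fg = rasterize(truth)
    img = np.full(params.image_shape, truth.background_intensity_mean, dtype=float)
    img[fg] = truth.mito_intensity_mean
    if params.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, params.psf_sigma / params.pixel_size,
                                      mode="nearest")
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    if quantize:
        img = np.round(img)
    img = np.clip(img, 0.0, max_val)
    return CellImage(img, params.pixel_size, params.bit_depth, cell_id, group_label)


# --------------------------------------------------------------------------
# dose-effect study
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseEffectSpec:
    """Dose-dependent shifts applied to the generated cells.

    ``branch_length_scale`` multiplies every branch length of a dose
    group (fragmentation < 1, fusion > 1); ``potential_scale``
    multiplies the mitochondria/background intensity contrast
    (membrane-potential proxy).  Defaults emulate a graded
    fragmentation-plus-depolarization phenotype across control / low /
    high zinc doses.
    """

    dose_labels: tuple[str, ...] = ("control", "zn5", "zn50")
    branch_length_scale: tuple[float, ...] = (1.0, 0.8, 0.6)
    potential_scale: tuple[float, ...] = (1.0, 0.85, 0.7)
    cells_per_dose: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.dose_labels)
        if len(self.branch_length_scale) != k or len(self.potential_scale) != k:
            raise ValueError("scale tuples must match dose_labels in length")
        if any(s <= 0 for s in self.branch_length_scale + self.potential_scale):
            raise ValueError("all scale factors must be positive")
        if self.cells_per_dose < 2:
            raise ValueError("cells_per_dose must be >= 2")


def generate_dose_study(
    spec: DoseEffectSpec,
    *,
    params: ImagingParams | None = None,
    branch_length_dist: BranchLengthDist | None = None,
    junctions_per_structure: JunctionDist | None = None,
    n_structures: int = 8,
    mito_intensity_mean: float = 150.0,
    background_intensity_mean: float = 30.0,
):
    """Yield ``(truth, image)`` pairs for every cell of a dose study.

    Fragmentation approximately conserves mitochondrial mass: when a
    dose scales branch lengths by f, the number of structures per cell
    is scaled by 1/f (shorter but more numerous structures), mirroring
    the fission phenotype where footprint stays roughly constant while
    branch length falls.  Cell seeds are derived deterministically from
    ``spec.seed`` so the whole study is reproducible.
    """
    params = params or ImagingParams()
    base_dist = branch_length_dist or BranchLengthDist()
    base_contrast = mito_intensity_mean - background_intensity_mean
    seed_rng = np.random.default_rng(spec.seed)
    for d, label in enumerate(spec.dose_labels):
        dist = base_dist.scaled(spec.branch_length_scale[d])
        mito = background_intensity_mean + base_contrast * spec.potential_scale[d]
        n_structs = max(1, round(n_structures / spec.branch_length_scale[d]))
        for i in range(spec.cells_per_dose):
            s1, s2 = (int(x) for x in seed_rng.integers(0, 2**31 - 1, size=2))
            cell_id = f"{label}_{i:03d}"
            truth = generate_network(
                n_structs,
                dist,
                junctions_per_structure,
                seed=s1,
                params=params,
                mito_intensity_mean=mito,
                background_intensity_mean=background_intensity_mean,
            )
            img = render_image(truth, params, seed=s2,
                               cell_id=cell_id, group_label=label)
            yield truth, img


# --------------------------------------------------------------------------
# respirometry traces
# --------------------------------------------------------------------------

def generate_ocr_trace(
    atp_linked: float,
    leak: float,
    nonmito: float,
    spare: float,
    n_measurements_per_phase: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    ecar_basal: float = 20.0,
    cell_count: int = 1,
    interval_min: float = 6.5,
    well_id: str = "A1",
    group_label: str = "",
) -> OCRTrace:
    """Synthesize a four-phase Mito Stress Test OCR/ECAR trace.

    Plateaus encode the stated components (all in pmol O₂/min, raw,
    i.e. before cell-count normalization):

    * basal phase:        nonmito + leak + atp_linked
    * post-oligomycin:    nonmito + leak
    * post-FCCP:          nonmito + leak + atp_linked + spare
    * post-rotenone/AA:   nonmito

    Gaussian noise of ``noise_sd`` is added to every measurement.
    """
    for name, v in (("atp_linked", atp_linked), ("leak", leak),
                    ("nonmito", nonmito), ("spare", spare)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if n_measurements_per_phase < 1:
        raise ValueError("n_measurements_per_phase must be >= 1")
    plateaus = {
        "basal": nonmito + leak + atp_linked,
        "oligomycin": nonmito + leak,
        "fccp": nonmito + leak + atp_linked + spare,
        "rot_aa": nonmito,
    }
    rng = np.random.default_rng(seed)
    rows = []
    t = 0.0
    for phase in PHASES:
        for _ in range(n_measurements_per_phase):
            ocr = plateaus[phase]
            ecar = ecar_basal
            if noise_sd > 0:
                ocr += rng.normal(0.0, noise_sd)
                ecar += rng.normal(0.0, noise_sd)
            rows.append((t, phase, ocr, ecar))
            t += interval_min
    df = pd.DataFrame(rows, columns=["time_min", "phase", "ocr", "ecar"])
    return OCRTrace(df, well_id=well_id, group_label=group_label,
                    cell_count=cell_count)


def generate_trace_study(
    group_components: dict[str, tuple[float, float, float, float]],
    wells_per_group: int = 6,
    noise_sd: float = 5.0,
    seed: int = 0,
    *,
    cell_count: int = 1,
    n_measurements_per_phase: int = 3,
) -> list[OCRTrace]:
    """Generate a multi-well study: for each group label, ``wells_per_group``
    traces from the stated (atp_linked, leak, nonmito, spare) raw components.

    ``cell_count`` defaults to 1, i.e. OCR stays in well-level pmol/min;
    supply the seeded cells per well to get per-cell normalization.
    """
    seed_rng = np.random.default_rng(seed)
    traces = []
    for label, comps in group_components.items():
        for w in range(wells_per_group):
            traces.append(
                generate_ocr_trace(
                    *comps,
                    n_measurements_per_phase=n_measurements_per_phase,
                    noise_sd=noise_sd,
                    seed=int(seed_rng.integers(0, 2**31 - 1)),
                    cell_count=cell_count,
                    well_id=f"{label}_{w:02d}",
                    group_label=label,
                )
            )
    return traces


def traces_to_csv(traces: list[OCRTrace], path) -> None:
    """Write traces as a flat CSV (time_min, phase, ocr, ecar, well, group,
    cell_count)."""
    frames = []
    for tr in traces:
        df = tr.measurements.copy()
        df["well"] = tr.well_id
        df["group"] = tr.group_label
        df["cell_count"] = tr.cell_count
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def traces_from_csv(path) -> list[OCRTrace]:
    """Read traces written by :func:`traces_to_csv`."""
    df = pd.read_csv(path)
    traces = []
    for well, sub in df.groupby("well", sort=False):
        sub = sub.sort_values("time_min").reset_index(drop=True)
        traces.append(
            OCRTrace(
                sub[["time_min", "phase", "ocr", "ecar"]],
                well_id=str(well),
                group_label=str(sub["group"].iloc[0]),
                cell_count=int(sub["cell_count"].iloc[0]),
            )
        )
    return traces
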