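"""End-to-end studies: synthetic generation → analysis → group statistics.

A study is described by a flat declarative configuration (YAML on disk)
with a strict schema — unknown keys are errors, because silently
misspelled keys are a classic failure mode of scientific configs.  Runs
are fully deterministic for a fixed seed and emit a manifest (config
hash, seeds, library versions) sufficient to reproduce them.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mitomorph import __version__
from mitomorph.imgproc import (
    CellImage,
    PreprocessParams,
    PREPROCESS_PRESETS,
    binarize,
    membrane_potential,
    otsu_threshold,
    preprocess,
)
from mitomorph.morphometrics import (
    MorphometricsRecord,
    compute_morphometrics,
    extract_graph,
    skeletonize,
)
from mitomorph.respirometry import partition, results_to_frame, summarize_groups
from mitomorph.stats import ComparisonResult, compare_endpoints
from mitomorph import synthgen

IMAGING_ENDPOINTS = (
    "mean_branch_length",
    "mean_summed_branch_length",
    "footprint_um2",
    "membrane_potential",
)
RESPIROMETRY_ENDPOINTS = (
    "basal", "maximal", "atp_linked", "leak", "nonmito", "spare", "ecar_basal",
)


class ConfigError(ValueError):
    """Invalid or unknown study configuration."""


def _take(d: dict, allowed: set[str], where: str) -> dict:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    return d


@dataclass
class ImagingStudyConfig:
    cell_type: str = "rasmc"
    pixel_size: float = 0.1
    psf_sigma: float = 0.1
    noise_sd: float = 3.0
    image_shape: tuple[int, int] = (160, 160)
    n_structures: int = 8
    dose_labels: tuple[str, ...] = ("control", "zn5", "zn50")
    branch_length_scale: tuple[float, ...] = (1.0, 0.8, 0.6)
    potential_scale: tuple[float, ...] = (1.0, 0.85, 0.7)
    cells_per_dose: int = 30
    image_dir: str | None = None  # analyze existing TIFFs instead of simulating
    tmrm_on_preprocessed: bool = False
    drop_zero_branch_cells: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "ImagingStudyConfig":
        d = _take(dict(d), set(cls.__dataclass_fields__), "imaging")
        for key in ("image_shape", "dose_labels", "branch_length_scale",
                    "potential_scale"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        if cfg.cell_type not in PREPROCESS_PRESETS:
            raise ConfigError(
                f"unknown cell_type {cfg.cell_type!r}; "
                f"available: {sorted(PREPROCESS_PRESETS)}"
            )
        return cfg


@dataclass
class RespirometryStudyConfig:
    # per-group raw components (atp_linked, leak, nonmito, spare), pmol O2/min
    groups: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "control": (60.0, 30.0, 10.0, 40.0),
            "zn5": (55.0, 32.0, 10.0, 35.0),
            "zn50": (45.0, 35.0, 10.0, 25.0),
        }
    )
    wells_per_group: int = 6
    noise_sd: float = 4.0
    cell_count: int = 1  # 1 = report well-level OCR; set seeded cells/well to normalize
    n_measurements_per_phase: int = 3
    trace_csv: str | None = None  # analyze existing traces instead of simulating

    @classmethod
    def from_dict(cls, d: dict) -> "RespirometryStudyConfig":
        d = _take(dict(d), set(cls.__dataclass_fields__), "respirometry")
        if "groups" in d:
            d["groups"] = {str(k): tuple(v) for k, v in d["groups"].items()}
        return cls(**d)


@dataclass
class RunConfig:
    seed: int = 0
    alpha: float = 0.05
    output_dir: str | None = None
    imaging: ImagingStudyConfig = field(default_factory=ImagingStudyConfig)
    respirometry: RespirometryStudyConfig = field(
        default_factory=RespirometryStudyConfig
    )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = _take(dict(d), set(cls.__dataclass_fields__), "top level")
        imaging = ImagingStudyConfig.from_dict(d.pop("imaging", {}))
        resp = RespirometryStudyConfig.from_dict(d.pop("respirometry", {}))
        return cls(imaging=imaging, respirometry=resp, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)

    def manifest(self) -> dict:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return {
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": self.seed,
            "mitomorph_version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
        }


# --------------------------------------------------------------------------
# per-cell analysis
# --------------------------------------------------------------------------

def analyze_cell(
    img: CellImage,
    params: PreprocessParams,
    tmrm_on_preprocessed: bool = False,
) -> MorphometricsRecord:
    """Full single-cell analysis: segmentation, TMRM potential, morphometrics.

    Morphology uses the sharpened/median-filtered image; the TMRM
    potential by default uses the raw image with an Otsu mask derived
    from that raw image (set ``tmrm_on_preprocessed`` to reuse the
    preprocessed segmentation instead).
    """
    work = preprocess(img, params)
    mask = binarize(work, otsu_threshold(work))
    if tmrm_on_preprocessed:
        potential = membrane_potential(img, mask)
    else:
        raw_mask = binarize(img, otsu_threshold(img))
        potential = membrane_potential(img, raw_mask)
    skel = skeletonize(mask)
    graph = extract_graph(skel)
    return compute_morphometrics(
        graph, mask, potential, cell_id=img.cell_id, group=img.group_label
    )


@dataclass
class StudyReport:
    """Per-item results table, group statistics, and a reproducibility manifest."""

    records: pd.DataFrame
    stats: list[ComparisonResult]
    manifest: dict
    group_summary: pd.DataFrame | None = None

    def stats_frame(self) -> pd.DataFrame:
        return pd.concat([r.to_frame() for r in self.stats], ignore_index=True)

    def summary(self) -> str:
        parts = [r.summary() for r in self.stats]
        flags = self.records.get("flags")
        if flags is not None:
            n_flagged = int((flags.fillna("") != "").sum())
            if n_flagged:
                parts.append(f"QC: {n_flagged} rows carry flags")
        return "\n\n".join(parts)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        self.stats_frame().to_csv(out / "stats.csv", index=False)
        if self.group_summary is not None:
            self.group_summary.to_csv(out / "group_summary.csv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1)
        with open(out / "report.txt", "w") as fh:
            fh.write(self.summary() + "\n")


# --------------------------------------------------------------------------
# studies
# --------------------------------------------------------------------------

def run_imaging_study(config: RunConfig) -> StudyReport:
    """Dose study on synthetic (or supplied) single-cell images.

    Generates (or loads) cells per dose group, runs the per-cell
    analysis and compares every morphology endpoint across groups with
    ANOVA + Tukey HSD.
    """
    icfg = config.imaging
    params = PREPROCESS_PRESETS[icfg.cell_type]

    images: list[CellImage] = []
    if icfg.image_dir is not None:
        paths = sorted(Path(icfg.image_dir).glob("*.tif*"))
        if not paths:
            raise ConfigError(f"no TIFF images found in {icfg.image_dir!r}")
        for p in paths:
            # file name convention: <group>_<cellid>.tif
            group = p.stem.split("_")[0]
            images.append(
                CellImage.from_tiff(p, icfg.pixel_size, cell_id=p.stem,
                                    group_label=group)
            )
    else:
        spec = synthgen.DoseEffectSpec(
            dose_labels=icfg.dose_labels,
            branch_length_scale=icfg.branch_length_scale,
            potential_scale=icfg.potential_scale,
            cells_per_dose=icfg.cells_per_dose,
            seed=config.seed,
        )
        imaging_params = synthgen.ImagingParams(
            pixel_size=icfg.pixel_size,
            psf_sigma=icfg.psf_sigma,
            noise_sd=icfg.noise_sd,
            image_shape=icfg.image_shape,
        )
        for _, img in synthgen.generate_dose_study(
            spec, params=imaging_params, n_structures=icfg.n_structures
        ):
            images.append(img)

    rows = []
    for img in images:
        try:
            rec = analyze_cell(img, params, icfg.tmrm_on_preprocessed)
        except Exception as exc:
            raise RuntimeError(f"analysis failed for cell {img.cell_id!r}") from exc
        rows.append(rec.to_dict())
    records = pd.DataFrame(rows)
    if icfg.drop_zero_branch_cells:
        records = records[records["n_branches"] > 0].reset_index(drop=True)

    stats = compare_endpoints(records, list(IMAGING_ENDPOINTS),
                              alpha=config.alpha)
    return StudyReport(records, stats, config.manifest())


def run_respirometry_study(config: RunConfig) -> StudyReport:
    """Mito Stress Test study: per-well partition + group comparison."""
    rcfg = config.respirometry
    if rcfg.trace_csv is not None:
        traces = synthgen.traces_from_csv(rcfg.trace_csv)
        if not traces:
            raise ConfigError(f"no traces found in {rcfg.trace_csv!r}")
    else:
        traces = synthgen.generate_trace_study(
            rcfg.groups,
            wells_per_group=rcfg.wells_per_group,
            noise_sd=rcfg.noise_sd,
            seed=config.seed,
            cell_count=rcfg.cell_count,
            n_measurements_per_phase=rcfg.n_measurements_per_phase,
        )
    results = []
    for tr in traces:
        try:
            results.append(partition(tr))
        except Exception as exc:
            raise RuntimeError(f"partition failed for well {tr.well_id!r}") from exc
    records = results_to_frame(results).rename(columns={"qc_flags": "flags"})
    summary = summarize_groups(results)
    stats = compare_endpoints(records, list(RESPIROMETRY_ENDPOINTS),
                              alpha=config.alpha)
    return StudyReport(records, stats, config.manifest(), group_summary=summary)
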