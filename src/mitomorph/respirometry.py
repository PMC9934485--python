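"""Mito Stress Test OCR partitioning.

An extracellular-flux Mito Stress Test measures the oxygen consumption
rate (OCR) of a well of cells through four phases separated by
injections: basal, after oligomycin (blocks ATP synthase), after FCCP
(uncouples, drives maximal respiration) and after rotenone/antimycin A
(shuts down the electron transport chain, leaving only
non-mitochondrial oxygen consumption).  From the four plateaus the
basal OCR is partitioned into ATP-linked, proton-leak and
non-mitochondrial components, and maximal/spare respiratory capacity is
derived; everything is normalized to the cell count of the well.

Plateau estimators follow the instrument vendor's conventions: the last
basal measurement (avoids equilibration drift), the minimum after
oligomycin, the maximum after FCCP, and the mean after rotenone/
antimycin A.  All four are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Injection phases in protocol order.
PHASES = ("basal", "oligomycin", "fccp", "rot_aa")

#: Default plateau estimator per phase.
DEFAULT_ESTIMATORS = {
    "basal": "last",
    "oligomycin": "min",
    "fccp": "max",
    "rot_aa": "mean",
}

_ESTIMATOR_FUNCS = {
    "last": lambda x: float(x.iloc[-1]),
    "first": lambda x: float(x.iloc[0]),
    "min": lambda x: float(x.min()),
    "max": lambda x: float(x.max()),
    "mean": lambda x: float(x.mean()),
}


@dataclass
class OCRTrace:
    """Timed OCR/ECAR measurements for one well.

    ``measurements`` has columns ``time_min``, ``phase`` (one of
    :data:`PHASES`), ``ocr`` (pmol O₂/min) and ``ecar`` (mpH/min),
    ordered in time with phases in protocol order.
    """

    measurements: pd.DataFrame
    well_id: str = ""
    group_label: str = ""
    cell_count: int = 1

    def __post_init__(self) -> None:
        df = self.measurements
        required = {"time_min", "phase", "ocr", "ecar"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trace missing columns: {sorted(missing)}")
        if self.cell_count <= 0:
            raise ValueError("cell_count must be positive")
        present = list(dict.fromkeys(df["phase"]))
        for ph in present:
            if ph not in PHASES:
                raise ValueError(f"unknown phase {ph!r}")
        expected = [ph for ph in PHASES if ph in present]
        if present != expected:
            raise ValueError(
                f"phases out of protocol order: {present} (expected subsequence "
                f"of {list(PHASES)})"
            )

    def phase_values(self, phase: str) -> pd.Series:
        sel = self.measurements.loc[self.measurements["phase"] == phase, "ocr"]
        if sel.empty:
            raise ValueError(f"missing phase: {phase!r} in well {self.well_id!r}")
        return sel


@dataclass
class PartitionResult:
    """Per-cell-normalized respiratory components of one well.

    Identities (before any clamping): ``basal = atp_linked + leak`` and
    ``maximal = basal + spare``.  Negative corrected components are
    clamped to 0 and named in ``qc_flags``.
    """

    well_id: str
    group_label: str
    nonmito: float
    leak: float
    atp_linked: float
    basal: float
    maximal: float
    spare: float
    ecar_basal: float
    qc_flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "well_id": self.well_id,
            "group": self.group_label,
            "nonmito": self.nonmito,
            "leak": self.leak,
            "atp_linked": self.atp_linked,
            "basal": self.basal,
            "maximal": self.maximal,
            "spare": self.spare,
            "ecar_basal": self.ecar_basal,
            "qc_flags": ";".join(self.qc_flags),
        }


def partition(
    trace: OCRTrace,
    estimators: dict[str, str] | None = None,
) -> PartitionResult:
    """Partition one well's trace into its respiratory components.

    Raw plateaus are estimated per phase, the non-mitochondrial plateau
    is subtracted, and everything is divided by the well's cell count:

    * ``nonmito``     = rot/AA plateau
    * ``basal``       = basal plateau − nonmito
    * ``leak``        = oligomycin plateau − nonmito
    * ``atp_linked``  = basal plateau − oligomycin plateau
    * ``maximal``     = FCCP plateau − nonmito
    * ``spare``       = maximal − basal

    Negative mitochondrial components are clamped to 0 with a QC flag
    (noisy wells occur; the flag preserves auditability).
    """
    est = dict(DEFAULT_ESTIMATORS)
    if estimators:
        unknown = set(estimators) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phases in estimators: {sorted(unknown)}")
        est.update(estimators)

    raw = {}
    for phase in PHASES:
        values = trace.phase_values(phase)  # raises on missing phase
        raw[phase] = _ESTIMATOR_FUNCS[est[phase]](values)

    n = trace.cell_count
    nonmito = raw["rot_aa"] / n
    basal = (raw["basal"] - raw["rot_aa"]) / n
    leak = (raw["oligomycin"] - raw["rot_aa"]) / n
    atp_linked = (raw["basal"] - raw["oligomycin"]) / n
    maximal = (raw["fccp"] - raw["rot_aa"]) / n
    spare = maximal - basal

    flags = []
    clamped = {}
    for name, value in (("basal", basal), ("leak", leak),
                        ("atp_linked", atp_linked), ("maximal", maximal),
                        ("spare", spare)):
        if value < 0:
            flags.append(f"clamped_{name}")
            value = 0.0
        clamped[name] = value

    ecar_basal = float(
        trace.measurements.loc[trace.measurements["phase"] == "basal", "ecar"].mean()
    ) / n

    return PartitionResult(
        well_id=trace.well_id,
        group_label=trace.group_label,
        nonmito=nonmito,
        leak=clamped["leak"],
        atp_linked=clamped["atp_linked"],
        basal=clamped["basal"],
        maximal=clamped["maximal"],
        spare=clamped["spare"],
        ecar_basal=ecar_basal,
        qc_flags=tuple(flags),
    )


_COMPONENTS = ("nonmito", "leak", "atp_linked", "basal", "maximal", "spare",
               "ecar_basal")


def results_to_frame(results: list[PartitionResult]) -> pd.DataFrame:
    """Tabulate partition results, one row per well."""
    if not results:
        raise ValueError("no partition results given")
    return pd.DataFrame([r.to_dict() for r in results])


def summarize_groups(results: list[PartitionResult]) -> pd.DataFrame:
    """Per-group mean ± SD of every respiratory component.

    Returns a table indexed by group with ``<component>_mean`` and
    ``<component>_sd`` columns.  Every group needs at least two wells.
    """
    df = results_to_frame(results)
    counts = df.groupby("group").size()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(
            f"groups with fewer than 2 wells: {sorted(small.index)}"
        )
    agg = df.groupby("group")[list(_COMPONENTS)].agg(["mean", "std"])
    agg.columns = [
        f"{comp}_sd" if stat == "std" else f"{comp}_{stat}"
        for comp, stat in agg.columns
    ]
    agg["n"] = counts
    return agg
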