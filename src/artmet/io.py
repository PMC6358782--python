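"""Readers and writers: delimited peak tables, MGF, reports, run configs.

The delimited peak-table format is a tab-separated file with the header
``sample_id  system  energy  mz  rt_min  intensity``; unknown extra columns
are preserved as opaque metadata on read. MGF input is mapped so that each
spectrum block's PEPMASS becomes a low-energy precursor peak and its peak
list the high-energy channel.

All m/z values are written with 4 decimals and mass errors with 1 decimal,
matching the reporting precision of accurate-mass metabolite tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .fragments import AnnotatedMetabolite
from .peaks import Peak, PeakTable

__all__ = [
    "RunConfig",
    "read_peak_table",
    "write_peak_table",
    "read_mgf",
    "write_annotation_report",
    "load_config",
]

REQUIRED_COLUMNS = ("sample_id", "system", "energy", "mz", "rt_min", "intensity")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run settings (tolerances per the accurate-mass workflow:
    +-2 mDa precursor, 0.5 Da fragment, 0.1 min retention alignment, at most
    10 fragment ions per match)."""

    parent: str = "C15H22O5"
    max_steps: int = 3
    adducts: tuple[str, ...] = ("M+H", "M+Na", "M+K")
    precursor_tol_mda: float = 2.0
    fragment_tol_da: float = 0.5
    rt_tol_min: float = 0.1
    fragment_cap: int = 10
    max_loss_depth: int = 4
    allow_h2: bool = True
    min_coverage: float = 0.5
    seed: int = 0
    rules: tuple = ()  # empty -> default rule set
    losses: tuple = ()  # empty -> default loss registry

    def __post_init__(self) -> None:
        if min(self.precursor_tol_mda, self.fragment_tol_da, self.rt_tol_min) <= 0:
            raise ValueError("all tolerances must be > 0")
        if self.fragment_cap < 1:
            raise ValueError("fragment cap must be >= 1")


def load_config(path) -> RunConfig:
    """Load a YAML run config; unspecified fields keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {k: v for k, v in raw.items() if k in RunConfig.__dataclass_fields__}
    for key in ("adducts", "rules", "losses"):
        if key in known and isinstance(known[key], list):
            known[key] = tuple(known[key])
    return RunConfig(**known)


def read_peak_table(path, format: str = "delimited") -> list[PeakTable]:
    """Read peak tables from a delimited file or MGF.

    One file may hold several samples; one :class:`PeakTable` is returned
    per distinct ``sample_id``.
    """
    if format == "mgf":
        return [read_mgf(path)]
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}; expected 'delimited' or 'mgf'")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if frame.empty and not frame.columns.size:
        warnings.warn(f"{path}: empty peak-table file")
        return []
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    tables = []
    for sample_id, group in frame.groupby("sample_id", sort=True):
        peaks = []
        system = "other"
        for row in group.itertuples():
            try:
                mz = float(row.mz)
                rt = float(row.rt_min)
                intensity = float(row.intensity)
            except ValueError as exc:
                # +2: itertuples Index is 0-based on data rows, header is line 1
                raise ValueError(f"{path}: non-numeric value at line {row.Index + 2}: {exc}")
            system = row.system
            peaks.append(Peak(mz=mz, rt_min=rt, intensity=intensity, energy=row.energy))
        tables.append(PeakTable(str(sample_id), system, tuple(peaks)))
    if not tables:
        warnings.warn(f"{path}: no peaks found")
    return tables


def write_peak_table(tables: PeakTable | Iterable[PeakTable], path) -> None:
    if isinstance(tables, PeakTable):
        tables = [tables]
    rows = [
        {
            "sample_id": t.sample_id,
            "system": t.system,
            "energy": p.energy,
            "mz": f"{p.mz:.4f}",
            "rt_min": f"{p.rt_min:.3f}",
            "intensity": f"{p.intensity:.1f}",
        }
        for t in tables
        for p in t.peaks
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_mgf(path, sample_id: str | None = None, system: str = "other") -> PeakTable:
    """Read an MGF file: PEPMASS -> low-energy precursor peak, the peak list
    -> high-energy channel; RTINSECONDS (when present) sets retention time."""
    from pyteomics import mgf

    peaks: list[Peak] = []
    with mgf.MGF(str(path)) as reader:
        for spectrum in reader:
            params = spectrum.get("params", {})
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            pepmass = params.get("pepmass", (0.0,))
            precursor_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            if precursor_mz:
                peaks.append(Peak(precursor_mz, rt, 1.0, "low"))
            for mz, intensity in zip(
                spectrum.get("m/z array", []), spectrum.get("intensity array", [])
            ):
                peaks.append(Peak(float(mz), rt, float(intensity), "high"))
    return PeakTable(sample_id or Path(path).stem, system, tuple(peaks))


def write_annotation_report(annotated: Sequence[AnnotatedMetabolite], path) -> None:
    """Write fragment annotations as delimited text: one row per assignment,
    plus a coverage row per metabolite."""
    rows = []
    for i, ann in enumerate(annotated):
        match = ann.match
        base = {
            "metabolite": f"{match.candidate.label}@{match.peak.rt_min:.2f}",
            "adduct": match.adduct,
            "precursor_mz": f"{match.peak.mz:.4f}",
            "error_mda": f"{match.reported_error_mda:.1f}",
            "coverage": "NA" if ann.coverage is None else f"{ann.coverage:.3f}",
        }
        if not ann.assignments:
            rows.append({**base, "fragment_mz": "", "loss_path": "", "h2": ""})
        for a in ann.assignments:
            rows.append(
                {
                    **base,
                    "fragment_mz": f"{a.observed_mz:.4f}",
                    "loss_path": "+".join(a.losses) or "(none)",
                    "h2": {0: "", 1: "+H2", -1: "-H2"}[a.h2],
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "metabolite",
            "adduct",
            "precursor_mz",
            "error_mda",
            "coverage",
            "fragment_mz",
            "loss_path",
            "h2",
        ],
    ).to_csv(path, sep="\t", index=False)
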