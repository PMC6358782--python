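"""Cross-system comparison of identified metabolites and fixture auditing.

The headline question of the underlying study is whether a fungal
biotransformation system reproduces mammalian metabolism: which metabolites
appear in mouse plasma (in vivo), which in fermentation broth (in vitro),
and which in both. This module joins metabolite records across the two
systems, tallies component classes, extracts per-class retention-time
windows, and audits every printed observation for internal consistency
(recomputing each mass error from the printed formula, adduct and observed
m/z).

The packaged reference table stores the published values verbatim —
including rows known to be internally inconsistent (typos in the printed
formula or observed m/z). ``validate_fixture`` reports such rows; it never
repairs them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Sequence

import pandas as pd

from .chem import Adduct, Formula, ion_mz, mass_error_mda, parse_ion, reported_mda

__all__ = [
    "Observation",
    "MetaboliteRecord",
    "ComparisonReport",
    "ConsistencyFinding",
    "load_reference_table",
    "compare_systems",
    "class_counts",
    "rt_range",
    "validate_fixture",
]


@dataclass(frozen=True)
class Observation:
    """One per-system accurate-mass observation as printed."""

    mz: float
    error_mda: float


@dataclass(frozen=True)
class MetaboliteRecord:
    """One row of the metabolite summary table.

    ``ion_text`` is the verbatim printed formula + adduct; ``formula`` and
    ``adduct`` are its parsed form. At least one of the per-system
    observations is present; the fragment list is never empty.
    """

    metabolite_id: str
    component: str
    ion_text: str
    formula: Formula
    adduct: Adduct
    rt_min: float
    in_vivo: Observation | None
    in_vitro: Observation | None
    fragments: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.in_vivo is None and self.in_vitro is None:
            raise ValueError(
                f"{self.metabolite_id}: at least one system observation required"
            )
        if not self.fragments:
            raise ValueError(f"{self.metabolite_id}: fragment list must be non-empty")

    def observation(self, system: str) -> Observation | None:
        if system == "in_vivo":
            return self.in_vivo
        if system == "in_vitro":
            return self.in_vitro
        raise ValueError(f"unknown system {system!r}")


@dataclass(frozen=True)
class ComparisonReport:
    in_vivo_ids: tuple[str, ...]
    in_vitro_ids: tuple[str, ...]
    common_ids: tuple[str, ...]
    class_counts: dict[str, dict[str, int]]  # selector -> class -> count
    rt_ranges: dict[str, tuple[float, float]]  # class -> (min rt, max rt)

    @property
    def counts(self) -> tuple[int, int, int]:
        """(in vivo, in vitro, common) set sizes — the Venn headline."""
        return (len(self.in_vivo_ids), len(self.in_vitro_ids), len(self.common_ids))


def _parse_cell(value: object) -> float | None:
    text = str(value).strip()
    if text in ("", "-", "nan", "None"):
        return None
    return float(text)


def load_reference_table(path=None) -> list[MetaboliteRecord]:
    """Load the packaged metabolite summary table (or a user TSV with the
    same columns) into validated records."""
    if path is None:
        source = resources.files("artmet.data").joinpath("table1.tsv")
        with resources.as_file(source) as p:
            frame = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in frame.itertuples(index=False):
        formula, adduct = parse_ion(row.ion)
        vivo_mz = _parse_cell(row.in_vivo_mz)
        vivo_err = _parse_cell(row.in_vivo_err_mda)
        vitro_mz = _parse_cell(row.in_vitro_mz)
        vitro_err = _parse_cell(row.in_vitro_err_mda)
        records.append(
            MetaboliteRecord(
                metabolite_id=row.id,
                component=row.component,
                ion_text=row.ion,
                formula=formula,
                adduct=adduct,
                rt_min=float(row.rt_min),
                in_vivo=Observation(vivo_mz, vivo_err) if vivo_mz is not None else None,
                in_vitro=Observation(vitro_mz, vitro_err)
                if vitro_mz is not None
                else None,
                fragments=tuple(
                    int(x) for x in str(row.fragments).split(",") if x.strip()
                ),
            )
        )
    return records


def compare_systems(records: Sequence[MetaboliteRecord]) -> ComparisonReport:
    """Venn comparison of the in vivo and in vitro metabolite sets.

    Set membership is presence of the per-system observation; the common set
    is the exact intersection. Output ordering is by metabolite id, so the
    report is invariant to record order. Duplicate ids are rejected.
    """
    ids = [r.metabolite_id for r in records]
    dupes = [i for i, n in Counter(ids).items() if n > 1]
    if dupes:
        raise ValueError(f"duplicate metabolite ids: {sorted(dupes)}")
    ordered = sorted(records, key=lambda r: _id_key(r.metabolite_id))
    vivo = tuple(r.metabolite_id for r in ordered if r.in_vivo is not None)
    vitro = tuple(r.metabolite_id for r in ordered if r.in_vitro is not None)
    common = tuple(i for i in vivo if i in set(vitro))
    selectors = {
        "all": None,
        "in_vivo": "in_vivo",
        "in_vitro": "in_vitro",
        "common": "common",
    }
    per_class = {name: class_counts(records, sel) for name, sel in selectors.items()}
    ranges = {
        component: rt_range(records, component)
        for component in sorted({r.component for r in records})
    }
    return ComparisonReport(vivo, vitro, common, per_class, ranges)


def _id_key(metabolite_id: str):
    digits = "".join(c for c in metabolite_id if c.isdigit())
    return (int(digits) if digits else 0, metabolite_id)


def _select(
    records: Sequence[MetaboliteRecord],
    selector: str | None | Callable[[MetaboliteRecord], bool],
) -> list[MetaboliteRecord]:
    if selector is None or selector == "all":
        return list(records)
    if callable(selector):
        return [r for r in records if selector(r)]
    if selector == "in_vivo":
        return [r for r in records if r.in_vivo is not None]
    if selector == "in_vitro":
        return [r for r in records if r.in_vitro is not None]
    if selector == "common":
        return [r for r in records if r.in_vivo is not None and r.in_vitro is not None]
    raise ValueError(f"unknown selector {selector!r}")


def class_counts(
    records: Sequence[MetaboliteRecord],
    selector: str | None | Callable[[MetaboliteRecord], bool] = None,
) -> dict[str, int]:
    """Per-component-class counts within the selected set; the counts sum to
    the set size."""
    chosen = _select(records, selector)
    return dict(Counter(r.component for r in chosen))


def rt_range(
    records: Sequence[MetaboliteRecord], component: str
) -> tuple[float, float]:
    """(min, max) retention time over all records of a component class."""
    rts = [r.rt_min for r in records if r.component == component]
    if not rts:
        raise ValueError(f"no records of class {component!r}")
    return (min(rts), max(rts))


@dataclass(frozen=True)
class ConsistencyFinding:
    """Audit result for one printed per-system observation."""

    metabolite_id: str
    system: str
    printed_error_mda: float
    recomputed_error_mda: float
    grade: str  # "pass" | "warn" | "fail"


def validate_fixture(
    records: Iterable[MetaboliteRecord],
    pass_tol_mda: float = 0.05,
    warn_tol_mda: float = 0.3,
) -> list[ConsistencyFinding]:
    """Recompute every printed mass error from formula + adduct + observed
    m/z and grade the discrepancy.

    pass: |printed - recomputed| <= 0.05 mDa; warn: <= 0.3 mDa; fail
    otherwise (the printed row is internally inconsistent — a formula or
    observed-m/z typo). Findings are reported, never raised.
    """
    findings = []
    for record in records:
        theo = ion_mz(record.formula, record.adduct.label)
        for system in ("in_vivo", "in_vitro"):
            obs = record.observation(system)
            if obs is None:
                continue
            recomputed = mass_error_mda(obs.mz, theo)
            gap = abs(obs.error_mda - recomputed)
            grade = "pass" if gap <= pass_tol_mda else "warn" if gap <= warn_tol_mda else "fail"
            findings.append(
                ConsistencyFinding(
                    metabolite_id=record.metabolite_id,
                    system=system,
                    printed_error_mda=obs.error_mda,
                    recomputed_error_mda=reported_mda(recomputed, 2),
                    grade=grade,
                )
            )
    return findings
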