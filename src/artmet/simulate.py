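"""Ground-truthed synthetic MS^E datasets for end-to-end pipeline testing.

No raw spectra were ever deposited for the study this package models, so
the generator emulates the *structure* of the acquisition instead: for each
true metabolite it emits a low-energy precursor peak at the theoretical
adduct m/z plus Gaussian error (sigma in mDa), and high-energy fragment
peaks on the protonated neutral-loss ladder; it adds Poisson-count decoy
peaks uniform over the scan range, and matrix peaks shared verbatim with a
paired blank so that blank subtraction has real work to do. Decoys and
matrix peaks are kept a configurable minimum distance from every candidate
ion so that they are genuine negatives rather than accidental colliders.

The default panel mirrors the published study conditions: 39 metabolites
with the published classes, adducts, retention times and per-system
membership (23 in vivo, 32 in vitro, 16 common).

All randomness flows from the single seed in the spec; the same spec is
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .biotransform import (
    ARTEMISININ,
    BiotransformationRule,
    LabelScheme,
    default_rule_set,
    enumerate_candidates,
)
from .chem import Formula, apply_formula_delta, ion_mz, parse_formula
from .fragments import default_loss_registry
from .peaks import DEFAULT_SCAN_RANGE, Peak, PeakTable

__all__ = [
    "TrueMetabolite",
    "SyntheticSpec",
    "SyntheticDataset",
    "default_panel",
    "simulate_dataset",
    "evaluate_recovery",
    "RecoveryReport",
    "CLASS_PATHS",
]

#: Component class -> biotransformation path multiset (rule labels).
CLASS_PATHS: dict[str, tuple[str, ...]] = {
    "ART": (),
    "ART + O": ("+O",),
    "ART + O2": ("+O", "+O"),
    "de-ART": ("-O",),
    "de-ART + O": ("+O", "-O"),
    "DHA": ("+H2",),
    "DHA + O": ("+H2", "+O"),
    "DHA-O": ("+H2", "-O"),
    "DHA-O + O": ("+H2", "+O", "-O"),
}

#: Default fragment loss paths injected per true metabolite.
_DEFAULT_FRAGMENT_PATHS: tuple[tuple[str, ...], ...] = (
    ("H2O",),
    ("H2O", "H2O"),
    ("HCOOH",),
    ("H2O", "CH3COOH"),
)


@dataclass(frozen=True)
class TrueMetabolite:
    """One planted metabolite: a biotransformation path plus acquisition
    coordinates."""

    metabolite_id: str
    path: tuple[str, ...]  # rule labels, multiset
    adduct: str
    rt_min: float
    systems: tuple[str, ...]  # subset of ("in_vivo", "in_vitro")
    fragment_paths: tuple[tuple[str, ...], ...] = _DEFAULT_FRAGMENT_PATHS

    def formula(
        self, parent: Formula, rules: Sequence[BiotransformationRule]
    ) -> Formula:
        by_label = {r.label: r for r in rules}
        f = parent
        for label in self.path:
            if label not in by_label:
                raise ValueError(
                    f"{self.metabolite_id}: rule {label!r} not in the rule set"
                )
            f = apply_formula_delta(f, by_label[label].delta_map)
        return f

    def label(self, scheme: LabelScheme | None = None) -> str:
        from collections import Counter

        return (scheme or LabelScheme()).label(Counter(self.path))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    parent: str = "C15H22O5"
    metabolites: tuple[TrueMetabolite, ...] = ()
    sigma_mda: float = 0.5  # Gaussian m/z error on every signal peak
    decoy_rate: float = 20.0  # expected Poisson decoy count per sample
    rt_jitter_min: float = 0.02
    seed: int = 0
    scan_range: tuple[float, float] = DEFAULT_SCAN_RANGE
    n_matrix_peaks: int = 30  # shared sample/blank background peaks
    decoy_min_separation_mda: float = 5.0

    def __post_init__(self) -> None:
        if self.sigma_mda < 0 or self.decoy_rate < 0 or self.rt_jitter_min < 0:
            raise ValueError("sigma, decoy rate and rt jitter must be >= 0")


@dataclass(frozen=True)
class SyntheticDataset:
    samples: dict[str, PeakTable]  # system -> sample table
    blanks: dict[str, PeakTable]  # system -> paired blank
    truth: pd.DataFrame  # one row per (metabolite, system)
    spec: SyntheticSpec


def default_panel() -> tuple[TrueMetabolite, ...]:
    """The 39-metabolite panel with the published composition: classes,
    adducts, retention times and per-system membership from the packaged
    reference table (Venn 23/32/16 by construction)."""
    from .compare import load_reference_table

    panel = []
    for record in load_reference_table():
        systems = tuple(
            s for s in ("in_vivo", "in_vitro") if record.observation(s) is not None
        )
        panel.append(
            TrueMetabolite(
                metabolite_id=record.metabolite_id,
                path=CLASS_PATHS[record.component],
                adduct=record.adduct.label,
                rt_min=record.rt_min,
                systems=systems,
            )
        )
    return tuple(panel)


def _uniform_away_from(
    rng: np.random.Generator,
    low: float,
    high: float,
    forbidden: np.ndarray,
    min_separation: float,
) -> float:
    """Uniform draw on [low, high] at least ``min_separation`` from every
    forbidden value (rejection sampling)."""
    for _ in range(1000):
        x = rng.uniform(low, high)
        if forbidden.size == 0 or np.min(np.abs(forbidden - x)) > min_separation:
            return x
    raise RuntimeError("could not place a peak away from the candidate ladder")


def simulate_dataset(
    spec: SyntheticSpec,
    rules: Sequence[BiotransformationRule] | None = None,
    losses: Mapping | None = None,
) -> SyntheticDataset:
    """Generate paired sample/blank peak tables per system plus a truth table.

    With ``sigma_mda=0`` every precursor sits exactly at its theoretical
    adduct m/z; with ``decoy_rate=0`` the sample contains only signal and
    matrix peaks. Identical specs (same seed) produce identical output.
    """
    rules = tuple(rules) if rules is not None else default_rule_set()
    registry = default_loss_registry() if losses is None else dict(losses)
    parent = parse_formula(spec.parent)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.scan_range

    # Forbidden zone for decoys/matrix: every candidate adduct m/z.
    candidates = enumerate_candidates(parent, rules, max_steps=5)
    ladder = np.array(
        sorted(
            ion_mz(c.formula, a) for c in candidates for a in ("M+H", "M+Na", "M+K")
        )
    )
    separation = spec.decoy_min_separation_mda / 1000.0

    # Matrix background shared between each sample and its paired blank.
    matrix = [
        Peak(
            mz=_uniform_away_from(rng, lo, hi, ladder, separation),
            rt_min=float(rng.uniform(0.5, 15.0)),
            intensity=float(10 ** rng.uniform(3, 5)),
            energy="low",
        )
        for _ in range(spec.n_matrix_peaks)
    ]

    sigma_da = spec.sigma_mda / 1000.0
    samples: dict[str, PeakTable] = {}
    blanks: dict[str, PeakTable] = {}
    truth_rows = []
    for system in ("in_vivo", "in_vitro"):
        peaks: list[Peak] = list(matrix)
        for met in spec.metabolites:
            formula = met.formula(parent, rules)
            theo = ion_mz(formula, met.adduct)
            proton_theo = ion_mz(formula, "M+H")
            in_system = system in met.systems
            rt = float(met.rt_min + rng.normal(0, spec.rt_jitter_min)) if spec.rt_jitter_min else met.rt_min
            if in_system:
                peaks.append(
                    Peak(
                        mz=float(theo + rng.normal(0, sigma_da)) if sigma_da else theo,
                        rt_min=max(rt, 0.0),
                        intensity=float(10 ** rng.uniform(4, 6)),
                        energy="low",
                    )
                )
                for path in met.fragment_paths:
                    frag_theo = proton_theo - sum(registry[l].mass for l in path)
                    if not lo <= frag_theo <= hi:
                        continue
                    peaks.append(
                        Peak(
                            mz=float(frag_theo + rng.normal(0, sigma_da))
                            if sigma_da
                            else frag_theo,
                            rt_min=max(rt, 0.0),
                            intensity=float(10 ** rng.uniform(2, 5)),
                            energy="high",
                        )
                    )
            truth_rows.append(
                {
                    "metabolite_id": met.metabolite_id,
                    "system": system,
                    "present": in_system,
                    "component": met.label(),
                    "formula": str(formula),
                    "adduct": met.adduct,
                    "rt_min": met.rt_min,
                    "theoretical_mz": theo,
                    "n_fragments": len(met.fragment_paths),
                }
            )
        n_decoys = int(rng.poisson(spec.decoy_rate))
        for _ in range(n_decoys):
            peaks.append(
                Peak(
                    mz=_uniform_away_from(rng, lo, hi, ladder, separation),
                    rt_min=float(rng.uniform(0.5, 15.0)),
                    intensity=float(10 ** rng.uniform(2, 4)),
                    energy=str(rng.choice(["low", "high"])),
                )
            )
        samples[system] = PeakTable(f"sample_{system}", system, tuple(peaks))
        blanks[system] = PeakTable(f"blank_{system}", "blank", tuple(matrix))

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "metabolite_id",
            "system",
            "present",
            "component",
            "formula",
            "adduct",
            "rt_min",
            "theoretical_mz",
            "n_fragments",
        ],
    )
    return SyntheticDataset(samples=samples, blanks=blanks, truth=truth, spec=spec)


@dataclass(frozen=True)
class RecoveryReport:
    """Per-stage recall/precision of the pipeline against a truth table."""

    recall: dict[str, float]
    precision: dict[str, float]
    n_true: int

    def stage(self, name: str) -> tuple[float, float]:
        return (self.recall[name], self.precision[name])


def evaluate_recovery(
    truth: pd.DataFrame,
    subtracted: Mapping[str, PeakTable],
    annotated: Mapping[str, Sequence],
    precursor_tol_mda: float = 2.0,
    rt_tol_min: float = 0.1,
    min_coverage: float = 0.5,
) -> RecoveryReport:
    """Score pipeline output against the generator's truth table.

    A true metabolite counts as recovered at the matching stage when some
    reported match in its system lies within the retention-time window and
    carries the true component class among its within-tolerance assignments
    (best or alternative — isomeric classes are indistinguishable by mass
    alone, so containment is the correct notion of recovery). Stages:

    * ``blank_subtraction`` — the precursor peak survived subtraction;
    * ``precursor_match`` — a reported match recovers the metabolite;
    * ``fragment_confirmation`` — additionally, fragment coverage >= the
      confirmation threshold.
    """
    present = truth[truth["present"].astype(bool)]
    stages = ("blank_subtraction", "precursor_match", "fragment_confirmation")
    recovered = {s: 0 for s in stages}
    tol_da = precursor_tol_mda / 1000.0

    # Greedy truth -> report assignment: each truth metabolite claims its
    # nearest-Rt unclaimed report whose assignment set contains the true
    # class, so two same-class metabolites eluting 0.1 min apart claim
    # distinct reports.
    claimed: set[tuple[str, int]] = set()
    matched_reports: dict[str, set[tuple[str, int]]] = {s: set() for s in stages[1:]}
    for row in present.itertuples(index=False):
        table = subtracted[row.system]
        if any(
            p.energy == "low"
            and abs(p.mz - row.theoretical_mz) <= tol_da
            and abs(p.rt_min - row.rt_min) <= rt_tol_min
            for p in table.peaks
        ):
            recovered["blank_subtraction"] += 1
        eligible = [
            (abs(ann.match.peak.rt_min - row.rt_min), idx, ann)
            for idx, ann in enumerate(annotated[row.system])
            if (row.system, idx) not in claimed
            and abs(ann.match.peak.rt_min - row.rt_min) <= rt_tol_min
            and row.component in ann.match.labels
        ]
        if not eligible:
            continue
        _, idx, ann = min(eligible, key=lambda t: (t[0], t[1]))
        claimed.add((row.system, idx))
        recovered["precursor_match"] += 1
        matched_reports["precursor_match"].add((row.system, idx))
        if ann.coverage is not None and ann.coverage >= min_coverage:
            recovered["fragment_confirmation"] += 1
            matched_reports["fragment_confirmation"].add((row.system, idx))

    n_true = len(present)
    recall = {s: (recovered[s] / n_true if n_true else 1.0) for s in stages}

    precision = {}
    # Blank-subtraction precision: surviving low-energy peaks that belong to
    # a true metabolite.
    survived = true_survivors = 0
    for system, table in subtracted.items():
        rows = present[present["system"] == system]
        for p in table.channel("low"):
            survived += 1
            if any(
                abs(p.mz - r.theoretical_mz) <= tol_da
                and abs(p.rt_min - r.rt_min) <= rt_tol_min
                for r in rows.itertuples(index=False)
            ):
                true_survivors += 1
    precision["blank_subtraction"] = true_survivors / survived if survived else 1.0
    for stage in stages[1:]:
        reported = sum(len(v) for v in annotated.values())
        if stage == "fragment_confirmation":
            reported = sum(
                1
                for v in annotated.values()
                for a in v
                if a.coverage is not None and a.coverage >= min_coverage
            )
        hits = len(matched_reports[stage])
        precision[stage] = hits / reported if reported else 1.0
    return RecoveryReport(recall=recall, precision=precision, n_true=n_true)
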