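"""End-to-end identification pipeline and cross-system joining.

Stages, in order: blank subtraction -> precursor matching against the
enumerated candidate ladder -> neutral-loss fragment annotation in the
precursor's retention-time window -> cross-system comparison. Two
metabolite identifications from different systems are considered the same
metabolite when they share a component class and elute within the
retention-time tolerance (default 0.1 min).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .biotransform import default_rule_set, enumerate_candidates, rules_from_config
from .fragments import (
    AnnotatedMetabolite,
    annotate_spectrum,
    default_loss_registry,
    losses_from_config,
)
from .io import RunConfig
from .peaks import PeakTable, match_precursors, subtract_blank

__all__ = ["Identification", "PipelineResult", "run_pipeline", "compare_identifications"]


@dataclass(frozen=True)
class Identification:
    """One identified metabolite in one system."""

    system: str
    component: str
    adduct: str
    rt_min: float
    observed_mz: float
    error_mda: float
    coverage: float | None
    alternatives: tuple[str, ...]


@dataclass(frozen=True)
class PipelineResult:
    subtracted: dict[str, PeakTable]
    annotated: dict[str, tuple[AnnotatedMetabolite, ...]]
    identifications: tuple[Identification, ...]
    venn: tuple[int, int, int]  # (in vivo, in vitro, common)
    common: tuple[tuple[str, float], ...]  # (component, in-vivo rt) pairs


def run_pipeline(
    config: RunConfig,
    samples: Mapping[str, PeakTable],
    blanks: Mapping[str, PeakTable],
) -> PipelineResult:
    """Run every stage on per-system sample/blank pairs.

    ``samples`` maps a system tag (``in_vivo`` / ``in_vitro``) to its peak
    table; ``blanks`` maps the same tags to the paired drug-free control.
    """
    if not samples:
        raise ValueError("at least one sample is required")
    rules = (
        rules_from_config({"rules": list(config.rules)})
        if config.rules
        else default_rule_set()
    )
    losses = (
        losses_from_config({"losses": list(config.losses)})
        if config.losses
        else default_loss_registry()
    )
    candidates = enumerate_candidates(config.parent, rules, config.max_steps)

    subtracted: dict[str, PeakTable] = {}
    annotated: dict[str, tuple[AnnotatedMetabolite, ...]] = {}
    identifications: list[Identification] = []
    for system, sample in samples.items():
        if system not in blanks:
            raise ValueError(f"no blank provided for system {system!r}")
        clean = subtract_blank(
            sample, blanks[system], config.precursor_tol_mda, config.rt_tol_min
        )
        subtracted[system] = clean
        matches = match_precursors(
            clean, candidates, config.adducts, config.precursor_tol_mda
        )
        high = clean.channel("high")
        anns = []
        for match in matches:
            window = [
                p
                for p in high
                if abs(p.rt_min - match.peak.rt_min) <= config.rt_tol_min
            ]
            ann = annotate_spectrum(
                match,
                window,
                losses,
                max_fragments=config.fragment_cap,
                max_depth=config.max_loss_depth,
                allow_h2=config.allow_h2,
                tol_da=config.fragment_tol_da,
            )
            anns.append(ann)
            identifications.append(
                Identification(
                    system=system,
                    component=match.candidate.label,
                    adduct=match.adduct,
                    rt_min=match.peak.rt_min,
                    observed_mz=match.peak.mz,
                    error_mda=match.error_mda,
                    coverage=ann.coverage,
                    alternatives=match.labels,
                )
            )
        annotated[system] = tuple(anns)

    venn, common = compare_identifications(identifications, config.rt_tol_min)
    return PipelineResult(
        subtracted=subtracted,
        annotated=annotated,
        identifications=tuple(identifications),
        venn=venn,
        common=common,
    )


def compare_identifications(
    identifications: Sequence[Identification], rt_tol_min: float = 0.1
) -> tuple[tuple[int, int, int], tuple[tuple[str, float], ...]]:
    """Venn counts across systems: identifications sharing a component class
    within the retention-time tolerance are the same metabolite.

    Pairing is greedy nearest-Rt within each class, each identification
    used at most once, so the common count never exceeds either side.
    """
    vivo = sorted(
        (i for i in identifications if i.system == "in_vivo"),
        key=lambda i: (i.component, i.rt_min),
    )
    vitro = [i for i in identifications if i.system == "in_vitro"]
    used: set[int] = set()
    common: list[tuple[str, float]] = []
    for ident in vivo:
        best_idx, best_gap = None, None
        for j, other in enumerate(vitro):
            if j in used or other.component != ident.component:
                continue
            gap = abs(other.rt_min - ident.rt_min)
            if gap <= rt_tol_min and (best_gap is None or gap < best_gap):
                best_idx, best_gap = j, gap
        if best_idx is not None:
            used.add(best_idx)
            common.append((ident.component, ident.rt_min))
    return (len(vivo), len(vitro), len(common)), tuple(common)
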