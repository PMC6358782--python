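"""Peak tables, blank subtraction, and accurate-mass precursor matching.

The pipeline starts from centroided peak lists (m/z, retention time,
intensity, MS^E energy channel). Drug-derived signals are isolated by
removing every sample peak that has a counterpart in the paired blank
within an m/z and a retention-time window; surviving low-energy peaks are
then matched to the theoretical adduct m/z of enumerated candidate
metabolites within a mDa tolerance.

A peak yields at most one *reported* match. Because isomeric candidate
classes can be strictly indistinguishable by mass (DHA and DHA-O + O share
one formula), all within-tolerance alternatives are retained on the match
as a diagnostics field. Ties are broken deterministically: smallest
|error| at 0.1 mDa granularity, then fewest transformations in the path,
then lexicographic class label, then adduct order H < Na < K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .biotransform import CandidateMetabolite
from .chem import ADDUCTS, Adduct, ion_mz, mass_error_mda, reported_mda

__all__ = [
    "Peak",
    "PeakTable",
    "PrecursorMatch",
    "MatchAlternative",
    "subtract_blank",
    "match_precursors",
    "SYSTEMS",
]

SYSTEMS = ("in_vivo", "in_vitro", "blank", "other")
ENERGY_CHANNELS = ("low", "high")

#: Default acquisition scan range (m/z).
DEFAULT_SCAN_RANGE = (50.0, 1000.0)


@dataclass(frozen=True)
class Peak:
    mz: float
    rt_min: float
    intensity: float
    energy: str = "low"

    def __post_init__(self) -> None:
        if self.energy not in ENERGY_CHANNELS:
            raise ValueError(f"energy must be one of {ENERGY_CHANNELS}")
        if self.rt_min < 0 or self.intensity < 0:
            raise ValueError("retention time and intensity must be >= 0")


@dataclass(frozen=True)
class PeakTable:
    """One sample's centroided peaks, canonically sorted by (rt, m/z)."""

    sample_id: str
    system: str
    peaks: tuple[Peak, ...] = ()

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise ValueError(f"system must be one of {SYSTEMS}")
        object.__setattr__(
            self,
            "peaks",
            tuple(sorted(self.peaks, key=lambda p: (p.rt_min, p.mz, p.energy))),
        )

    def channel(self, energy: str) -> tuple[Peak, ...]:
        return tuple(p for p in self.peaks if p.energy == energy)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class MatchAlternative:
    candidate: CandidateMetabolite
    adduct: str
    theoretical_mz: float
    error_mda: float


@dataclass(frozen=True)
class PrecursorMatch:
    """Best (candidate, adduct) assignment for one low-energy peak.

    ``alternatives`` lists every within-tolerance assignment, best first —
    the diagnostics field for mass-degenerate candidate classes.
    """

    peak: Peak
    candidate: CandidateMetabolite
    adduct: str
    theoretical_mz: float
    error_mda: float
    alternatives: tuple[MatchAlternative, ...] = ()

    @property
    def reported_error_mda(self) -> float:
        return reported_mda(self.error_mda)

    @property
    def labels(self) -> tuple[str, ...]:
        """Class labels of the best match and every alternative."""
        return tuple(dict.fromkeys(a.candidate.label for a in self.alternatives))


def subtract_blank(
    sample: PeakTable,
    blank: PeakTable,
    mz_tol_mda: float = 2.0,
    rt_tol_min: float = 0.1,
) -> PeakTable:
    """Remove sample peaks with a blank counterpart within both tolerances.

    Idempotent; a peak the blank lacks is never removed. Sample and blank
    must come from the same ionization mode (here: the same energy-channel
    vocabulary); blanks of a different system tag than ``blank``/``other``
    are rejected to catch sample/blank argument swaps.
    """
    if blank.system not in ("blank", "other"):
        raise ValueError(
            f"blank table has system tag {blank.system!r}; expected 'blank'"
        )
    tol_da = mz_tol_mda / 1000.0
    blank_peaks = blank.peaks
    kept = []
    for peak in sample.peaks:
        matched = any(
            abs(peak.mz - b.mz) <= tol_da
            and abs(peak.rt_min - b.rt_min) <= rt_tol_min
            and peak.energy == b.energy
            for b in blank_peaks
        )
        if not matched:
            kept.append(peak)
    return replace(sample, peaks=tuple(kept))


def _tie_key(alt: MatchAlternative) -> tuple:
    adduct_order = list(ADDUCTS)
    return (
        reported_mda(abs(alt.error_mda)),
        alt.candidate.n_steps,
        alt.candidate.label,
        adduct_order.index(alt.adduct) if alt.adduct in adduct_order else len(adduct_order),
    )


def match_precursors(
    peaks: PeakTable | Iterable[Peak],
    candidates: Sequence[CandidateMetabolite],
    adducts: Iterable[str | Adduct] = ("M+H", "M+Na", "M+K"),
    tol_mda: float = 2.0,
) -> list[PrecursorMatch]:
    """Match low-energy peaks to candidate adduct ions within ``tol_mda``.

    Each matched peak contributes one :class:`PrecursorMatch` carrying the
    tie-break winner plus all within-tolerance alternatives; unmatched peaks
    are absent from the output.
    """
    if tol_mda <= 0:
        raise ValueError("tolerance must be positive")
    peak_seq = peaks.channel("low") if isinstance(peaks, PeakTable) else tuple(peaks)
    adduct_labels = [a.label if isinstance(a, Adduct) else str(a) for a in adducts]
    # Precompute the theoretical ion ladder once per candidate set.
    ladder = [
        (cand, label, ion_mz(cand.formula, label))
        for cand in candidates
        for label in adduct_labels
    ]
    matches: list[PrecursorMatch] = []
    for peak in peak_seq:
        if peak.energy != "low":
            continue
        hits = [
            MatchAlternative(cand, label, theo, mass_error_mda(peak.mz, theo))
            for cand, label, theo in ladder
            if abs(mass_error_mda(peak.mz, theo)) <= tol_mda
        ]
        if not hits:
            continue
        hits.sort(key=_tie_key)
        best = hits[0]
        matches.append(
            PrecursorMatch(
                peak=peak,
                candidate=best.candidate,
                adduct=best.adduct,
                theoretical_mz=best.theoretical_mz,
                error_mda=best.error_mda,
                alternatives=tuple(hits),
            )
        )
    return matches
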