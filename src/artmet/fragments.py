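"""Neutral-loss explanation of high-energy (MS^E) fragment ions.

A fragment is explained when the mass difference between the theoretical
protonated precursor and the observed fragment equals the summed mass of a
small multiset of neutral losses (H2O, HCOOH, CH3COOH, CO, C2H4 by
default), optionally adjusted by a single +-H2 (hydrogen-pair
rearrangement). Fragment series continue from the [M+H]+ value even when
the precursor was detected as a sodium or potassium adduct: the heavier
adducts behave as adduct clusters rather than as fragmenting species, so
the protonated ladder is the reference.

The search is over loss *multisets* (cumulative mass is the only testable
quantity; narrated loss orders are not), preferring minimal cardinality,
then no hydrogen adjustment over +H2 over -H2, then the lexicographically
smallest label sequence. ``explain_fragment`` runs an iterative-deepening
depth-first search with mass pruning; ``explain_fragment_oracle`` is a
separate brute-force enumeration used to cross-check it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

from .chem import Formula, formula_mass, ion_mz, parse_formula
from .peaks import Peak, PrecursorMatch

__all__ = [
    "NeutralLoss",
    "FragmentAssignment",
    "AnnotatedMetabolite",
    "default_loss_registry",
    "losses_from_config",
    "explain_fragment",
    "explain_fragment_oracle",
    "annotate_spectrum",
    "H2_MASS",
]

H2_MASS = 2 * 1.007825  # Da, the +-H2 rearrangement step

#: Hydrogen adjustments in preference order: none, +H2, -H2.
_H2_CHOICES = ((0, 0.0), (+1, H2_MASS), (-1, -H2_MASS))


@dataclass(frozen=True)
class NeutralLoss:
    label: str
    formula: Formula
    mass: float

    @classmethod
    def from_formula(cls, label: str, formula: str | Formula) -> "NeutralLoss":
        f = parse_formula(formula) if isinstance(formula, str) else formula
        return cls(label, f, formula_mass(f))


def default_loss_registry() -> dict[str, NeutralLoss]:
    """Losses observed in artemisinin-family CID spectra: water, formic
    acid, acetic acid, carbon monoxide, ethylene (the CHCH3 loss)."""
    losses = [
        NeutralLoss.from_formula("H2O", "H2O"),
        NeutralLoss.from_formula("HCOOH", "CH2O2"),
        NeutralLoss.from_formula("CH3COOH", "C2H4O2"),
        NeutralLoss.from_formula("CO", "CO"),
        NeutralLoss.from_formula("C2H4", "C2H4"),
    ]
    return {l.label: l for l in losses}


def losses_from_config(config: Mapping) -> dict[str, NeutralLoss]:
    """Build a loss registry from config entries ``{label, formula}``."""
    losses = [
        NeutralLoss.from_formula(str(e["label"]), str(e["formula"]))
        for e in config["losses"]
    ]
    return {l.label: l for l in losses}


@dataclass(frozen=True)
class FragmentAssignment:
    """One explained fragment: observed m/z, loss multiset, +-H2 flag."""

    observed_mz: float
    losses: tuple[str, ...]  # lexicographically sorted loss labels
    h2: int  # -1, 0, +1
    theoretical_mz: float
    error_da: float


@dataclass(frozen=True)
class AnnotatedMetabolite:
    """A precursor match plus its fragment annotations and coverage.

    ``coverage`` is explained / considered over the top-N most intense
    fragments; ``None`` when no fragments were available (not evaluable,
    distinct from coverage 0).
    """

    match: PrecursorMatch
    assignments: tuple[FragmentAssignment, ...]
    considered: int
    coverage: float | None


def _sorted_losses(registry: Mapping[str, NeutralLoss]) -> list[NeutralLoss]:
    return sorted(registry.values(), key=lambda l: l.label)


def explain_fragment(
    precursor_mz: float,
    fragment_mz: float,
    losses: Mapping[str, NeutralLoss] | None = None,
    max_depth: int = 4,
    allow_h2: bool = True,
    tol: float = 0.5,
) -> FragmentAssignment | None:
    """Find a minimal loss multiset explaining ``fragment_mz``.

    Returns ``None`` when no loss path within ``max_depth`` (and at most one
    +-H2 adjustment when ``allow_h2``) matches the precursor-fragment mass
    difference within ``tol`` Da. Absence of an explanation is a valid
    result, not an error.
    """
    registry = default_loss_registry() if losses is None else losses
    loss_list = _sorted_losses(registry)
    h2_choices = _H2_CHOICES if allow_h2 else _H2_CHOICES[:1]
    target = precursor_mz - fragment_mz
    min_loss = min((l.mass for l in loss_list), default=0.0)

    # Iterative deepening: the first depth with a solution is minimal.
    for depth in range(max_depth + 1):
        for h2, h2_mass in h2_choices:
            # Need sum(losses) = target + h2_mass within tol.
            residual = target + h2_mass
            path = _dfs(loss_list, 0, depth, residual, tol, min_loss)
            if path is not None:
                loss_sum = sum(registry[l].mass for l in path)
                theo = precursor_mz - loss_sum + h2_mass
                return FragmentAssignment(
                    observed_mz=fragment_mz,
                    losses=tuple(path),
                    h2=h2,
                    theoretical_mz=theo,
                    error_da=fragment_mz - theo,
                )
    return None


def _dfs(
    loss_list: Sequence[NeutralLoss],
    start: int,
    remaining: int,
    residual: float,
    tol: float,
    min_loss: float,
) -> list[str] | None:
    """Find exactly ``remaining`` losses (labels non-decreasing, i.e. a
    multiset in lexicographic order) summing to ``residual`` within ``tol``."""
    if remaining == 0:
        return [] if abs(residual) <= tol else None
    # Prune: residual must still be reachable by `remaining` positive losses.
    if residual < remaining * min_loss - tol:
        return None
    for i in range(start, len(loss_list)):
        loss = loss_list[i]
        if loss.mass > residual + tol:
            continue
        rest = _dfs(loss_list, i, remaining - 1, residual - loss.mass, tol, min_loss)
        if rest is not None:
            return [loss.label] + rest
    return None


def explain_fragment_oracle(
    precursor_mz: float,
    fragment_mz: float,
    losses: Mapping[str, NeutralLoss] | None = None,
    max_depth: int = 4,
    allow_h2: bool = True,
    tol: float = 0.5,
) -> set[tuple[tuple[str, ...], int]]:
    """Exhaustively enumerate every valid (loss multiset, h2) explanation.

    Brute force over all combinations-with-replacement up to ``max_depth``;
    the independent cross-check for :func:`explain_fragment`.
    """
    if max_depth > 5:
        raise ValueError("oracle is exhaustive; max_depth must be <= 5")
    registry = default_loss_registry() if losses is None else losses
    labels = sorted(registry)
    h2_choices = (0, 1, -1) if allow_h2 else (0,)
    target = precursor_mz - fragment_mz
    valid: set[tuple[tuple[str, ...], int]] = set()
    for depth in range(max_depth + 1):
        for combo in combinations_with_replacement(labels, depth):
            total = sum(registry[l].mass for l in combo)
            for h2 in h2_choices:
                if abs(target + h2 * H2_MASS - total) <= tol:
                    valid.add((combo, h2))
    return valid


def annotate_spectrum(
    match: PrecursorMatch,
    fragments: Iterable[float | Peak],
    losses: Mapping[str, NeutralLoss] | None = None,
    max_fragments: int = 10,
    max_depth: int = 4,
    allow_h2: bool = True,
    tol_da: float = 0.5,
) -> AnnotatedMetabolite:
    """Annotate the top-N high-energy fragments of a precursor match.

    Fragments may be plain m/z values or :class:`~artmet.peaks.Peak` objects;
    peaks are ranked by intensity before the cap is applied. The loss ladder
    starts from the theoretical *protonated* ion of the matched candidate,
    regardless of the detected adduct.
    """
    if max_fragments < 1:
        raise ValueError("fragment cap must be >= 1")
    items = list(fragments)
    if items and isinstance(items[0], Peak):
        items.sort(key=lambda p: -p.intensity)
        mzs = [p.mz for p in items[:max_fragments]]
    else:
        mzs = [float(x) for x in items[:max_fragments]]
    if not mzs:
        return AnnotatedMetabolite(match, (), 0, None)

    precursor_theo = ion_mz(match.candidate.formula, "M+H")
    assignments = []
    for mz in mzs:
        if mz > precursor_theo + tol_da + H2_MASS:
            continue  # heavier than any reachable fragment (e.g. adduct cluster)
        assignment = explain_fragment(
            precursor_theo, mz, losses, max_depth=max_depth, allow_h2=allow_h2, tol=tol_da
        )
        if assignment is not None:
            assignments.append(assignment)
    assignments.sort(key=lambda a: -a.observed_mz)
    return AnnotatedMetabolite(
        match=match,
        assignments=tuple(assignments),
        considered=len(mzs),
        coverage=len(assignments) / len(mzs),
    )
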