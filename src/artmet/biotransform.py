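"""Rule-based enumeration of candidate phase-I metabolites.

A biotransformation rule is a signed element-count delta (hydroxylation +O,
deoxygenation -O, carbonyl reduction +H2) with a per-path application cap.
Candidates are the closure of rule applications on the parent drug up to a
step limit. Paths are *multisets*: at the formula level the order of rule
application is chemically irrelevant, so {+O then -O} and {-O then +O} are
the same candidate.

Class labels follow the naming convention of the artemisinin metabolism
literature: the parent alias is "ART", reduction (+H2) switches the alias to
"DHA", deoxygenation prefixes "de-" (or suffixes "-O" on the reduced alias),
and hydroxylations append " + O" / " + O2". Two candidates may share a
formula yet carry distinct labels (DHA and DHA-O + O are both C15H24O5);
identity is the path multiset, not the composition.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .chem import Formula, FormulaError, apply_formula_delta, parse_formula

__all__ = [
    "BiotransformationRule",
    "CandidateMetabolite",
    "LabelScheme",
    "default_rule_set",
    "enumerate_candidates",
    "rules_from_config",
    "ARTEMISININ",
]

logger = logging.getLogger(__name__)

#: Parent drug of the reference application: artemisinin.
ARTEMISININ = parse_formula("C15H22O5")


@dataclass(frozen=True)
class BiotransformationRule:
    """One formula-level transformation with a per-path application cap."""

    label: str
    delta: tuple[tuple[str, int], ...]  # signed element-count mapping
    max_applications: int = 1

    def __post_init__(self) -> None:
        if not self.delta:
            raise ValueError(f"rule {self.label!r} has an empty delta")

    @classmethod
    def make(cls, label: str, delta: Mapping[str, int], max_applications: int = 1):
        return cls(label, tuple(sorted(delta.items())), max_applications)

    @property
    def delta_map(self) -> dict[str, int]:
        return dict(self.delta)


@dataclass(frozen=True)
class LabelScheme:
    """How path multisets map to the field's component-class strings."""

    parent_alias: str = "ART"
    reduced_alias: str = "DHA"
    hydroxylation: str = "+O"
    deoxygenation: str = "-O"
    reduction: str = "+H2"

    def label(self, path: Counter) -> str:
        n_oxy = path.get(self.hydroxylation, 0)
        n_deoxy = path.get(self.deoxygenation, 0)
        reduced = path.get(self.reduction, 0) > 0
        base = self.reduced_alias if reduced else self.parent_alias
        if reduced:
            name = base + "-O" * n_deoxy
        else:
            name = "de-" * n_deoxy + base
        if n_oxy == 1:
            name += " + O"
        elif n_oxy > 1:
            name += f" + O{n_oxy}"
        return name


@dataclass(frozen=True)
class CandidateMetabolite:
    """A parent drug plus an (unordered) biotransformation path."""

    parent: Formula
    path: tuple[str, ...]  # sorted rule labels, multiset representation
    formula: Formula
    label: str

    @property
    def n_steps(self) -> int:
        return len(self.path)


def default_rule_set() -> tuple[BiotransformationRule, ...]:
    """The phase-I rules observed for artemisinin: hydroxylation (up to two
    per path), deoxygenation (one), carbonyl reduction to the lactol (one)."""
    return (
        BiotransformationRule.make("+O", {"O": 1}, max_applications=2),
        BiotransformationRule.make("-O", {"O": -1}, max_applications=1),
        BiotransformationRule.make("+H2", {"H": 2}, max_applications=1),
    )


def enumerate_candidates(
    parent: Formula | str,
    rules: Iterable[BiotransformationRule] | None = None,
    max_steps: int = 3,
    scheme: LabelScheme | None = None,
) -> list[CandidateMetabolite]:
    """Breadth-first closure of rule applications on ``parent``.

    Candidates are deduplicated by path multiset and returned in a
    deterministic order (path length, then class label). Branches whose
    delta would drive an element count negative are pruned silently.
    """
    if max_steps < 0:
        raise ValueError("max_steps must be >= 0")
    if isinstance(parent, str):
        parent = parse_formula(parent)
    rule_list = tuple(rules) if rules is not None else default_rule_set()
    labels = {r.label for r in rule_list}
    if len(labels) != len(rule_list):
        raise ValueError("rule labels must be unique within a rule set")
    scheme = scheme or LabelScheme()

    seen: dict[frozenset, CandidateMetabolite] = {}
    root = Counter()
    seen[frozenset(root.items())] = CandidateMetabolite(
        parent, (), parent, scheme.label(root)
    )
    frontier = [(root, parent)]
    for _ in range(max_steps):
        nxt = []
        for path, formula in frontier:
            for rule in rule_list:
                if path.get(rule.label, 0) >= rule.max_applications:
                    continue
                try:
                    derived = apply_formula_delta(formula, rule.delta_map)
                except FormulaError:
                    logger.debug(
                        "pruned infeasible branch %s on %s", rule.label, formula
                    )
                    continue
                new_path = path + Counter({rule.label: 1})
                key = frozenset(new_path.items())
                if key in seen:
                    continue
                seen[key] = CandidateMetabolite(
                    parent,
                    tuple(sorted(new_path.elements())),
                    derived,
                    scheme.label(new_path),
                )
                nxt.append((new_path, derived))
        frontier = nxt
        if not frontier:
            break
    return sorted(seen.values(), key=lambda c: (c.n_steps, c.label))


def rules_from_config(config: Mapping) -> tuple[BiotransformationRule, ...]:
    """Build a rule set from a config mapping, e.g. loaded from YAML::

        rules:
          - {label: "+O", delta: {O: 1}, max_applications: 2}
    """
    rules = []
    for entry in config["rules"]:
        rules.append(
            BiotransformationRule.make(
                str(entry["label"]),
                {str(k): int(v) for k, v in entry["delta"].items()},
                int(entry.get("max_applications", 1)),
            )
        )
    return tuple(rules)
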