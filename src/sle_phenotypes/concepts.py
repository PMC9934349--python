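"""Concept sets: named lists of (vocabulary, code) pairs with a clinical role.

A concept set defines one clinical idea — the SLE diagnosis codes, the
signs/symptoms used for index-date correction, the antimalarial drugs of the
comparator algorithms, and so on.  Matching is exact string match on
``(vocabulary, code)``; no vocabulary hierarchy is expanded, so users must
supply literal code lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: The clinical roles a concept set may play in the algorithms.
ROLES = frozenset(
    {
        "sle_diagnosis",
        "sle_sign_symptom",
        "sle_treatment_drug",
        "antimalarial",
        "exclusion_dx",
        "comorbidity",
        "other",
    }
)

#: Roles whose events may pull the cohort index date earlier than the first
#: diagnosis code (signs/symptoms and SLE treatment drugs participate on
#: equal footing).
PRECURSOR_ROLES = ("sle_sign_symptom", "sle_treatment_drug")


@dataclass(frozen=True)
class ConceptSet:
    """A named set of codes sharing one clinical role.

    ``codes`` holds ``(vocabulary, code, label)`` triples; the
    ``(vocabulary, code)`` pairs are unique within a set.
    """

    name: str
    role: str
    codes: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(
                f"concept set {self.name!r}: unknown role {self.role!r}; "
                f"expected one of {sorted(ROLES)}"
            )
        if not self.codes:
            logger.warning("concept set %r is empty", self.name)

    def pairs(self) -> set[tuple[str, str]]:
        return {(v, c) for v, c, _ in self.codes}


@dataclass
class ConceptRegistry:
    """Registry of concept sets keyed by name, with fast role lookup."""

    sets: dict[str, ConceptSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._rebuild_lookup()

    def _rebuild_lookup(self) -> None:
        lookup: dict[tuple[str, str], set[str]] = {}
        for cs in self.sets.values():
            for pair in cs.pairs():
                lookup.setdefault(pair, set()).add(cs.role)
        self._role_lookup = {k: frozenset(v) for k, v in lookup.items()}

    def add(self, concept_set: ConceptSet) -> None:
        if concept_set.name in self.sets:
            raise ValueError(f"duplicate concept set name {concept_set.name!r}")
        self.sets[concept_set.name] = concept_set
        self._rebuild_lookup()

    def classify(self, vocabulary: str, code: str) -> frozenset[str]:
        """All roles carried by ``(vocabulary, code)``; empty if unknown.

        Pure function of the pair and the registry contents; a single code
        may carry several roles (hydroxychloroquine is both an SLE treatment
        drug and an antimalarial).
        """
        return self._role_lookup.get((str(vocabulary), str(code)), frozenset())

    def codes_for_role(self, role: str) -> list[tuple[str, str]]:
        out: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        for cs in self.sets.values():
            if cs.role != role:
                continue
            for v, c, _ in cs.codes:
                if (v, c) not in seen:
                    seen.add((v, c))
                    out.append((v, c))
        return out

    def role_frame(self) -> pd.DataFrame:
        """Long-format ``(vocabulary, code, role)`` table for vectorised joins."""
        rows = [
            (v, c, role)
            for (v, c), roles in self._role_lookup.items()
            for role in sorted(roles)
        ]
        return pd.DataFrame(rows, columns=["vocabulary", "code", "role"])


def classify_event(event, registry: ConceptRegistry) -> frozenset[str]:
    """Roles of a single clinical event (anything with vocabulary/code)."""
    if isinstance(event, Mapping):
        return registry.classify(event["vocabulary"], event["code"])
    return registry.classify(event.vocabulary, event.code)


def _parse_sets(doc: dict) -> Iterable[ConceptSet]:
    for entry in doc.get("concept_sets", []):
        raw_codes = entry.get("codes", []) or []
        codes: list[tuple[str, str, str]] = []
        seen: set[tuple[str, str]] = set()
        for item in raw_codes:
            v, c = str(item[0]), str(item[1])
            label = str(item[2]) if len(item) > 2 else ""
            if (v, c) in seen:
                logger.warning(
                    "concept set %r: duplicate code (%s, %s) dropped",
                    entry["name"], v, c,
                )
                continue
            seen.add((v, c))
            codes.append((v, c, label))
        yield ConceptSet(name=str(entry["name"]), role=str(entry["role"]),
                         codes=tuple(codes))


def load_concept_sets(config_path: str | Path) -> ConceptRegistry:
    """Load a concept-set registry from a YAML config file.

    The config is a mapping with one key, ``concept_sets``, a list of
    ``{name, role, codes}`` entries where each code is a
    ``[vocabulary, code, label]`` triple.  Duplicate codes within a set are
    dropped with a warning; a duplicate set name or an unknown role is fatal.
    """
    with open(config_path) as fh:
        doc = yaml.safe_load(fh)
    registry = ConceptRegistry()
    for cs in _parse_sets(doc or {}):
        registry.add(cs)
    return registry


def default_registry() -> ConceptRegistry:
    """The shipped default registry (main-text subset of the full code lists)."""
    ref = resources.files("sle_phenotypes.data") / "default_concept_sets.yaml"
    with resources.as_file(ref) as path:
        return load_concept_sets(path)
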