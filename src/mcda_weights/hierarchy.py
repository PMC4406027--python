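"""Criteria taxonomy for MCDA weight elicitation.

A :class:`CriteriaHierarchy` is a fixed two-level tree: categories at the
top, criteria ("leaves") underneath.  The bundled default is the EVIDEM
health-technology-assessment framework with 14 criteria in 6 categories.
Every weight and score vector in this package is keyed by the hierarchy's
canonical leaf order, so a single hierarchy instance is threaded through
all derivation and comparison code to prevent silent misalignment.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["Criterion", "CriteriaHierarchy", "load_hierarchy", "flat_criteria"]

#: Node label for the category-level (top) block of a hierarchy.
TOP_BLOCK = "TOP"


@dataclass(frozen=True)
class Criterion:
    """A single decision criterion (a leaf of the hierarchy)."""

    code: str
    name: str
    category: str
    definition: str = ""


class HierarchyError(ValueError):
    """Raised when a hierarchy definition violates its invariants."""


@dataclass(frozen=True)
class CriteriaHierarchy:
    """Two-level criteria tree: ordered categories, each holding criteria.

    Parameters
    ----------
    criteria
        Leaves in canonical order.  Category order is the order of first
        appearance; all leaves of one category must be contiguous.
    """

    criteria: tuple[Criterion, ...]
    categories: tuple[str, ...] = field(init=False)
    structure: Mapping[str, tuple[Criterion, ...]] = field(init=False)

    def __post_init__(self) -> None:
        if not self.criteria:
            raise HierarchyError("hierarchy has no criteria")
        codes = [c.code for c in self.criteria]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise HierarchyError(f"duplicate criterion codes: {dupes}")
        cats: list[str] = []
        structure: dict[str, list[Criterion]] = {}
        for c in self.criteria:
            if not c.category:
                raise HierarchyError(f"criterion {c.code!r} has an empty category")
            if c.category == TOP_BLOCK:
                raise HierarchyError(f"category name {TOP_BLOCK!r} is reserved")
            if c.category not in structure:
                cats.append(c.category)
                structure[c.category] = []
            elif cats[-1] != c.category:
                raise HierarchyError(
                    f"criteria of category {c.category!r} are not contiguous"
                )
            structure[c.category].append(c)
        object.__setattr__(self, "categories", tuple(cats))
        object.__setattr__(
            self, "structure", {k: tuple(v) for k, v in structure.items()}
        )

    # -- basic accessors -------------------------------------------------

    @property
    def codes(self) -> tuple[str, ...]:
        """Leaf codes in canonical order."""
        return tuple(c.code for c in self.criteria)

    @property
    def n_criteria(self) -> int:
        return len(self.criteria)

    def category_of(self, code: str) -> str:
        return self[code].category

    def category_codes(self, category: str) -> tuple[str, ...]:
        return tuple(c.code for c in self.structure[category])

    def category_sizes(self) -> dict[str, int]:
        return {cat: len(members) for cat, members in self.structure.items()}

    def block_items(self, block: str) -> tuple[str, ...]:
        """Item codes of a judgment block: categories for ``TOP``, else leaves."""
        if block == TOP_BLOCK:
            return self.categories
        if block not in self.structure:
            raise KeyError(f"unknown block {block!r}")
        return self.category_codes(block)

    def __getitem__(self, code: str) -> Criterion:
        for c in self.criteria:
            if c.code == code:
                return c
        raise KeyError(code)

    def __contains__(self, code: str) -> bool:
        return any(c.code == code for c in self.criteria)

    def __len__(self) -> int:
        return len(self.criteria)

    # -- constructors ----------------------------------------------------

    @classmethod
    def default(cls) -> "CriteriaHierarchy":
        """The bundled EVIDEM hierarchy: 14 criteria in 6 categories."""
        ref = importlib.resources.files("mcda_weights.data") / "evidem_criteria.yaml"
        with importlib.resources.as_file(ref) as path:
            return load_hierarchy(path)


def load_hierarchy(path: str | Path) -> CriteriaHierarchy:
    """Read a hierarchy definition from a YAML file.

    The file holds a ``criteria`` list of records with keys ``code``,
    ``name``, ``category`` and optionally ``definition``.  Category order
    is the order of first appearance in the file.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "criteria" not in doc:
        raise HierarchyError(f"{path}: expected a mapping with a 'criteria' list")
    records = doc["criteria"]
    if not isinstance(records, list) or not records:
        raise HierarchyError(f"{path}: 'criteria' must be a non-empty list")
    leaves = []
    for rec in records:
        try:
            leaves.append(
                Criterion(
                    code=str(rec["code"]),
                    name=str(rec["name"]),
                    category=str(rec["category"]),
                    definition=str(rec.get("definition", "")).strip(),
                )
            )
        except KeyError as exc:  # pragma: no cover - message detail only
            raise HierarchyError(f"{path}: record missing key {exc}") from exc
    return CriteriaHierarchy(tuple(leaves))


def flat_criteria(h: CriteriaHierarchy) -> list[Criterion]:
    """Leaves in canonical order (category order, then within-category order).

    Deterministic: repeated calls on the same hierarchy return the same
    list.  This order keys every weight/score vector in the package.
    """
    return list(h.criteria)
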