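"""Trait schema: the typed vocabulary behind species trait tables.

A schema is an ordered list of ten trait definitions. Each trait is either
nominal (unordered categories, e.g. feeding mode) or ordinal (categories with
a strict rank order, e.g. maximum longevity classes). Category vocabularies
are fixed: a trait value outside its vocabulary is a validation error, never
silently coerced.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

__all__ = ["TraitDefinition", "TraitSchema", "default_schema", "SchemaError"]

N_TRAITS = 10


class SchemaError(ValueError):
    """Raised when a schema definition violates its invariants."""


@dataclass(frozen=True)
class TraitDefinition:
    """One trait: a code (A-J), a kind, and an ordered category vocabulary.

    For ordinal traits the listed order *is* the rank order (rank 1..K).
    ``category_labels`` are optional human-readable descriptions, parallel
    to ``categories``; they play no role in any computation.
    """

    code: str
    name: str
    kind: str  # "nominal" | "ordinal"
    categories: tuple[str, ...]
    category_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("nominal", "ordinal"):
            raise SchemaError(f"trait {self.code}: kind must be nominal or ordinal, got {self.kind!r}")
        if not self.categories:
            raise SchemaError(f"trait {self.code}: empty category vocabulary")
        if len(set(self.categories)) != len(self.categories):
            raise SchemaError(f"trait {self.code}: duplicate category labels")
        if self.category_labels is not None and len(self.category_labels) != len(self.categories):
            raise SchemaError(f"trait {self.code}: category_labels length mismatch")

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def rank(self, value: str) -> int:
        """1-based rank of a category (ordinal traits; also defined for nominal)."""
        return self.categories.index(value) + 1


@dataclass(frozen=True)
class TraitSchema:
    """Ordered collection of exactly ten trait definitions."""

    traits: tuple[TraitDefinition, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.traits) != N_TRAITS:
            raise SchemaError(f"schema must define exactly {N_TRAITS} traits, got {len(self.traits)}")
        codes = [t.code for t in self.traits]
        if len(set(codes)) != len(codes):
            raise SchemaError("duplicate trait codes in schema")

    @property
    def codes(self) -> list[str]:
        return [t.code for t in self.traits]

    def __getitem__(self, code: str) -> TraitDefinition:
        for t in self.traits:
            if t.code == code:
                return t
        raise KeyError(code)

    def __iter__(self):
        return iter(self.traits)

    @classmethod
    def from_dict(cls, d: dict) -> "TraitSchema":
        traits = []
        for item in d["traits"]:
            labels = item.get("category_labels")
            traits.append(
                TraitDefinition(
                    code=str(item["code"]),
                    name=str(item["name"]),
                    kind=str(item["kind"]),
                    categories=tuple(str(c) for c in item["categories"]),
                    category_labels=tuple(str(c) for c in labels) if labels else None,
                )
            )
        return cls(traits=tuple(traits))

    @classmethod
    def from_yaml(cls, path) -> "TraitSchema":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "traits": [
                {
                    "code": t.code,
                    "name": t.name,
                    "kind": t.kind,
                    "categories": list(t.categories),
                    **({"category_labels": list(t.category_labels)} if t.category_labels else {}),
                }
                for t in self.traits
            ]
        }


def default_schema() -> TraitSchema:
    """The packaged ten-trait benthic schema (feeding, longevity, coloniality,
    morphology, carbon storage, energetic resource, height, growth rate,
    calcification, motility)."""
    ref = importlib.resources.files("benthovuln.data").joinpath("default_schema.yaml")
    with ref.open(encoding="utf-8") as fh:
        return TraitSchema.from_dict(yaml.safe_load(fh))
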