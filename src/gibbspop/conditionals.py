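"""Conditional probability tables: P(target | conditioning attributes).

A :class:`ConditionalTable` is the unit of the conditional tree: one target variable,
a (possibly empty) tuple of conditioning variables, and per conditioning cell a
probability vector over the target categories together with the support count and the
spatial resolution level at which the cell was estimated ("model" for generative
ground-truth tables).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .schema import AttributeSchema, SchemaError

__all__ = ["Cell", "ConditionalTable", "ConditionalError"]

_PROB_TOL = 1e-9


class ConditionalError(KeyError):
    """A conditioning cell is missing or invalid."""


def _native(v):
    """Numpy scalars to plain Python for JSON round-trips."""
    if isinstance(v, np.generic):
        return v.item()
    return v


@dataclass
class Cell:
    probs: np.ndarray
    support: int = 0
    level: str = "model"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1:
            raise ValueError("probability vector must be 1-D")
        if np.any(self.probs < -_PROB_TOL):
            raise ValueError("negative probability")
        total = float(self.probs.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")


@dataclass
class ConditionalTable:
    """P(target | given) over explicit categories.

    ``cells`` maps a tuple of conditioning values (in ``given`` order) to a
    :class:`Cell`.  An empty ``given`` tuple yields a single cell keyed ``()``
    (a marginal / prior).
    """

    target: str
    given: tuple[str, ...]
    categories: tuple
    cells: dict[tuple, Cell] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.given = tuple(self.given)
        self.categories = tuple(self.categories)
        for key, cell in self.cells.items():
            if len(cell.probs) != len(self.categories):
                raise ValueError(
                    f"cell {key!r} of P({self.target}|{','.join(self.given)}) has "
                    f"{len(cell.probs)} probabilities for {len(self.categories)} categories"
                )

    @property
    def key(self) -> tuple[str, tuple[str, ...]]:
        return (self.target, self.given)

    def cell(self, cond: tuple) -> Cell:
        try:
            return self.cells[tuple(cond)]
        except KeyError:
            raise ConditionalError(
                f"P({self.target}|{','.join(self.given) or '-'}) has no cell for "
                f"conditioning values {tuple(cond)!r}"
            ) from None

    def probs(self, cond: tuple = ()) -> np.ndarray:
        return self.cell(cond).probs

    def sample(self, cond: tuple, rng: np.random.Generator):
        p = self.probs(cond)
        return self.categories[int(rng.choice(len(p), p=p))]

    def marginal(self) -> np.ndarray:
        """Support-weighted (equal-weighted for model tables) average over cells."""
        if not self.cells:
            raise ConditionalError(f"P({self.target}|...) has no cells")
        weights = np.array([max(c.support, 1) for c in self.cells.values()], dtype=float)
        mat = np.stack([c.probs for c in self.cells.values()])
        p = weights @ mat
        return p / p.sum()

    def validate_against(self, schema: AttributeSchema) -> None:
        if self.target not in schema:
            raise SchemaError(f"target {self.target!r} not in schema")
        if tuple(self.categories) != tuple(schema.categories(self.target)):
            raise SchemaError(
                f"categories of {self.target!r} do not match the schema"
            )
        for g in self.given:
            if g not in schema and g != "zone_id":
                raise SchemaError(f"conditioning variable {g!r} not in schema")

    # -- serialization ------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "given": list(self.given),
            "categories": list(self.categories),
            "cells": [
                {
                    "cond": [_native(v) for v in k],
                    "probs": [float(x) for x in c.probs],
                    "support": int(c.support),
                    "level": c.level,
                }
                for k, c in self.cells.items()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionalTable":
        cells = {
            tuple(e["cond"]): Cell(np.array(e["probs"]), e.get("support", 0), e.get("level", "model"))
            for e in d["cells"]
        }
        return cls(d["target"], tuple(d["given"]), tuple(d["categories"]), cells)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConditionalTable":
        return cls.from_dict(json.loads(Path(path).read_text()))


def cpts_to_json(cpts: dict, path: str | Path) -> None:
    """Serialize a mapping {(target, given): ConditionalTable} to one JSON file."""
    Path(path).write_text(
        json.dumps([t.to_dict() for t in cpts.values()], indent=1)
    )


def cpts_from_json(path: str | Path) -> dict:
    tables = [ConditionalTable.from_dict(d) for d in json.loads(Path(path).read_text())]
    return {t.key: t for t in tables}
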