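"""Zone hierarchy: region → department → (canton) → commune → IRIS.

The hierarchy supports the fallback walk used when a conditional cell is too sparse at
the IRIS level: estimation climbs to the parent zone until enough observations pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["ZoneHierarchy", "ZoneNode", "HierarchyError", "ZONE_LEVELS"]

#: ordered coarse → fine
ZONE_LEVELS: tuple[str, ...] = ("region", "department", "canton", "commune", "iris")


class HierarchyError(ValueError):
    """Orphan, cyclic or otherwise malformed zone table."""


@dataclass(frozen=True)
class ZoneNode:
    zone_id: str
    level: str
    parent_id: str | None
    population: int


class ZoneHierarchy:
    """Validated tree of spatial zones."""

    def __init__(self, nodes: dict[str, ZoneNode]):
        self.nodes = nodes
        self._children: dict[str, list[str]] = {z: [] for z in nodes}
        self._validate()

    def _validate(self) -> None:
        roots = []
        for node in self.nodes.values():
            if node.level not in ZONE_LEVELS:
                raise HierarchyError(f"unknown level {node.level!r} for zone {node.zone_id!r}")
            if node.population < 0:
                raise HierarchyError(f"negative population for zone {node.zone_id!r}")
            if node.parent_id is None:
                if node.level != "region":
                    raise HierarchyError(
                        f"zone {node.zone_id!r} at level {node.level!r} has no parent"
                    )
                roots.append(node.zone_id)
            else:
                if node.parent_id not in self.nodes:
                    raise HierarchyError(
                        f"zone {node.zone_id!r} references missing parent {node.parent_id!r}"
                    )
                parent = self.nodes[node.parent_id]
                if ZONE_LEVELS.index(parent.level) >= ZONE_LEVELS.index(node.level):
                    raise HierarchyError(
                        f"zone {node.zone_id!r} ({node.level}) has parent "
                        f"{node.parent_id!r} at level {parent.level}, not coarser"
                    )
                self._children[node.parent_id].append(node.zone_id)
        if not roots:
            raise HierarchyError("no region root found")
        # reachability from roots rules out cycles
        seen: set[str] = set()
        stack = list(roots)
        while stack:
            z = stack.pop()
            if z in seen:
                raise HierarchyError(f"cycle detected at zone {z!r}")
            seen.add(z)
            stack.extend(self._children[z])
        unreachable = set(self.nodes) - seen
        if unreachable:
            raise HierarchyError(f"zones unreachable from any region: {sorted(unreachable)}")

    # -- queries ------------------------------------------------------------------

    def __contains__(self, zone_id: str) -> bool:
        return zone_id in self.nodes

    def level(self, zone_id: str) -> str:
        return self.nodes[zone_id].level

    def parent(self, zone_id: str) -> str | None:
        return self.nodes[zone_id].parent_id

    def population(self, zone_id: str) -> int:
        return self.nodes[zone_id].population

    def ancestors(self, zone_id: str) -> list[str]:
        """Chain fine → coarse starting at ``zone_id`` itself."""
        if zone_id not in self.nodes:
            raise HierarchyError(f"unknown zone {zone_id!r}")
        chain = [zone_id]
        while (p := self.nodes[chain[-1]].parent_id) is not None:
            chain.append(p)
        return chain

    def zones_at(self, level: str) -> list[str]:
        return [z for z, n in self.nodes.items() if n.level == level]

    def iris_ids(self) -> list[str]:
        return self.zones_at("iris")

    def subtree(self, zone_id: str) -> set[str]:
        """All zone ids in the subtree rooted at ``zone_id`` (inclusive)."""
        out, stack = set(), [zone_id]
        while stack:
            z = stack.pop()
            out.add(z)
            stack.extend(self._children[z])
        return out

    def descendants_at(self, zone_id: str, level: str) -> list[str]:
        """All zones at ``level`` in the subtree of ``zone_id`` (inclusive)."""
        out, stack = [], [zone_id]
        while stack:
            z = stack.pop()
            if self.nodes[z].level == level:
                out.append(z)
            stack.extend(self._children[z])
        return sorted(out)

    def commune_of(self, iris_id: str) -> str:
        for z in self.ancestors(iris_id):
            if self.nodes[z].level == "commune":
                return z
        raise HierarchyError(f"IRIS {iris_id!r} has no commune ancestor")

    def depth(self) -> int:
        return max(len(self.ancestors(z)) for z in self.nodes)

    # -- I/O ----------------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "zone_id": n.zone_id,
                    "level": n.level,
                    "parent_id": "" if n.parent_id is None else n.parent_id,
                    "population": n.population,
                }
                for n in self.nodes.values()
            ]
        )

    @classmethod
    def from_frame(cls, table: pd.DataFrame) -> "ZoneHierarchy":
        required = {"zone_id", "level", "parent_id", "population"}
        missing = required - set(table.columns)
        if missing:
            raise HierarchyError(f"zone table is missing columns {sorted(missing)}")
        if table["zone_id"].duplicated().any():
            dups = table.loc[table["zone_id"].duplicated(), "zone_id"].tolist()
            raise HierarchyError(f"duplicate zone ids: {dups}")
        nodes = {}
        for row in table.itertuples(index=False):
            parent = None if (pd.isna(row.parent_id) or row.parent_id == "") else str(row.parent_id)
            nodes[str(row.zone_id)] = ZoneNode(
                str(row.zone_id), str(row.level), parent, int(row.population)
            )
        return cls(nodes)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t") -> "ZoneHierarchy":
        return cls.from_frame(pd.read_csv(path, sep=sep, dtype={"zone_id": str, "parent_id": str}, keep_default_na=False))
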