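"""Airway tree topology: branches, generation numbering, lobe assignment.

A bronchial tree is a rooted branch graph. Generations count branch depth
from the trachea: trachea G1, main stem bronchi G2, lobar bronchi G3,
segmental G4, and subsegmental bronchi G5 onward. Lobe membership is
inherited: once the six lobar entry branches are labelled (RUL, RML, RLL,
LUL, LLi, LLL), every descendant carries its lobar ancestor's label, while
the trachea and main bronchi stay non-lobar.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

#: Labels of the central (non-lobar) airways.
CENTRAL_LABELS = ("trachea", "right-main", "left-main")


class TreeStructureError(ValueError):
    """Cyclic graph, multiple roots, or disconnected branches."""


@dataclass
class Branch:
    """One airway branch with its centerline and (optional) measured geometry."""

    id: int
    parent_id: int | None
    centerline: np.ndarray                 # (n, 3) points in mm, start→end
    generation: int | None = None
    lobe: str | None = None                # lobe name, a central label, or None
    lumen_diameter: float | None = None    # ground-truth lumen diameter (mm)
    wall_thickness: float | None = None    # ground-truth wall thickness (mm)
    geometry: dict = field(default_factory=dict)   # measured TD/WT/LA/WP medians
    sections: list = field(default_factory=list)   # CrossSectionMeasure list
    excluded_reason: str | None = None

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if self.centerline.shape[1] != 3 or self.centerline.shape[0] < 2:
            raise ValueError("centerline must be an (n>=2, 3) array of mm points")

    @property
    def length_mm(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)))

    @property
    def measured_lumen_diameter(self) -> float | None:
        la = self.geometry.get("LA")
        return None if la is None else 2.0 * float(np.sqrt(la / np.pi))


class AirwayTreeModel:
    """Rooted airway branch graph with per-branch centerlines and labels."""

    def __init__(self, branches: Iterable[Branch]):
        self.branches: dict[int, Branch] = {}
        for b in branches:
            if b.id in self.branches:
                raise TreeStructureError(f"duplicate branch id {b.id}")
            self.branches[b.id] = b
        self._validate_topology()

    def _validate_topology(self) -> None:
        roots = [b.id for b in self.branches.values() if b.parent_id is None]
        if len(roots) != 1:
            raise TreeStructureError(f"expected exactly one root branch, found {len(roots)}")
        self.root_id = roots[0]
        for b in self.branches.values():
            if b.parent_id is not None and b.parent_id not in self.branches:
                raise TreeStructureError(f"branch {b.id} references missing parent {b.parent_id}")
        # reachability from the root detects cycles/disconnection
        seen = set()
        queue = deque([self.root_id])
        while queue:
            bid = queue.popleft()
            if bid in seen:
                raise TreeStructureError("cycle detected in branch graph")
            seen.add(bid)
            queue.extend(self.children(bid))
        if seen != set(self.branches):
            raise TreeStructureError("branch graph contains branches unreachable from the root")

    def children(self, branch_id: int) -> list[int]:
        return sorted(b.id for b in self.branches.values() if b.parent_id == branch_id)

    def __iter__(self):
        return iter(self.branches.values())

    def __len__(self) -> int:
        return len(self.branches)

    def parent_child_pairs(self) -> list[tuple[Branch, Branch]]:
        return [
            (self.branches[b.parent_id], b)
            for b in self.branches.values()
            if b.parent_id is not None
        ]

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = []
        for b in self.branches.values():
            payload.append(
                {
                    "id": b.id,
                    "parent_id": b.parent_id,
                    "centerline_mm": np.asarray(b.centerline).tolist(),
                    "generation": b.generation,
                    "lobe": b.lobe,
                    "lumen_diameter_mm": b.lumen_diameter,
                    "wall_thickness_mm": b.wall_thickness,
                    "geometry": {k: float(v) for k, v in b.geometry.items()},
                    "excluded_reason": b.excluded_reason,
                }
            )
        return json.dumps({"branches": payload}, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AirwayTreeModel":
        payload = json.loads(text)
        branches = []
        for d in payload["branches"]:
            branches.append(
                Branch(
                    id=int(d["id"]),
                    parent_id=None if d["parent_id"] is None else int(d["parent_id"]),
                    centerline=np.asarray(d["centerline_mm"], dtype=float),
                    generation=d.get("generation"),
                    lobe=d.get("lobe"),
                    lumen_diameter=d.get("lumen_diameter_mm"),
                    wall_thickness=d.get("wall_thickness_mm"),
                    geometry=dict(d.get("geometry", {})),
                )
            )
            branches[-1].excluded_reason = d.get("excluded_reason")
        return cls(branches)


def label_generations(tree: AirwayTreeModel) -> AirwayTreeModel:
    """Number generations breadth-first from the trachea (G1).

    Every child is exactly one generation deeper than its parent, so a
    trifurcation increments all three children equally.
    """
    queue = deque([(tree.root_id, 1)])
    while queue:
        bid, gen = queue.popleft()
        tree.branches[bid].generation = gen
        for cid in tree.children(bid):
            queue.append((cid, gen + 1))
    return tree


def assign_lobes(tree: AirwayTreeModel, lobar_entry_labels: dict[int, str]) -> AirwayTreeModel:
    """Propagate the six lobar entry labels down the tree.

    ``lobar_entry_labels`` maps branch id → lobe name for the lobar bronchi.
    Descendants inherit; the trachea and main bronchi are labelled by their
    central names. A G>=4 branch with no labelled ancestor is flagged
    unassigned (``lobe`` stays None, ``excluded_reason`` set) and is skipped
    by the lobar aggregates.
    """
    if any(b.generation is None for b in tree):
        label_generations(tree)
    root = tree.branches[tree.root_id]
    root.lobe = "trachea"
    # centrals: generation-2 branches without an entry label
    queue = deque([tree.root_id])
    main_names = iter(("right-main", "left-main"))
    while queue:
        bid = queue.popleft()
        b = tree.branches[bid]
        if bid in lobar_entry_labels:
            b.lobe = lobar_entry_labels[bid]
        elif b.parent_id is not None:
            parent_lobe = tree.branches[b.parent_id].lobe
            if parent_lobe in CENTRAL_LABELS or parent_lobe is None:
                if b.generation == 2:
                    b.lobe = next(main_names, "central")
                else:
                    b.lobe = None
                    b.excluded_reason = "no labelled lobar ancestor"
            else:
                b.lobe = parent_lobe
        queue.extend(tree.children(bid))
    return tree
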