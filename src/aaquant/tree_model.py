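"""Bronchial-tree data model and generation/lobe labeling.

An airway tree is a rooted tree of centreline branches. Airway *generation*
counts branching events from the trachea (trachea 0, main stem bronchi 1).
Because upper- and lower-lobe segmental bronchi sit at different generations,
analyses are aligned on the *segmental generation*: each segmental bronchus is
renumbered 1 and its descendants count up from there. Segmental generation >= 4
defines the peripheral airways.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

LOBES = ("RUL", "RML", "RLL", "LUL", "LING", "LLL", "central")

#: segmental generation at or beyond which an airway counts as peripheral
PERIPHERAL_SEG_GEN = 4

#: offset added when renumbering generations from the segmental bronchus, so
#: that the segmental bronchus itself gets segmental generation 1
SEG_GEN_OFFSET = 1


class TreeStructureError(ValueError):
    """Raised when branch links do not form a valid rooted tree."""


class TreeParseError(ValueError):
    """Raised when a tree file violates the JSON schema."""


class LabelingError(ValueError):
    """Raised when generation labels cannot be assigned consistently."""


@dataclass
class Branch:
    """One airway branch: a centreline polyline plus per-branch attributes.

    Ground-truth radii (``inner_radius_mm``, ``outer_radius_mm``,
    ``artery_radius_mm``) are present only for synthetic trees; real segmented
    trees carry geometry and labels only.
    """

    branch_id: str
    parent_id: Optional[str]
    centreline: np.ndarray  # (n, 3) world mm
    lobe: str = "central"
    segment_label: Optional[str] = None
    is_segmental_bronchus: bool = False
    inner_radius_mm: Optional[float] = None
    outer_radius_mm: Optional[float] = None
    artery_radius_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.centreline = np.asarray(self.centreline, dtype=float)
        if self.centreline.ndim != 2 or self.centreline.shape[1] != 3:
            raise ValueError(
                f"branch {self.branch_id}: centreline must be (n, 3), "
                f"got {self.centreline.shape}"
            )
        if len(self.centreline) < 2:
            raise ValueError(f"branch {self.branch_id}: centreline needs >= 2 points")
        steps = np.linalg.norm(np.diff(self.centreline, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError(
                f"branch {self.branch_id}: consecutive centreline points coincide"
            )
        if self.lobe not in LOBES:
            raise ValueError(f"branch {self.branch_id}: unknown lobe {self.lobe!r}")
        if self.inner_radius_mm is not None and self.outer_radius_mm is not None:
            if not (self.outer_radius_mm > self.inner_radius_mm > 0):
                raise ValueError(
                    f"branch {self.branch_id}: need outer > inner > 0, got "
                    f"outer={self.outer_radius_mm}, inner={self.inner_radius_mm}"
                )
        if self.artery_radius_mm is not None and self.artery_radius_mm <= 0:
            raise ValueError(f"branch {self.branch_id}: artery radius must be > 0")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.diff(self.centreline, axis=0), axis=1).sum())

    def point_at(self, fraction: float) -> np.ndarray:
        """Point at an arclength fraction in [0, 1] along the centreline."""
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"arclength fraction must be in [0, 1], got {fraction}")
        seg = np.linalg.norm(np.diff(self.centreline, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        target = fraction * cum[-1]
        i = int(np.searchsorted(cum, target, side="right") - 1)
        i = min(i, len(seg) - 1)
        t = (target - cum[i]) / seg[i]
        return (1 - t) * self.centreline[i] + t * self.centreline[i + 1]


class AirwayTree:
    """Rooted bronchial tree keyed by branch_id.

    Validates on construction: exactly one root, acyclic connected parent
    links, and each non-root branch starting on (near) its parent centreline.
    """

    def __init__(self, branches: Sequence[Branch], root_id: Optional[str] = None,
                 attach_tol_mm: float = 1.0):
        self.branches: Dict[str, Branch] = {}
        for b in branches:
            if b.branch_id in self.branches:
                raise TreeStructureError(f"duplicate branch_id {b.branch_id!r}")
            self.branches[b.branch_id] = b

        roots = [b.branch_id for b in self.branches.values() if b.parent_id is None]
        if len(roots) != 1:
            raise TreeStructureError(
                f"tree must have exactly one root, found {len(roots)}: {roots}"
            )
        self.root_id = roots[0]
        if root_id is not None and root_id != self.root_id:
            raise TreeStructureError(
                f"declared root {root_id!r} disagrees with parent links "
                f"(actual root {self.root_id!r})"
            )

        self._children: Dict[str, List[str]] = {bid: [] for bid in self.branches}
        for b in self.branches.values():
            if b.parent_id is None:
                continue
            if b.parent_id not in self.branches:
                raise TreeStructureError(
                    f"branch {b.branch_id!r} references missing parent {b.parent_id!r}"
                )
            self._children[b.parent_id].append(b.branch_id)

        # connectivity (a cycle among non-root branches is unreachable from root)
        seen = set()
        stack = [self.root_id]
        while stack:
            bid = stack.pop()
            seen.add(bid)
            stack.extend(self._children[bid])
        orphans = set(self.branches) - seen
        if orphans:
            raise TreeStructureError(
                f"branches not reachable from root (cycle or orphan): {sorted(orphans)}"
            )

        # branches are maximal inter-branch-point segments, so an internal
        # node always has >= 2 children (trifurcations allowed)
        for bid, kids in self._children.items():
            if len(kids) == 1:
                raise TreeStructureError(
                    f"branch {bid!r} has exactly one child {kids[0]!r}; "
                    f"merge unbranched segments into a single branch"
                )

        for b in self.branches.values():
            if b.parent_id is None:
                continue
            parent = self.branches[b.parent_id]
            d = np.linalg.norm(parent.centreline - b.centreline[0], axis=1).min()
            if d > attach_tol_mm:
                raise TreeStructureError(
                    f"branch {b.branch_id!r} starts {d:.2f} mm from parent "
                    f"{b.parent_id!r} centreline (tolerance {attach_tol_mm} mm)"
                )

    def children(self, branch_id: str) -> List[str]:
        return list(self._children[branch_id])

    def __len__(self) -> int:
        return len(self.branches)

    def __iter__(self):
        return iter(self.branches.values())

    def __getitem__(self, branch_id: str) -> Branch:
        return self.branches[branch_id]


@dataclass
class GenerationLabels:
    """Per-branch generation, segmental-generation and peripheral labels.

    ``segmental_generation`` is absent (no key) for central airways proximal
    to every segmental bronchus.
    """

    generation: Dict[str, int] = field(default_factory=dict)
    segmental_generation: Dict[str, int] = field(default_factory=dict)
    is_peripheral: Dict[str, bool] = field(default_factory=dict)


def label_generations(tree: AirwayTree) -> GenerationLabels:
    """Assign airway generations: trachea 0, +1 at every branching node.

    A trifurcation still advances the generation by one for all children;
    the count is of branching events on the path from the root, not of
    individual daughter splits.
    """
    labels = GenerationLabels()
    queue = deque([(tree.root_id, 0)])
    while queue:
        bid, gen = queue.popleft()
        labels.generation[bid] = gen
        for child in tree.children(bid):
            queue.append((child, gen + 1))
    return labels


def label_segmental_generations(tree: AirwayTree,
                                labels: GenerationLabels) -> GenerationLabels:
    """Renumber generations relative to each segmental bronchus.

    For a branch whose nearest ancestor-or-self segmental bronchus is ``s``:
    ``seg_gen = generation - generation(s) + 1`` so that ``s`` itself gets 1,
    aligning upper and lower lobes that enter their segments at different
    depths. Branches proximal to every segmental bronchus get no segmental
    generation. Peripheral airways are those with ``seg_gen >= 4``.
    """
    if not labels.generation:
        labels = label_generations(tree)
    labels.segmental_generation = {}
    labels.is_peripheral = {}

    def walk(bid: str, seg_root_gen: Optional[int]) -> None:
        b = tree[bid]
        if b.is_segmental_bronchus:
            seg_root_gen = labels.generation[bid]
        if seg_root_gen is not None:
            sg = labels.generation[bid] - seg_root_gen + SEG_GEN_OFFSET
            labels.segmental_generation[bid] = sg
            labels.is_peripheral[bid] = sg >= PERIPHERAL_SEG_GEN
        else:
            labels.is_peripheral[bid] = False
            if not tree.children(bid) and b.lobe != "central":
                raise LabelingError(
                    f"leaf {bid!r} in lobe {b.lobe} has no segmental-bronchus "
                    f"ancestor"
                )
        for child in tree.children(bid):
            walk(child, seg_root_gen)

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, len(tree) + 100))
    try:
        walk(tree.root_id, None)
    finally:
        sys.setrecursionlimit(old)
    return labels


def label_tree(tree: AirwayTree) -> GenerationLabels:
    """Convenience: generation + segmental-generation labeling in one call."""
    return label_segmental_generations(tree, label_generations(tree))


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------

_RADIUS_KEYS = ("inner_radius_mm", "outer_radius_mm", "artery_radius_mm")


def write_tree(tree: AirwayTree, path) -> None:
    """Write a tree as JSON (world-mm coordinates, full float precision)."""
    doc = {
        "root_id": tree.root_id,
        "branches": [
            {
                "branch_id": b.branch_id,
                "parent_id": b.parent_id,
                "centreline": b.centreline.tolist(),
                "lobe": b.lobe,
                "segment_label": b.segment_label,
                "is_segmental_bronchus": b.is_segmental_bronchus,
                **{k: getattr(b, k) for k in _RADIUS_KEYS if getattr(b, k) is not None},
            }
            for b in tree
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_tree(path) -> AirwayTree:
    """Read a JSON tree document, validating schema and tree invariants."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TreeParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "branches" not in doc:
        raise TreeParseError(f"{path}: $.branches missing")
    branches = []
    seen = set()
    for i, rec in enumerate(doc["branches"]):
        where = f"{path}: $.branches[{i}]"
        for key in ("branch_id", "parent_id", "centreline"):
            if key not in rec:
                raise TreeParseError(f"{where}.{key} missing")
        if rec["branch_id"] in seen:
            raise TreeParseError(f"{where}: duplicate branch_id {rec['branch_id']!r}")
        seen.add(rec["branch_id"])
        try:
            branches.append(Branch(
                branch_id=rec["branch_id"],
                parent_id=rec["parent_id"],
                centreline=np.asarray(rec["centreline"], dtype=float),
                lobe=rec.get("lobe", "central"),
                segment_label=rec.get("segment_label"),
                is_segmental_bronchus=bool(rec.get("is_segmental_bronchus", False)),
                **{k: rec.get(k) for k in _RADIUS_KEYS},
            ))
        except ValueError as exc:
            raise TreeParseError(f"{where}: {exc}") from exc
    try:
        tree = AirwayTree(branches, root_id=doc.get("root_id"))
    except TreeStructureError as exc:
        raise TreeParseError(f"{path}: $.branches: {exc}") from exc
    return tree
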