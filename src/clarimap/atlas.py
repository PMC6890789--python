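"""Hierarchical brain-atlas ontology and label-volume utilities.

An atlas comes in two aligned pieces: an integer label volume (every voxel
carries the id of the finest region containing it) and an ontology — a tree
of regions from the root (whole brain) down to leaf structures such as
individual cortical layers.  Each node records its ``graph_depth`` (distance
from the root) and ``graph_order`` (depth-first enumeration position, the
convention used by the Allen structure graph), both of which downstream
connectivity filters rely on.

The ontology JSON dialect is a flat record list.  Field names can be
remapped through an alias table so real Allen structure-graph exports load
unchanged (``parent_structure_id`` vs ``parent_id``, ``st_level`` vs
``graph_depth``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .volio import VoxelGrid

__all__ = [
    "OntologyNode",
    "OntologyTree",
    "LabelVolume",
    "load_ontology",
    "collapse_to_depth",
    "labels_in_mask",
]

#: default alias table: canonical field -> accepted JSON keys, first match wins
FIELD_ALIASES: dict[str, tuple[str, ...]] = {
    "id": ("id",),
    "acronym": ("acronym", "abbrev"),
    "name": ("name", "safe_name"),
    "parent_id": ("parent_id", "parent_structure_id"),
    "graph_depth": ("graph_depth", "depth", "st_level"),
    "graph_order": ("graph_order", "order"),
}


@dataclasses.dataclass(frozen=True)
class OntologyNode:
    id: int
    acronym: str
    name: str
    parent_id: int | None
    graph_depth: int
    graph_order: int


class OntologyTree:
    """Region hierarchy with O(1) id lookup and parent/child navigation."""

    def __init__(self, nodes: list[OntologyNode]):
        self.nodes: dict[int, OntologyNode] = {}
        for node in nodes:
            if node.id in self.nodes:
                raise ValueError(f"duplicate ontology id {node.id}")
            self.nodes[node.id] = node
        roots = [n for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self.children: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for node in self.nodes.values():
            if node.parent_id is not None:
                if node.parent_id not in self.nodes:
                    raise ValueError(
                        f"node {node.id} references unknown parent {node.parent_id}"
                    )
                self.children[node.parent_id].append(node.id)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for nid in self.nodes:
            seen = set()
            cur: int | None = nid
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle in parent chain at id {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent_id

    def __contains__(self, node_id: int) -> bool:
        return node_id in self.nodes

    def __getitem__(self, node_id: int) -> OntologyNode:
        return self.nodes[node_id]

    def ancestors(self, node_id: int) -> list[OntologyNode]:
        """Path from the node's parent up to the root, nearest first."""
        if node_id not in self.nodes:
            raise KeyError(f"unknown ontology id {node_id}")
        out = []
        cur = self.nodes[node_id].parent_id
        while cur is not None:
            node = self.nodes[cur]
            out.append(node)
            cur = node.parent_id
        return out

    def ancestor_at_depth(self, node_id: int, depth: int) -> OntologyNode:
        """The unique ancestor at ``depth`` (the node itself if shallower)."""
        node = self.nodes[node_id]
        if node.graph_depth <= depth:
            return node
        for anc in self.ancestors(node_id):
            if anc.graph_depth == depth:
                return anc
        return self.root

    def descendants(self, node_id: int) -> set[int]:
        out: set[int] = set()
        stack = list(self.children[node_id])
        while stack:
            nid = stack.pop()
            out.add(nid)
            stack.extend(self.children[nid])
        return out

    def max_depth(self) -> int:
        return max(n.graph_depth for n in self.nodes.values())

    def to_records(self) -> list[dict]:
        recs = []
        for node in sorted(self.nodes.values(), key=lambda n: n.graph_order):
            recs.append(
                {
                    "id": node.id,
                    "acronym": node.acronym,
                    "name": node.name,
                    "parent_id": node.parent_id,
                    "graph_depth": node.graph_depth,
                    "graph_order": node.graph_order,
                }
            )
        return recs

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_records(), indent=1))


def load_ontology(path: str | Path, aliases: dict[str, tuple[str, ...]] | None = None) -> OntologyTree:
    """Load a flat-record ontology JSON into an :class:`OntologyTree`.

    ``aliases`` overrides the default field-name alias table, letting
    Allen-style exports (``parent_structure_id``/``st_level``) load without
    conversion.
    """
    aliases = {**FIELD_ALIASES, **(aliases or {})}
    records = json.loads(Path(path).read_text())
    if isinstance(records, dict) and "msg" in records:  # Allen API envelope
        records = records["msg"]

    def pick(rec: dict, field: str):
        for key in aliases[field]:
            if key in rec:
                return rec[key]
        raise ValueError(f"record missing required field {field!r}: {rec}")

    nodes = []
    for rec in records:
        nodes.append(
            OntologyNode(
                id=int(pick(rec, "id")),
                acronym=str(pick(rec, "acronym")),
                name=str(pick(rec, "name")),
                parent_id=(lambda p: None if p is None else int(p))(pick(rec, "parent_id")),
                graph_depth=int(pick(rec, "graph_depth")),
                graph_order=int(pick(rec, "graph_order")),
            )
        )
    return OntologyTree(nodes)


@dataclasses.dataclass
class LabelVolume:
    """Integer region map aligned to a voxel grid."""

    grid: VoxelGrid
    ontology: OntologyTree

    def __post_init__(self) -> None:
        if not np.issubdtype(self.grid.data.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")
        present = np.unique(self.grid.data)
        unknown = [int(v) for v in present if v != 0 and int(v) not in self.ontology]
        if unknown:
            raise ValueError(f"label values missing from ontology: {unknown}")

    @property
    def data(self) -> np.ndarray:
        return self.grid.data

    def region_ids(self) -> list[int]:
        return [int(v) for v in np.unique(self.grid.data) if v != 0]

    def region_volume_mm3(self, region_id: int) -> float:
        nvox = int(np.count_nonzero(self.grid.data == region_id))
        voxel_mm3 = float(np.prod(self.grid.spacing_um / 1000.0))
        return nvox * voxel_mm3


def collapse_to_depth(labels: LabelVolume, target_depth: int, up_k_levels: int | None = None) -> LabelVolume:
    """Replace every voxel id by its ancestor at ``target_depth``.

    Regions already at or above the target depth pass through unchanged.
    ``up_k_levels`` is a convenience mode: each id is collapsed k levels
    toward the root instead of to a fixed depth (the "grand-parent" grouping
    used to pool cortical layers into their parent area is k=2).
    """
    if up_k_levels is None and target_depth < 0:
        raise ValueError("target_depth must be >= 0")
    tree = labels.ontology
    mapping = {}
    for rid in labels.region_ids():
        if up_k_levels is not None:
            depth = max(tree[rid].graph_depth - up_k_levels, 0)
        else:
            depth = target_depth
        mapping[rid] = tree.ancestor_at_depth(rid, depth).id
    out = labels.grid.data.copy()
    for src, dst in mapping.items():
        if src != dst:
            out[labels.grid.data == src] = dst
    return LabelVolume(labels.grid.like(out), tree)


def labels_in_mask(labels: LabelVolume, mask: VoxelGrid, top_n: int | None = None) -> list[tuple[int, int]]:
    """Regions present in a binary mask, as (id, in-mask voxel count).

    Sorted by count descending, ties broken by ascending id; at most
    ``top_n`` entries.
    """
    if not labels.grid.same_geometry(mask):
        raise ValueError("mask and label volume geometries differ")
    m = mask.data.astype(bool)
    vals = labels.grid.data[m]
    vals = vals[vals != 0]
    ids, counts = np.unique(vals, return_counts=True)
    pairs = sorted(zip(ids.tolist(), counts.tolist()), key=lambda t: (-t[1], t[0]))
    if top_n is not None:
        pairs = pairs[:top_n]
    return [(int(i), int(c)) for i, c in pairs]
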