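"""Lumen skeletonization and the labeled centerline segment tree.

The lumen mask is thinned to a one-voxel-wide skeleton, organized into a
rooted tree of segments split at branch voxels, with the root being the
segment containing the minimum-z skeleton point (the aortic end of the
tree in feet-first axial CTA).  Each centerline point carries world mm
coordinates and a radius (distance to the nearest background voxel).

Anatomical names are supplied by the user as a label map — they are clinical
knowledge, not something inferable from the mask — and validated against a
packaged AHA-style 17-name vocabulary.  Unlabeled segments inherit their
nearest labeled ancestor's name with a ``-sub`` suffix.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skimage_skeletonize

from .errors import InputError
from .segmentation import LumenMask, structuring_element

__all__ = [
    "Segment",
    "CenterlineTree",
    "skeletonize",
    "build_tree",
    "estimate_radius",
    "apply_labels",
    "aha_segment_names",
    "load_label_map",
]

UNLABELED = "unlabeled"


@dataclass
class Segment:
    """One centerline segment: an ordered run of points between tree nodes."""

    id: int
    parent: int | None
    points: np.ndarray  # (N, 3) world mm
    indices: np.ndarray  # (N, 3) voxel indices
    radii: np.ndarray | None = None  # (N,) mm
    label: str = UNLABELED

    @property
    def length(self) -> float:
        """Polyline length in mm (sum of consecutive point distances)."""
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class CenterlineTree:
    segments: dict[int, Segment] = field(default_factory=dict)
    root: int = 0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def children(self, seg_id: int) -> list[int]:
        return sorted(s.id for s in self.segments.values() if s.parent == seg_id)

    def depth(self, seg_id: int) -> int:
        d = 0
        seg = self.segments[seg_id]
        while seg.parent is not None:
            seg = self.segments[seg.parent]
            d += 1
        return d

    def is_labeled(self) -> bool:
        return any(s.label != UNLABELED for s in self.segments.values())

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "spacing": list(self.spacing),
            "origin": list(self.origin),
            "segments": [
                {
                    "id": s.id,
                    "parent": s.parent,
                    "label": s.label,
                    "length_mm": s.length,
                    "points": np.asarray(s.points, dtype=float).tolist(),
                    "indices": np.asarray(s.indices, dtype=int).tolist(),
                    "radii": None if s.radii is None else np.asarray(s.radii, dtype=float).tolist(),
                }
                for s in sorted(self.segments.values(), key=lambda s: s.id)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CenterlineTree":
        segs = {}
        for sd in d["segments"]:
            segs[sd["id"]] = Segment(
                id=sd["id"],
                parent=sd["parent"],
                points=np.asarray(sd["points"], dtype=float).reshape(-1, 3),
                indices=np.asarray(sd["indices"], dtype=int).reshape(-1, 3),
                radii=None if sd.get("radii") is None else np.asarray(sd["radii"], dtype=float),
                label=sd.get("label", UNLABELED),
            )
        return cls(
            segments=segs, root=d["root"],
            spacing=tuple(d.get("spacing", (1.0, 1.0, 1.0))),
            origin=tuple(d.get("origin", (0.0, 0.0, 0.0))),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "CenterlineTree":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def all_labeled_points(self) -> tuple[np.ndarray, list[str], np.ndarray]:
        """Concatenated (points, labels, depths) over all segments, for localization."""
        pts, labs, deps = [], [], []
        for s in self.segments.values():
            d = self.depth(s.id)
            for p in np.asarray(s.points, dtype=float):
                pts.append(p)
                labs.append(s.label)
                deps.append(d)
        return np.asarray(pts), labs, np.asarray(deps)


def skeletonize(mask: LumenMask) -> np.ndarray:
    """Thin the lumen to a one-voxel-wide, topology-preserving skeleton."""
    if not mask.mask.any():
        raise InputError("cannot skeletonize an empty mask")
    _, ncomp = ndimage.label(mask.mask, structure=structuring_element(26))
    if ncomp != 1:
        raise InputError(
            f"mask has {ncomp} connected components; skeletonize expects one "
            "(run region_grow first)"
        )
    if int(mask.mask.sum()) == 1:
        return mask.mask.copy()
    skel = _skimage_skeletonize(mask.mask)
    return np.asarray(skel, dtype=bool)


def _voxel_graph(skeleton: np.ndarray, spacing) -> tuple[nx.Graph, np.ndarray]:
    coords = np.argwhere(skeleton)
    index_of = {tuple(c): i for i, c in enumerate(coords)}
    sp = np.asarray(spacing, dtype=float)
    g = nx.Graph()
    g.add_nodes_from(range(len(coords)))
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)  # half the 26-neighbourhood; undirected graph
    ]
    for i, c in enumerate(coords):
        for off in offsets:
            nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            j = index_of.get(nb)
            if j is not None:
                w = float(np.linalg.norm(np.asarray(off) * sp))
                g.add_edge(i, j, weight=w)
    return g, coords


def build_tree(
    skeleton: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    prune_mm: float = 0.0,
) -> CenterlineTree:
    """Organize skeleton voxels into a rooted tree of segments.

    Segments are split at branch voxels (three or more skeleton neighbours).
    The root is the segment containing the skeleton point with minimum world
    z coordinate (ties broken by minimum y, then x).  Cycles — closed loops
    from imaging artifacts — are broken by dropping the longest edge of each
    loop (minimum spanning tree), with a warning.  Leaf spurs shorter than
    *prune_mm* hanging off a junction are removed first.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    if not skeleton.any():
        raise InputError("cannot build a tree from an empty skeleton")
    g, coords = _voxel_graph(skeleton, spacing)
    if nx.number_connected_components(g) != 1:
        raise InputError("skeleton is disconnected; build_tree expects one component")
    if g.number_of_edges() >= g.number_of_nodes():
        warnings.warn("skeleton contains loops; breaking each by removing its longest edge", stacklevel=2)
        g = nx.minimum_spanning_tree(g, weight="weight")

    if prune_mm > 0:
        _prune_spurs(g, prune_mm)

    world = np.asarray(origin, dtype=float) + coords * np.asarray(spacing, dtype=float)
    # root voxel: min world z, ties by y then x
    order = np.lexsort((world[:, 0], world[:, 1], world[:, 2]))
    root_node = next(n for n in order if g.has_node(n))

    def sort_key(node: int):
        w = world[node]
        return (w[2], w[1], w[0])

    segments: dict[int, Segment] = {}
    next_id = [0]

    def add_segment(path: list[int], parent: int | None) -> int:
        sid = next_id[0]
        next_id[0] += 1
        segments[sid] = Segment(
            id=sid, parent=parent,
            points=world[path].copy(), indices=coords[path].copy(),
        )
        return sid

    if g.degree(root_node) == 0:
        add_segment([root_node], None)
    else:
        visited_edges: set[tuple[int, int]] = set()
        # walk each branch from the root outward; split at nodes of degree != 2
        stack: list[tuple[int, int | None]] = [(root_node, None)]
        while stack:
            node, parent_seg = stack.pop()
            for nb in sorted(g.neighbors(node), key=sort_key):
                e = (min(node, nb), max(node, nb))
                if e in visited_edges:
                    continue
                path = [node]
                prev, cur = node, nb
                visited_edges.add(e)
                path.append(cur)
                while g.degree(cur) == 2 and cur != root_node:
                    nxt = next(n for n in g.neighbors(cur) if n != prev)
                    ee = (min(cur, nxt), max(cur, nxt))
                    if ee in visited_edges:
                        break
                    visited_edges.add(ee)
                    prev, cur = cur, nxt
                    path.append(cur)
                sid = add_segment(path, parent_seg)
                if g.degree(cur) > 2 or cur == root_node:
                    stack.append((cur, sid))
    tree = CenterlineTree(
        segments=segments, root=0,
        spacing=tuple(float(s) for s in spacing),
        origin=tuple(float(o) for o in origin),
    )
    return tree


def _prune_spurs(g: nx.Graph, prune_mm: float) -> None:
    """Remove leaf paths shorter than prune_mm that hang off a junction."""
    changed = True
    while changed:
        changed = False
        for leaf in [n for n in g.nodes if g.degree(n) == 1]:
            if not g.has_node(leaf):
                continue
            path = [leaf]
            length = 0.0
            cur = leaf
            while True:
                nbs = [n for n in g.neighbors(cur) if n not in path]
                if not nbs:
                    break  # the whole component is this path: never prune
                nxt = nbs[0]
                length += g.edges[cur, nxt]["weight"]
                if length >= prune_mm:
                    break
                if g.degree(nxt) > 2:  # short leaf path ending at a junction
                    g.remove_nodes_from(path)
                    changed = True
                    break
                path.append(nxt)
                cur = nxt


def estimate_radius(tree: CenterlineTree, mask: LumenMask) -> CenterlineTree:
    """Fill per-point radii: Euclidean mm distance to the nearest background voxel.

    The distance is anisotropy-aware (computed with the grid spacing) and is
    the raw distance to the nearest background voxel centre.  Radii grow
    monotonically if the mask is dilated.  Points must lie inside the mask.
    """
    edt = ndimage.distance_transform_edt(mask.mask, sampling=mask.spacing)
    for seg in tree.segments.values():
        idx = np.asarray(seg.indices, dtype=int)
        inside = mask.mask[idx[:, 0], idx[:, 1], idx[:, 2]]
        if not inside.all():
            bad = idx[~inside][0]
            raise InputError(f"centerline point at voxel {tuple(int(v) for v in bad)} lies outside the mask")
        seg.radii = edt[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
    return tree


def aha_segment_names() -> dict[str, str]:
    """The packaged controlled vocabulary: short code -> full segment name."""
    text = resources.files("voxelmap").joinpath("data/aha17_segments.txt").read_text()
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, name = line.split("\t", 1)
        out[code] = name
    return out


def load_label_map(path) -> dict[str, str]:
    """Read a two-column label map file: ``<segment id or path key> <name>``."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, name = line.replace(",", " ").split(None, 1)
        out[key] = name.strip()
    return out


def _resolve_key(tree: CenterlineTree, key) -> int:
    """Resolve a segment id or a branch-order path ('root', 'root/0/1') to an id."""
    if isinstance(key, (int, np.integer)):
        if int(key) in tree.segments:
            return int(key)
        raise KeyError(key)
    s = str(key)
    if s.isdigit() and int(s) in tree.segments:
        return int(s)
    parts = s.split("/")
    if parts[0] != "root":
        raise KeyError(key)
    cur = tree.root
    for p in parts[1:]:
        kids = tree.children(cur)
        if not p.isdigit() or int(p) >= len(kids):
            raise KeyError(key)
        cur = kids[int(p)]
    return cur


def apply_labels(tree: CenterlineTree, label_map: dict) -> CenterlineTree:
    """Attach anatomical names to segments and propagate to descendants.

    Keys are segment ids or branch-order paths (``root/0/1``: second child of
    the first child of the root), so a map survives re-runs where raw ids
    change.  Segments without an explicit label inherit the nearest labeled
    ancestor's name with ``-sub`` appended; with no labeled ancestor they stay
    ``unlabeled``.  Names outside the packaged vocabulary only warn.
    """
    explicit: dict[int, str] = {}
    unknown = []
    for key, name in label_map.items():
        try:
            explicit[_resolve_key(tree, key)] = str(name)
        except KeyError:
            unknown.append(key)
    if unknown:
        raise InputError(f"label map keys do not resolve to any segment: {unknown}")
    vocab = aha_segment_names()
    odd = sorted({n for n in explicit.values() if n.split("-sub")[0] not in vocab})
    if odd:
        warnings.warn(f"labels not in the AHA vocabulary: {odd}", stacklevel=2)

    def resolve(seg_id: int) -> str:
        if seg_id in explicit:
            return explicit[seg_id]
        seg = tree.segments[seg_id]
        while seg.parent is not None:
            if seg.parent in explicit:
                return explicit[seg.parent] + "-sub"
            seg = tree.segments[seg.parent]
        return UNLABELED

    for sid, seg in tree.segments.items():
        seg.label = resolve(sid)
    return tree
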