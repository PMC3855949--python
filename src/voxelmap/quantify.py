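"""Severity classification, plaque detection, volumetry, and localization.

Wall attenuation is binned into six severity levels
(0-49, 50-99, 100-199, 200-299, 300-399, >=400 HU); levels 1-3 grade
noncalcified plaque (NCP), levels 4-6 calcified plaque (CP).  A healthy wall
shows a characteristic outward-decreasing gradient — the innermost layer
sits in level 3, the middle in level 2, the outermost in level 1 — so an
NCP candidate is a wall voxel whose level EXCEEDS its layer's expected
level while staying in the NCP range.  Candidates are grouped into
26-connected components; each surviving component is one plaque, quantified
per level (voxel count, mm^3, percent of plaque volume) and localized to the
anatomical segment of the nearest labeled centerline points by majority
vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .centerline import CenterlineTree
from .errors import InputError, ParameterError
from .segmentation import LumenMask, structuring_element
from .voxel_map import VoxelMapLabels, WallModel

__all__ = [
    "LevelScheme",
    "Plaque",
    "classify_level",
    "level_percents",
    "detect_plaques",
    "quantify_plaque",
    "locate_plaque",
    "export_obj",
    "report",
    "DEFAULT_BASELINE",
]

# expected severity level per wall layer on a healthy outward-decreasing wall
DEFAULT_BASELINE: dict[int, int] = {1: 3, 2: 2, 3: 1}

DEFAULT_MIN_VOXELS = 4

NCP_MAX_LEVEL = 3


@dataclass(frozen=True)
class LevelScheme:
    """Contiguous HU bins covering [0, inf) with level ids 1..6 and display colors."""

    edges: tuple[float, ...] = (0.0, 50.0, 100.0, 200.0, 300.0, 400.0)
    colors: tuple[str, ...] = ("#2c7bb6", "#abd9e9", "#ffffbf", "#fdae61", "#d7191c", "#7f0000")

    def __post_init__(self):
        if list(self.edges) != sorted(self.edges) or self.edges[0] != 0.0:
            raise ParameterError("level edges must start at 0 and increase")
        if len(self.colors) != len(self.edges):
            raise ParameterError("need one color per level")

    @property
    def n_levels(self) -> int:
        return len(self.edges)


DEFAULT_SCHEME = LevelScheme()


def classify_level(hu, scheme: LevelScheme = DEFAULT_SCHEME):
    """Severity level (1..6) of a clamped wall attenuation value.

    Accepts scalars or arrays.  Negative input is an error: the epicardial-fat
    clamp must be applied upstream (see :func:`voxelmap.voxel_map.build_cawm`).
    """
    arr = np.asarray(hu)
    if np.any(arr < 0):
        raise InputError("negative HU passed to classify_level; clamp fat to 0 upstream")
    lev = np.digitize(arr, scheme.edges[1:], right=False) + 1
    if np.isscalar(hu) or arr.ndim == 0:
        return int(lev)
    return lev.astype(np.int8)


@dataclass
class Plaque:
    """One connected component of outlier wall voxels."""

    id: int
    voxels: np.ndarray  # (N, 3) voxel indices
    levels: np.ndarray  # (N,) severity level per voxel
    layers: np.ndarray  # (N,) Voxel-Map layer per voxel
    level_counts: dict[int, int] = field(default_factory=dict)
    level_volumes_mm3: dict[int, float] = field(default_factory=dict)
    level_percents: dict[int, float] = field(default_factory=dict)
    total_volume_mm3: float = 0.0
    label: str = ""
    centroid_mm: tuple[float, float, float] | None = None
    vote_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


def _round2(x: float) -> float:
    """Round half-up to two decimals (33.285 -> 33.29, never banker's)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def level_percents(level_volumes: dict[int, float]) -> dict[int, float]:
    """Percent of total plaque volume per level, rounded half-up to 2 decimals."""
    total = float(sum(level_volumes.values()))
    if total <= 0:
        raise InputError("total plaque volume must be positive")
    return {lev: _round2(100.0 * v / total) for lev, v in level_volumes.items()}


def detect_plaques(
    wall: WallModel,
    vmap: VoxelMapLabels | None = None,
    baseline: dict[int, int] | None = None,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    scheme: LevelScheme = DEFAULT_SCHEME,
) -> list[Plaque]:
    """Find noncalcified-plaque components among wall-layer outlier voxels.

    A candidate voxel sits on a positive (wall) layer, is not fat-clamped,
    and its severity level exceeds the layer's expected baseline level while
    remaining in the NCP range (level <= 3).  Voxels in levels 4-6 are
    calcified plaque: tallied by :func:`report`, never part of an NCP
    component.  Candidates are grouped under 26-connectivity and components
    smaller than *min_voxels* are discarded.
    """
    if vmap is None:
        vmap = wall.vmap
    if vmap is None:
        raise InputError("detect_plaques needs the companion VoxelMapLabels")
    if wall.values.shape != vmap.labels.shape:
        raise InputError("wall model and voxel map shapes differ")
    baseline = DEFAULT_BASELINE if baseline is None else baseline
    layers_present = sorted(int(v) for v in np.unique(vmap.labels) if v > 0)
    missing = [k for k in layers_present if k not in baseline]
    if missing:
        raise ParameterError(f"baseline has no expected level for wall layer(s) {missing}")

    levels = classify_level(wall.values, scheme)
    expected = np.zeros_like(vmap.labels, dtype=np.int8)
    for layer, lev in baseline.items():
        expected[vmap.labels == layer] = lev
    candidate = (
        (vmap.labels > 0)
        & ~wall.fat_flag
        & (levels > expected)
        & (levels <= NCP_MAX_LEVEL)
    )
    comp, ncomp = ndimage.label(candidate, structure=structuring_element(26))
    plaques: list[Plaque] = []
    for lab in range(1, ncomp + 1):
        vox = np.argwhere(comp == lab)
        if len(vox) < min_voxels:
            continue
        plaques.append(
            Plaque(
                id=len(plaques) + 1,
                voxels=vox,
                levels=levels[vox[:, 0], vox[:, 1], vox[:, 2]],
                layers=vmap.labels[vox[:, 0], vox[:, 1], vox[:, 2]].astype(int),
            )
        )
    return plaques


def quantify_plaque(p: Plaque, spacing) -> Plaque:
    """Fill per-level voxel counts, volumes (mm^3), percents, total and centroid."""
    if p.n_voxels == 0:
        raise InputError("cannot quantify an empty plaque")
    dx, dy, dz = (float(s) for s in spacing)
    voxvol = dx * dy * dz
    levs, counts = np.unique(p.levels, return_counts=True)
    p.level_counts = {int(l): int(c) for l, c in zip(levs, counts)}
    p.level_volumes_mm3 = {l: c * voxvol for l, c in p.level_counts.items()}
    p.total_volume_mm3 = p.n_voxels * voxvol
    p.level_percents = level_percents(p.level_volumes_mm3)
    c = p.voxels.mean(axis=0) * np.asarray([dx, dy, dz])
    p.centroid_mm = tuple(float(v) for v in c)
    return p


def locate_plaque(p: Plaque, tree: CenterlineTree, mask: LumenMask) -> str:
    """Anatomical label of a plaque: majority vote of nearest centerline points.

    Each plaque voxel votes for the label of its nearest (Euclidean, mm)
    centerline point.  Ties between labels are broken in favour of the
    segment closer to the root.  Vote counts are recorded on the plaque for
    audit.
    """
    if not tree.is_labeled():
        raise InputError("locate_plaque requires a labeled centerline tree (apply_labels first)")
    pts, labels, depths = tree.all_labeled_points()
    if len(pts) == 0:
        raise InputError("centerline tree has no points")
    world = mask.index_to_world(p.voxels)
    _, nearest = cKDTree(pts).query(world)
    votes: dict[str, int] = {}
    label_depth: dict[str, int] = {}
    for i in np.atleast_1d(nearest):
        lab = labels[int(i)]
        votes[lab] = votes.get(lab, 0) + 1
        d = int(depths[int(i)])
        label_depth[lab] = min(label_depth.get(lab, d), d)
    # majority; ties -> smaller depth (closer to root)
    winner = sorted(votes.items(), key=lambda kv: (-kv[1], label_depth[kv[0]], kv[0]))[0][0]
    p.vote_counts = dict(sorted(votes.items(), key=lambda kv: -kv[1]))
    p.label = winner
    return winner


def export_obj(obj, spacing, origin, path) -> None:
    """Write a closed triangulated surface of a voxel set as Wavefront OBJ.

    Accepts a :class:`Plaque` or a :class:`LumenMask` (or a raw binary grid).
    The surface is the 0.5 iso-surface of the binary indicator, computed on a
    one-voxel zero pad so it is always watertight; vertices are in world mm.
    """
    import trimesh
    from skimage.measure import marching_cubes

    if isinstance(obj, Plaque):
        vox = np.asarray(obj.voxels, dtype=int)
        if len(vox) == 0:
            raise InputError("cannot export an empty plaque")
        lo = vox.min(axis=0)
        grid = np.zeros(vox.max(axis=0) - lo + 1, dtype=bool)
        grid[tuple((vox - lo).T)] = True
        offset = lo
    else:
        grid = obj.mask if isinstance(obj, LumenMask) else np.asarray(obj, dtype=bool)
        if not grid.any():
            raise InputError("cannot export an empty voxel set")
        offset = np.zeros(3, dtype=int)
    padded = np.pad(grid, 1).astype(np.float32)
    verts, faces, _, _ = marching_cubes(
        padded, level=0.5, spacing=tuple(float(s) for s in spacing),
        gradient_direction="ascent",  # outward-facing winding: positive enclosed volume
    )
    sp = np.asarray(spacing, dtype=float)
    verts = verts - sp + (np.asarray(offset) * sp) + np.asarray(origin, dtype=float)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    Path(path).write_text(trimesh.exchange.obj.export_obj(mesh, include_normals=False))


def report(
    plaques: list[Plaque],
    tree: CenterlineTree | None = None,
    wall: WallModel | None = None,
    scheme: LevelScheme = DEFAULT_SCHEME,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate quantified, located plaques.

    Returns ``(per_plaque, per_segment)``: one row per plaque with total and
    per-level volumes/percents and centroid, plus per-segment aggregates.
    With no plaques both tables are header-only.  If *wall* is given, a
    calcified-plaque (levels 4-6) voxel tally is attached as
    ``per_plaque.attrs['cp_voxel_counts']``.
    """
    n_lev = scheme.n_levels
    cols = ["plaque_id", "label", "n_voxels", "total_mm3"]
    for lev in range(1, n_lev + 1):
        cols += [f"level{lev}_mm3", f"level{lev}_pct"]
    cols += ["cx_mm", "cy_mm", "cz_mm"]
    rows = []
    for p in plaques:
        row: dict = {
            "plaque_id": p.id,
            "label": p.label,
            "n_voxels": p.n_voxels,
            "total_mm3": p.total_volume_mm3,
        }
        for lev in range(1, n_lev + 1):
            row[f"level{lev}_mm3"] = p.level_volumes_mm3.get(lev, 0.0)
            row[f"level{lev}_pct"] = p.level_percents.get(lev, 0.0)
        cx, cy, cz = p.centroid_mm if p.centroid_mm else (np.nan, np.nan, np.nan)
        row["cx_mm"], row["cy_mm"], row["cz_mm"] = cx, cy, cz
        rows.append(row)
    per_plaque = pd.DataFrame(rows, columns=cols)
    if len(per_plaque):
        per_segment = (
            per_plaque.groupby("label", as_index=False)
            .agg(n_plaques=("plaque_id", "count"), total_mm3=("total_mm3", "sum"))
        )
    else:
        per_segment = pd.DataFrame(columns=["label", "n_plaques", "total_mm3"])
    if wall is not None:
        on_shell = (wall.vmap.labels > 0) if wall.vmap is not None else (wall.values > 0)
        lv = classify_level(wall.values[on_shell & ~wall.fat_flag], scheme)
        cp = {lev: int((lv == lev).sum()) for lev in range(NCP_MAX_LEVEL + 1, n_lev + 1)}
        per_plaque.attrs["cp_voxel_counts"] = cp
    return per_plaque, per_segment


def report_long(per_plaque: pd.DataFrame, scheme: LevelScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Long-format report (one row per plaque x nonzero level) for CSV export."""
    rows = []
    for _, r in per_plaque.iterrows():
        for lev in range(1, scheme.n_levels + 1):
            if r[f"level{lev}_mm3"] > 0:
                rows.append(
                    {
                        "plaque_id": r["plaque_id"],
                        "label": r["label"],
                        "total_mm3": r["total_mm3"],
                        "level": lev,
                        "level_mm3": r[f"level{lev}_mm3"],
                        "level_pct": r[f"level{lev}_pct"],
                        "cx": r["cx_mm"],
                        "cy": r["cy_mm"],
                        "cz": r["cz_mm"],
                    }
                )
    return pd.DataFrame(
        rows, columns=["plaque_id", "label", "total_mm3", "level", "level_mm3", "level_pct", "cx", "cy", "cz"]
    )
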