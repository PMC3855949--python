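"""Digital vessel phantoms: branching tubes in a CT-like volume with truth.

The generator emulates the attenuation structure the pipeline relies on:

* a contrast-filled lumen whose HU falls linearly with arc length from the
  aortic (proximal, low-z) end toward the distal tips — bright near the
  root, dimmer distally, always above the 160 HU segmentation threshold;
* a vessel wall whose mean HU decreases outward layer by layer (the
  innermost shell sits in severity level 3, the middle in level 2, the
  outermost in level 1);
* negative-HU epicardial fat everywhere else;
* optional spherical noncalcified-plaque inserts of known voxel set, HU and
  target wall layer;
* optional additive Gaussian noise (rounded to integer HU) from a single
  seeded stream, so volumes are bitwise reproducible.

Everything the pipeline should recover is returned as :class:`PhantomTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import InputError, ParameterError
from .segmentation import LumenMask
from .volume_io import CTVolume
from .voxel_map import build_voxel_map

__all__ = [
    "Branch",
    "PlaqueInsert",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "default_spec",
    "tube_spec",
    "y_spec",
    "label_map_from_truth",
]

SEGMENTATION_THRESHOLD = 160.0


@dataclass(frozen=True)
class Branch:
    """A straight vessel branch: start point (mm), unit direction, length, radius."""

    name: str
    start: tuple[float, float, float]
    direction: tuple[float, float, float]
    length_mm: float
    radius_mm: float
    parent: str | None = None

    def unit(self) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ParameterError(f"branch {self.name!r} has a zero direction")
        return d / n

    def end(self) -> np.ndarray:
        return np.asarray(self.start, dtype=float) + self.unit() * self.length_mm


@dataclass(frozen=True)
class PlaqueInsert:
    """A spherical NCP insert on a wall layer of a branch.

    ``arc_frac`` places the sphere centre along the branch (0 = start,
    1 = end); the centre is pushed outward perpendicular to the branch so the
    lesion sits one-sided on the wall, and only voxels of ``layer`` within
    ``radius_mm`` of the centre are stamped with ``hu``.
    """

    branch: str
    arc_frac: float
    radius_mm: float
    hu: float
    layer: int = 2


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    branches: tuple[Branch, ...] = ()
    lumen_hu: tuple[float, float] = (450.0, 250.0)  # proximal, distal
    wall_layer_hu: tuple[float, ...] = (140.0, 75.0, 25.0)  # layers +1, +2, +3
    fat_hu: float = -80.0
    plaques: tuple[PlaqueInsert, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    connectivity: int = 6
    n_in: int = 1

    def __post_init__(self):
        if self.lumen_hu[0] <= SEGMENTATION_THRESHOLD:
            raise ParameterError("proximal lumen HU must exceed the 160 HU threshold")
        hw = self.wall_layer_hu
        if any(hw[i] <= hw[i + 1] for i in range(len(hw) - 1)):
            raise ParameterError("wall layer HU means must strictly decrease outward")
        if self.fat_hu >= 0:
            raise ParameterError("background fat HU must be negative")
        for p in self.plaques:
            if not (0 <= p.hu < 200):
                raise ParameterError(f"plaque HU {p.hu} outside the NCP range [0, 200)")

    @property
    def n_out(self) -> int:
        return len(self.wall_layer_hu)


@dataclass
class PlaqueTruth:
    voxels: np.ndarray  # (N, 3) indices
    hu: float
    layer: int
    level: int
    branch: str


@dataclass
class PhantomTruth:
    lumen: LumenMask
    branches: dict[str, np.ndarray] = field(default_factory=dict)  # label -> (N, 3) world mm polyline
    plaques: list[PlaqueTruth] = field(default_factory=list)


def default_spec(
    shape=(128, 128, 128),
    spacing=(0.5, 0.5, 0.5),
    noise_sd: float = 0.0,
    seed: int = 0,
    radius_mm: float = 2.0,
    plaque_radius_mm: float = 2.2,
) -> PhantomSpec:
    """Two-branch right-coronary fixture: pRCA stem, dRCA continuation, RMA side
    branch carrying one level-3 plaque (120 HU) on wall layer +2."""
    ex, ey, ez = (n * s for n, s in zip(shape, spacing))
    z0 = max(0.12 * ez, radius_mm + 4.05 * max(spacing))
    zj = 0.47 * ez
    stem_len = zj - z0
    rma_len = min(0.30 * ez, (0.42 * ex) / 0.6)
    branches = (
        Branch("pRCA", (ex / 2, ey / 2, z0), (0, 0, 1), stem_len, radius_mm),
        Branch("dRCA", (ex / 2, ey / 2, zj), (0, 0, 1), stem_len, radius_mm, parent="pRCA"),
        Branch("RMA", (ex / 2, ey / 2, zj), (0.6, 0, 0.8), rma_len, radius_mm * 0.8, parent="pRCA"),
    )
    plaques = (PlaqueInsert("RMA", 0.55, plaque_radius_mm, 120.0, layer=2),)
    return PhantomSpec(
        shape=tuple(shape), spacing=tuple(spacing),
        branches=branches, plaques=plaques, noise_sd=noise_sd, seed=seed,
    )


def tube_spec(shape=(32, 32, 64), spacing=(1.0, 1.0, 1.0), radius_mm: float = 3.0) -> PhantomSpec:
    """A single straight z-aligned tube (no plaque) for geometry tests."""
    ex, ey, ez = (n * s for n, s in zip(shape, spacing))
    margin = radius_mm + 4 * max(spacing)
    branch = Branch("pRCA", (ex / 2, ey / 2, margin), (0, 0, 1), ez - 2 * margin, radius_mm)
    return PhantomSpec(shape=tuple(shape), spacing=tuple(spacing), branches=(branch,))


def y_spec(shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0), radius_mm: float = 2.5) -> PhantomSpec:
    """A Y-shaped bifurcation (stem at low z, two oblique children)."""
    ex, ey, ez = (n * s for n, s in zip(shape, spacing))
    z0, zj = 0.12 * ez, 0.5 * ez
    child_len = 0.32 * ez
    branches = (
        Branch("pRCA", (ex / 2, ey / 2, z0), (0, 0, 1), zj - z0, radius_mm),
        Branch("dRCA", (ex / 2, ey / 2, zj), (-0.5, 0, 0.866), child_len, radius_mm, parent="pRCA"),
        Branch("RMA", (ex / 2, ey / 2, zj), (0.5, 0, 0.866), child_len, radius_mm, parent="pRCA"),
    )
    return PhantomSpec(shape=tuple(shape), spacing=tuple(spacing), branches=branches)


def _perpendicular(direction: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to *direction*."""
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(direction)))] = 1.0
    p = np.cross(direction, axis)
    return p / np.linalg.norm(p)


def _branch_offsets(branches: tuple[Branch, ...]) -> dict[str, float]:
    """Arc-length offset of each branch start from the tree root."""
    by_name = {b.name: b for b in branches}
    offsets: dict[str, float] = {}

    def offset(b: Branch) -> float:
        if b.name in offsets:
            return offsets[b.name]
        if b.parent is None:
            offsets[b.name] = 0.0
        else:
            parent = by_name[b.parent]
            offsets[b.name] = offset(parent) + float(
                np.linalg.norm(np.asarray(b.start) - np.asarray(parent.start))
            )
        return offsets[b.name]

    for b in branches:
        offset(b)
    return offsets


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Rasterize the phantom volume and its ground truth.

    A voxel belongs to the lumen when its centre lies strictly within one
    branch radius of that branch's axis.  Wall shells are stamped with the
    per-layer means using the same morphology the pipeline applies, so the
    noise-free pipeline recovers the truth exactly.  Deterministic for a
    fixed spec (including its seed).
    """
    if not spec.branches:
        raise ParameterError("phantom spec has no branches")
    shape = tuple(int(n) for n in spec.shape)
    sp = np.asarray(spec.spacing, dtype=float)
    org = np.asarray(spec.origin, dtype=float)
    extent = org + np.asarray(shape) * sp

    step = 0.25 * float(sp.min())
    offsets = _branch_offsets(spec.branches)
    samples, samp_radius, samp_arc, samp_branch = [], [], [], []
    polylines: dict[str, np.ndarray] = {}
    margin = (spec.n_out + 1) * sp.max()
    for bi, b in enumerate(spec.branches):
        n = max(2, int(np.ceil(b.length_mm / step)) + 1)
        t = np.linspace(0.0, b.length_mm, n)
        pts = np.asarray(b.start, dtype=float) + np.outer(t, b.unit())
        lo_ok = (pts - b.radius_mm - margin >= org).all()
        hi_ok = (pts + b.radius_mm + margin <= extent).all()
        if not (lo_ok and hi_ok):
            raise InputError(f"branch {b.name!r} (with its wall layers) exits the grid")
        polylines[b.name] = pts
        samples.append(pts)
        samp_radius.append(np.full(n, b.radius_mm))
        samp_arc.append(offsets[b.name] + t)
        samp_branch.append(np.full(n, bi))
    samples = np.concatenate(samples)
    samp_radius = np.concatenate(samp_radius)
    samp_arc = np.concatenate(samp_arc)

    tree = cKDTree(samples)
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    centers = org + np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * sp
    dist, nearest = tree.query(centers, workers=-1)
    dist = dist.reshape(shape)
    nearest = nearest.reshape(shape)
    lumen = dist < samp_radius[nearest]
    if not lumen.any():
        raise InputError("phantom lumen rasterized to an empty mask")

    hu_prox, hu_dist = spec.lumen_hu
    max_arc = float(samp_arc.max()) or 1.0
    profile = hu_prox + (hu_dist - hu_prox) * samp_arc[nearest] / max_arc

    volume = np.full(shape, float(spec.fat_hu))
    volume[lumen] = profile[lumen]

    mask = LumenMask(spacing=tuple(sp), origin=tuple(org), mask=lumen)
    vmap = build_voxel_map(mask, n_out=spec.n_out, n_in=spec.n_in, connectivity=spec.connectivity)
    for k, hu in enumerate(spec.wall_layer_hu, start=1):
        volume[vmap.labels == k] = hu

    by_name = {b.name: b for b in spec.branches}
    plaque_truths: list[PlaqueTruth] = []
    stamped = np.zeros(shape, dtype=bool)
    level_edges = np.asarray([0.0, 50.0, 100.0, 200.0])
    for p in spec.plaques:
        if p.branch not in by_name:
            raise ParameterError(f"plaque insert references unknown branch {p.branch!r}")
        b = by_name[p.branch]
        axis_pt = np.asarray(b.start, dtype=float) + b.unit() * (p.arc_frac * b.length_mm)
        perp = _perpendicular(b.unit())
        if b.parent is not None and float(np.dot(perp, by_name[b.parent].unit())) > 0:
            perp = -perp  # point away from the parent vessel's wall
        center = axis_pt + perp * (b.radius_mm + p.layer * sp.max())
        on_layer = vmap.labels == p.layer
        within = (np.linalg.norm(centers - center, axis=1) < p.radius_mm).reshape(shape)
        sel = on_layer & within
        if not sel.any():
            raise InputError(f"plaque insert on branch {p.branch!r} stamped no voxels")
        if (sel & stamped).any():
            raise InputError(f"plaque insert on branch {p.branch!r} overlaps a previous insert")
        stamped |= sel
        volume[sel] = p.hu
        level = int(np.digitize(p.hu, level_edges[1:]) + 1)
        plaque_truths.append(
            PlaqueTruth(voxels=np.argwhere(sel), hu=p.hu, layer=p.layer, level=level, branch=b.name)
        )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        volume = volume + rng.normal(0.0, spec.noise_sd, size=shape)
    values = np.rint(volume).astype(np.int16)

    vol = CTVolume(spacing=tuple(sp), origin=tuple(org), values=values)
    truth = PhantomTruth(lumen=mask, branches=polylines, plaques=plaque_truths)
    return vol, truth


def label_map_from_truth(tree, truth: PhantomTruth) -> dict[str, str]:
    """Build a segment-id -> branch-name label map from phantom ground truth.

    Stands in for the manual anatomical labeling a radiologist supplies on
    patient data: each extracted segment is named after the truth branch whose
    axis its points are closest to (majority over points).
    """
    names = list(truth.branches)
    pts = np.concatenate([truth.branches[n] for n in names])
    owner = np.concatenate([np.full(len(truth.branches[n]), i) for i, n in enumerate(names)])
    kd = cKDTree(pts)
    out: dict[str, str] = {}
    for sid, seg in tree.segments.items():
        _, nearest = kd.query(np.asarray(seg.points, dtype=float))
        votes = np.bincount(owner[np.atleast_1d(nearest)], minlength=len(names))
        out[str(sid)] = names[int(np.argmax(votes))]
    return out
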