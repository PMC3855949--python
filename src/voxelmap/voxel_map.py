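"""The Voxel-Map: signed morphological shell layers around the lumen.

Iterated binary dilation of the lumen mask produces one-voxel-thick outward
shells (+1, +2, +3 by default — the vessel wall layers); iterated erosion
produces inward shells (-1 by default — the luminal boundary layer).  With a
6-connected (face) structuring element shell +k is exactly the set of
background voxels at city-block distance k from the lumen, and shell -k the
lumen voxels at city-block distance k from the background.

Restricting the original HU volume to these shells, with negative values
(epicardial fat) clamped to 0 HU, yields the 3D coronary artery wall model
(3D-CAWM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InputError, ParameterError
from .segmentation import LumenMask, structuring_element
from .volume_io import CTVolume, _Grid3D

__all__ = [
    "VoxelMapLabels",
    "WallModel",
    "dilate_shell",
    "erode_shell",
    "build_voxel_map",
    "build_cawm",
    "layer_profile",
]

DEFAULT_N_OUT = 3
DEFAULT_N_IN = 1
DEFAULT_CONNECTIVITY = 6


@dataclass
class VoxelMapLabels(_Grid3D):
    """Signed layer map: +k = k-th outward shell, -k = k-th inward shell, 0 elsewhere."""

    labels: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1), dtype=np.int8))
    n_out: int = DEFAULT_N_OUT
    n_in: int = DEFAULT_N_IN
    connectivity: int = DEFAULT_CONNECTIVITY

    def __post_init__(self) -> None:
        super().__post_init__()
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise InputError(f"label grid must be 3D, got shape {self.labels.shape}")

    def _array(self) -> np.ndarray:
        return self.labels

    def shell(self, k: int) -> np.ndarray:
        """Binary grid of layer k (k != 0)."""
        if k == 0:
            raise ParameterError("layer 0 is 'not in the Voxel-Map', not a shell")
        return self.labels == k


@dataclass
class WallModel(_Grid3D):
    """HU values on the Voxel-Map shells, fat-clamped: the 3D-CAWM.

    ``values`` is zero off-shell and never negative; ``fat_flag`` marks shell
    voxels whose original attenuation was below 0 HU (epicardial fat, set to
    0 but kept inside the model).
    """

    values: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1), dtype=np.int32))
    fat_flag: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1), dtype=bool))
    vmap: VoxelMapLabels | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = np.asarray(self.values)
        self.fat_flag = np.asarray(self.fat_flag, dtype=bool)
        if self.values.shape != self.fat_flag.shape:
            raise InputError("values and fat_flag must share a shape")

    def _array(self) -> np.ndarray:
        return self.values


def _iterated(op, mask: np.ndarray, k: int, structure: np.ndarray) -> np.ndarray:
    if k == 0:
        return mask.copy()
    return op(mask, structure=structure, iterations=k)


def dilate_shell(mask: LumenMask | np.ndarray, k: int, connectivity: int = DEFAULT_CONNECTIVITY) -> np.ndarray:
    """The k-th outward one-voxel-thick boundary: dilate^k(A) \\ dilate^(k-1)(A)."""
    if k < 1:
        raise ParameterError(f"shell order k must be >= 1, got {k}")
    m = mask.mask if isinstance(mask, LumenMask) else np.asarray(mask, dtype=bool)
    st = structuring_element(connectivity)
    inner = _iterated(ndimage.binary_dilation, m, k - 1, st)
    outer = ndimage.binary_dilation(inner, structure=st)
    return outer & ~inner


def erode_shell(mask: LumenMask | np.ndarray, k: int, connectivity: int = DEFAULT_CONNECTIVITY) -> np.ndarray:
    """The k-th inward boundary: erode^(k-1)(A) \\ erode^k(A).

    Each erosion shrinks the region by one voxel in every direction of the
    structuring element; the grid border counts as background.
    """
    if k < 1:
        raise ParameterError(f"shell order k must be >= 1, got {k}")
    m = mask.mask if isinstance(mask, LumenMask) else np.asarray(mask, dtype=bool)
    st = structuring_element(connectivity)
    outer = _iterated(ndimage.binary_erosion, m, k - 1, st)
    inner = ndimage.binary_erosion(outer, structure=st)
    return outer & ~inner


def build_voxel_map(
    mask: LumenMask,
    n_out: int = DEFAULT_N_OUT,
    n_in: int = DEFAULT_N_IN,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> VoxelMapLabels:
    """Assign signed shell labels around (and inside) the lumen.

    Defaults (n_out=3, n_in=1) produce the four wall/boundary layers
    -1, 1, 2, 3.  Dilating more than three times normally crosses the outer
    wall border into tissue at or below 0 HU, so larger n_out warns.
    """
    if n_out < 1:
        raise ParameterError(f"n_out must be >= 1, got {n_out}")
    if n_in < 0:
        raise ParameterError(f"n_in must be >= 0, got {n_in}")
    if n_out > 3:
        warnings.warn(
            "n_out > 3: outward layers beyond the third typically cross the "
            "outer wall border into epicardial fat",
            stacklevel=2,
        )
    if not mask.mask.any():
        raise InputError("cannot build a Voxel-Map around an empty lumen mask")
    st = structuring_element(connectivity)
    labels = np.zeros(mask.shape, dtype=np.int8)
    grown = mask.mask.copy()
    for k in range(1, n_out + 1):
        nxt = ndimage.binary_dilation(grown, structure=st)
        labels[nxt & ~grown] = k
        grown = nxt
    shrunk = mask.mask.copy()
    for k in range(1, n_in + 1):
        nxt = ndimage.binary_erosion(shrunk, structure=st)
        labels[shrunk & ~nxt] = -k
        shrunk = nxt
    return VoxelMapLabels(
        spacing=mask.spacing, origin=mask.origin, labels=labels,
        n_out=n_out, n_in=n_in, connectivity=connectivity,
    )


def build_cawm(vol: CTVolume, vmap: VoxelMapLabels) -> WallModel:
    """Restrict the ORIGINAL volume to the Voxel-Map shells with the fat clamp.

    Wall voxels lie outside the lumen mask, so the source must be the raw
    volume, not the lumen-masked tree model.  Shell voxels below 0 HU are
    epicardial fat: their value is set to 0 and ``fat_flag`` is raised; they
    stay inside the wall model but are excluded from plaque candidacy.
    Voxels not in the Voxel-Map are excluded (value 0).
    """
    if vol.shape != vmap.shape:
        raise InputError(f"volume shape {vol.shape} != voxel-map shape {vmap.shape}")
    on_shell = vmap.labels != 0
    vals = np.where(on_shell, vol.values, 0)
    fat = on_shell & (vol.values < 0)
    vals = np.where(fat, 0, vals)
    return WallModel(
        spacing=vol.spacing, origin=vol.origin,
        values=vals.astype(np.int32), fat_flag=fat, vmap=vmap,
    )


def layer_profile(wall: WallModel, vmap: VoxelMapLabels | None = None) -> pd.DataFrame:
    """Per-slice, per-layer mean attenuation of the wall model.

    Returns a tidy table with columns ``slice`` (z index), ``layer`` (signed
    shell label), ``mean_hu`` and ``count``.  Fat-clamped voxels contribute
    their clamped value (0 HU) to the means.  Empty (slice, layer) cells are
    reported with count 0 and NaN mean.
    """
    if vmap is None:
        vmap = wall.vmap
    if vmap is None:
        raise InputError("layer_profile needs the companion VoxelMapLabels")
    labels = vmap.labels
    if not (labels != 0).any():
        raise InputError("the Voxel-Map has no shell voxels")
    nz = wall.values.shape[2]
    layer_ids = sorted(int(v) for v in np.unique(labels) if v != 0)
    rows = []
    for z in range(nz):
        lab_z = labels[:, :, z]
        val_z = wall.values[:, :, z]
        for layer in layer_ids:
            sel = lab_z == layer
            n = int(sel.sum())
            mean = float(val_z[sel].mean()) if n else float("nan")
            rows.append({"slice": z, "layer": layer, "mean_hu": mean, "count": n})
    return pd.DataFrame(rows, columns=["slice", "layer", "mean_hu", "count"])
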