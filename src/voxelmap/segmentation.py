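"""Coronary lumen segmentation and the masked coronary tree model.

Contrast-filled lumen is segmented by a global HU threshold (default
strictly greater than 160 HU), refined to a single seeded connected
component with enclosed cavities filled, and combined with the original
volume by voxelwise multiplication to give the 3D coronary tree model
(3D-CTM): original attenuation values inside the lumen, zero elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InputError, ParameterError
from .volume_io import CTVolume, _Grid3D

__all__ = ["LumenMask", "threshold_lumen", "region_grow", "build_ctm", "structuring_element"]

DEFAULT_THRESHOLD_HU = 160


@dataclass
class LumenMask(_Grid3D):
    """Binary 3D grid marking lumen voxels (True = lumen)."""

    mask: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1), dtype=bool))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise InputError(f"mask must be 3D, got shape {self.mask.shape}")

    def _array(self) -> np.ndarray:
        return self.mask


def structuring_element(connectivity: int) -> np.ndarray:
    """3x3x3 structuring element: 6 (faces) or 26 (full neighbourhood)."""
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ParameterError(f"connectivity must be 6 or 26, got {connectivity}")


def threshold_lumen(vol: CTVolume, threshold_hu: float = DEFAULT_THRESHOLD_HU) -> LumenMask:
    """Mark voxels with attenuation strictly greater than *threshold_hu*.

    The comparison is strict: a voxel at exactly the threshold value is
    background.  An all-background result is legal (e.g. a non-contrast scan).
    """
    if vol.values.size == 0:
        raise InputError("cannot threshold an empty volume")
    return LumenMask(spacing=vol.spacing, origin=vol.origin, mask=vol.values > threshold_hu)


def default_seed(vol: CTVolume) -> tuple[int, int, int]:
    """Deterministic automatic seed: the maximum-HU voxel.

    In contrast CTA the brightest voxel sits in or near the aortic root,
    which is connected to the coronary ostia, so it is a safe lumen seed.
    Ties resolve to the lowest flat index (C order).
    """
    idx = np.unravel_index(int(np.argmax(vol.values)), vol.values.shape)
    return tuple(int(i) for i in idx)


def region_grow(mask: LumenMask, seed: tuple[int, int, int], connectivity: int = 26) -> LumenMask:
    """Keep the seed's connected component and fill its enclosed cavities.

    The component is taken under *connectivity* (26 by default, since
    coronaries run obliquely through slices); interior cavities — background
    regions not reaching the grid border — are filled using the dual
    6-connectivity on the background so holes cannot leak out through
    diagonal gaps.  The result is idempotent.
    """
    seed = tuple(int(s) for s in seed)
    if len(seed) != 3 or any(s < 0 or s >= n for s, n in zip(seed, mask.shape)):
        raise InputError(f"seed {seed} is outside the grid of shape {mask.shape}")
    if not mask.mask[seed]:
        raise InputError(
            f"seed {seed} lies on background; pick a lumen voxel "
            "(e.g. the highest-HU voxel of the volume)"
        )
    labels, _ = ndimage.label(mask.mask, structure=structuring_element(connectivity))
    component = labels == labels[seed]
    filled = ndimage.binary_fill_holes(component, structure=structuring_element(6))
    return LumenMask(spacing=mask.spacing, origin=mask.origin, mask=filled)


def build_ctm(vol: CTVolume, mask: LumenMask) -> CTVolume:
    """Voxelwise multiply: original HU inside the lumen mask, 0 outside.

    This is the 3D coronary tree model; masked HU values are carried through
    exactly, with no clamping at this stage.
    """
    if vol.shape != mask.shape:
        raise InputError(f"volume shape {vol.shape} != mask shape {mask.shape}")
    out = np.where(mask.mask, vol.values, 0)
    return CTVolume(spacing=vol.spacing, origin=vol.origin, values=out)
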