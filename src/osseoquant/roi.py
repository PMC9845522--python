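"""Regions of interest: distance shells and anatomical compartments.

All peri-implant ROIs are built from anisotropy-aware Euclidean distance
transforms of binary masks: the 5 mm gas-evaluation region around the
screw restricted to the bone area, and the 30 µm / 1 mm enlargement
shells around the registered non-degraded reference screw in which bone
volume fraction is evaluated.  Distances are measured from the screw
voxel set (0 inside the mask), and shells exclude the mask itself —
they are the peri-implant region where bone or gas is sought.
ROI-dependent quantities are normalized to a 100 mm^3 reference volume
so differently sized compartments are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import ndimage

from .volume_io import LabeledVolume

__all__ = [
    "RoiSet",
    "distance_map",
    "dilate_to_distance",
    "build_gas_roi",
    "enlarged_screw_shells",
    "normalize_per_100mm3",
]

SUB_ROI_NAMES = ("dpROI", "ppROI", "cROI", "iROI")


@dataclass
class RoiSet:
    """Named binary masks on a shared grid.

    The four anatomical sub-ROIs (dpROI, ppROI, cROI, iROI), when present,
    must be pairwise disjoint.
    """

    masks: dict[str, np.ndarray] = field(default_factory=dict)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"ROI masks must share one grid shape, got {shapes}")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        present = [n for n in SUB_ROI_NAMES if n in self.masks]
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                if (self.masks[a] & self.masks[b]).any():
                    raise ValueError(f"sub-ROI masks {a} and {b} overlap")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.masks)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def volume_mm3(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.voxel_volume

    def add(self, name: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask, dtype=bool)
        if self.masks and mask.shape != next(iter(self.masks.values())).shape:
            raise ValueError("mask shape does not match ROI grid")
        self.masks[name] = mask


def _as_mask(mask: LabeledVolume | np.ndarray) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    if isinstance(mask, LabeledVolume):
        return mask.labels != 0, mask.spacing
    return np.asarray(mask, dtype=bool), None


def distance_map(mask: LabeledVolume | np.ndarray, spacing=None) -> np.ndarray:
    """Per-voxel Euclidean distance (mm) to the nearest mask voxel.

    Exact and anisotropy-aware; 0 inside the mask.  ``spacing`` is taken
    from the volume when a :class:`LabeledVolume` is given.
    """
    m, sp = _as_mask(mask)
    spacing = sp if spacing is None else tuple(float(s) for s in spacing)
    if spacing is None:
        raise ValueError("spacing required when passing a bare array")
    if not m.any():
        raise ValueError("distance_map of an empty mask is undefined")
    return ndimage.distance_transform_edt(~m, sampling=spacing)


def dilate_to_distance(mask: LabeledVolume | np.ndarray, d: float, spacing=None) -> np.ndarray:
    """All voxels within Euclidean distance ``d`` (mm) of the mask.

    Includes the mask itself; ``d = 0`` returns the mask unchanged.
    Monotone in ``d``.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    m, sp = _as_mask(mask)
    spacing = sp if spacing is None else spacing
    if d == 0:
        return m.copy()
    return distance_map(m, spacing) <= d


def build_gas_roi(
    screw_mask: LabeledVolume | np.ndarray,
    bone_region_mask: np.ndarray,
    d: float = 5.0,
    spacing=None,
) -> np.ndarray:
    """Gas-evaluation ROI: within ``d`` mm of the screw surface, inside the
    bone area, excluding the screw itself.

    Restricting to the bone area drops gas in the (removed) soft tissue.
    Empty result raises no error but warns.
    """
    m, sp = _as_mask(screw_mask)
    spacing = sp if spacing is None else spacing
    bone_region = np.asarray(bone_region_mask, dtype=bool)
    if bone_region.shape != m.shape:
        raise ValueError("screw and bone-region masks must share a grid")
    roi = dilate_to_distance(m, d, spacing) & bone_region & ~m
    if not roi.any():
        warnings.warn("gas ROI is empty (bone region disjoint from the peri-implant shell)")
    return roi


def enlarged_screw_shells(
    registered_reference_mask: LabeledVolume,
    distances_mm: tuple[float, ...] = (0.03, 1.0),
    strict: bool = True,
) -> RoiSet:
    """Peri-implant shells by enlarging the registered reference screw.

    For each distance ``d`` the shell is every voxel within ``d`` of the
    reference screw, excluding the screw mask itself.  The default
    distances are 30 µm (about one osteoblast, probing embedding
    shrinkage at the interface) and 1 mm (about twice the thread depth,
    averaging out thread-shape effects on bone formation).

    A shell thinner than one voxel is unresolvable on the grid: in
    ``strict`` mode that is an error; otherwise a warning reports the
    effective achievable thickness (one voxel) and proceeds.
    """
    ref, _ = _as_mask(registered_reference_mask)
    spacing = registered_reference_mask.spacing
    out = RoiSet(spacing=spacing)
    names = {0.03: "shell_30um", 1.0: "shell_1mm"}
    for d in distances_mm:
        d_eff = d
        if d < min(spacing):
            msg = (f"requested shell of {d} mm is thinner than one voxel "
                   f"(spacing {min(spacing)} mm)")
            if strict:
                raise ValueError(msg)
            d_eff = min(spacing)
            warnings.warn(msg + f"; effective thickness is one voxel ({d_eff} mm)")
        shell = dilate_to_distance(ref, d_eff, spacing) & ~ref
        name = names.get(round(d, 6), f"shell_{d:g}mm")
        out.add(name, shell)
    return out


def normalize_per_100mm3(value: float, roi_volume: float) -> float:
    """Scale an ROI-dependent quantity to a 100 mm^3 reference ROI."""
    if roi_volume <= 0:
        raise ValueError("roi_volume must be > 0")
    return value * 100.0 / roi_volume
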