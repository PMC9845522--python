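"""Independent brute-force oracles.

Deliberately naive implementations (explicit neighbor enumeration,
all-pairs distances) used to validate the vectorized production code.
They share no code path with the package internals.
"""

import itertools

import numpy as np

OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
OFFSETS_26 = [
    o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)
]


def brute_force_bic(implant, bone, connectivity=6):
    """Count implant surface and bone-contact voxels by explicit loops.

    A neighbor beyond the grid edge counts as background (non-implant,
    non-bone), matching scanner fields of view that crop the object.
    """
    offsets = OFFSETS_6 if connectivity == 6 else OFFSETS_26
    implant = np.asarray(implant, bool)
    bone = np.asarray(bone, bool)
    nz, ny, nx = implant.shape
    surface = contact = 0
    for z, y, x in np.argwhere(implant):
        is_surface = is_contact = False
        for dz, dy, dx in offsets:
            zz, yy, xx = z + dz, y + dy, x + dx
            if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx):
                is_surface = True
                continue
            if not implant[zz, yy, xx]:
                is_surface = True
                if bone[zz, yy, xx]:
                    is_contact = True
        surface += is_surface
        contact += is_contact
    return surface, contact


def brute_force_distance_map(mask, spacing):
    """All-pairs minimum Euclidean distance to the mask voxel set."""
    mask = np.asarray(mask, bool)
    spacing = np.asarray(spacing, float)
    sources = np.argwhere(mask) * spacing
    out = np.empty(mask.shape, float)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx) * spacing
        out[idx] = np.sqrt(((sources - p) ** 2).sum(axis=1)).min()
    return out
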