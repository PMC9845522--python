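"""Synthetic screw-in-bone phantoms with exact ground truth.

The generator stands in for scan data: it voxelizes an analytic cortical
screw (head + threaded shaft + tapered tip), embeds it in a layered bone
environment (entry cortex, cortical tube around an intramedullary cavity,
trabecular bone proximal and distal of a physis gap), applies uniform
surface recession with a corrosion-product layer, and rasterizes gas
pockets.  Every stage is a pure function of its specs, seed and spacing,
and the true per-class volumes, recession depth and per-ROI gas volumes
are recorded for recovery tests.

Geometry conventions
--------------------
Array axis 0 is the screw axis; the screw head sits at world ``z = 0`` with
the tip toward increasing ``z``, and the axis passes through world
``(y, x) = (0, 0)``.  The screw solid is modeled as a signed distance
field (negative inside): a trapezoidal thread profile swept helically
around the core, unioned with the head cylinder, with linearly tapered
radii at the tip.  Voxelization uses the center-in-solid rule, so voxel
volumes converge to the analytic solid volume as spacing shrinks.

The analytic field also lets surface recession be applied at *sub-voxel*
depths (``sdf < -depth``), which a mask-based distance threshold cannot
represent once the depth falls below one voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .volume_io import LabeledVolume, LabelScheme, DEFAULT_SCHEME

__all__ = [
    "ScrewSpec",
    "BoneEnvironmentSpec",
    "DegradationSpec",
    "PhantomGroundTruth",
    "PhantomResult",
    "screw_sdf",
    "generate_screw",
    "apply_degradation",
    "generate_bone_environment",
    "insert_gas_pockets",
    "generate_phantom",
]

#: Mineralized-tissue-free gap modeling the growth plate, mm.
PHYSIS_GAP_MM = 0.6

SUB_ROI_NAMES = ("dpROI", "ppROI", "cROI", "iROI")


@dataclass(frozen=True)
class ScrewSpec:
    """Analytic cortical-screw geometry (all lengths in mm).

    Defaults approximate a 3.5 mm x 16 mm cortical compression screw:
    3.5 mm outer thread diameter, 2.4 mm core, 1.25 mm pitch, cylindrical
    head and a conically tapered tip.  The trapezoidal thread profile has
    a root half-width of ``0.3 * pitch`` and a crest half-width of
    ``0.08 * pitch``.
    """

    outer_diameter: float = 3.5
    core_diameter: float = 2.4
    length: float = 16.0
    thread_pitch: float = 1.25
    head_diameter: float = 4.5
    head_length: float = 2.0
    tip_taper_length: float = 2.0

    def __post_init__(self) -> None:
        if self.core_diameter > self.outer_diameter:
            raise ValueError("core_diameter must be <= outer_diameter")
        for name in ("outer_diameter", "core_diameter", "length", "thread_pitch",
                     "head_diameter", "head_length", "tip_taper_length"):
            if getattr(self, name) < 0 or (name not in ("head_length", "tip_taper_length") and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")

    @property
    def thread_depth(self) -> float:
        """Radial height of the thread, ``(outer - core) / 2`` mm."""
        return (self.outer_diameter - self.core_diameter) / 2.0

    @property
    def root_half_width(self) -> float:
        return 0.3 * self.thread_pitch

    @property
    def crest_half_width(self) -> float:
        return 0.08 * self.thread_pitch


@dataclass(frozen=True)
class BoneEnvironmentSpec:
    """Layered bone environment along the screw axis (lengths in mm).

    From the screw head toward the tip: entry cortex of
    ``cortical_thickness``; intramedullary cavity of ``medullary_extent``
    lined by a cortical tube of the same wall thickness; trabecular bone
    up to the physis plane at ``physis_plane_offset``; a mineralized-
    tissue-free physis gap; trabecular bone beyond it.  Trabecular bone is
    a thresholded Gaussian random field hitting ``trabecular_fill_fraction``
    exactly (by quantile) with struts of ``trabecular_strut_thickness``.
    """

    cortical_thickness: float = 1.5
    trabecular_fill_fraction: float = 0.3
    trabecular_strut_thickness: float = 0.4
    physis_plane_offset: float = 11.0
    medullary_extent: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.trabecular_fill_fraction < 1.0:
            raise ValueError("trabecular_fill_fraction must be in (0, 1)")
        if self.cortical_thickness <= 0 or self.trabecular_strut_thickness <= 0:
            raise ValueError("thicknesses must be > 0")


@dataclass(frozen=True)
class DegradationSpec:
    """Degradation state: uniform surface recession of the metal (mm), a
    corrosion-product layer of ``layer_thickness`` (mm) grown outward from
    the residual metal, and spherical gas pockets ``(center_mm, radius_mm)``."""

    recession_depth: float = 0.0
    layer_thickness: float = 0.0
    gas_pockets: Sequence[tuple[tuple[float, float, float], float]] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.recession_depth < 0 or self.layer_thickness < 0:
            raise ValueError("recession_depth and layer_thickness must be >= 0")


@dataclass
class PhantomGroundTruth:
    """Exact phantom truth used as the oracle in recovery tests."""

    class_volumes_mm3: dict[str, float] = field(default_factory=dict)
    recession_depth_mm: float = 0.0
    applied_transform: object | None = None  # RigidTransform or None (identity)
    gas_volume_per_roi_mm3: dict[str, float] = field(default_factory=dict)


@dataclass
class PhantomResult:
    """Bundle returned by :func:`generate_phantom`."""

    volume: LabeledVolume
    rois: "object"  # RoiSet; forward reference avoids an import cycle
    reference_screw: LabeledVolume
    ground_truth: PhantomGroundTruth


# ---------------------------------------------------------------------------
# analytic screw


def _segment_distance(pr, pu, ar, au, br, bu):
    """Vectorized point-to-segment distance in the (r, u) plane."""
    dr, du = br - ar, bu - au
    denom = dr * dr + du * du
    t = np.clip(((pr - ar) * dr + (pu - au) * du) / np.where(denom == 0, 1.0, denom), 0.0, 1.0)
    return np.hypot(pr - (ar + t * dr), pu - (au + t * du))


def screw_sdf(spec: ScrewSpec) -> Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]:
    """Approximate signed distance field of the screw solid.

    Returns ``f(z, y, x) -> sdf`` (mm, negative inside) for world
    coordinates in mm.  The field is metrically accurate near the surface
    (|grad| ~ 1) except close to the head/shaft corner ring and on the
    tapered tip, which is what surface-recession modeling needs.
    """
    R_o = spec.outer_diameter / 2.0
    R_c = spec.core_diameter / 2.0
    R_h = spec.head_diameter / 2.0
    pitch = spec.thread_pitch
    w0, w1 = spec.root_half_width, spec.crest_half_width
    L, Lh, Lt = spec.length, spec.head_length, spec.tip_taper_length

    def f(z, y, x):
        z, y, x = np.broadcast_arrays(np.asarray(z, float), np.asarray(y, float), np.asarray(x, float))
        r = np.hypot(y, x)
        theta = np.arctan2(x, y)

        # tip taper: both radii shrink linearly to 0 over the last Lt mm
        scale = np.ones_like(z)
        if Lt > 0:
            scale = np.clip((L - z) / Lt, 0.0, 1.0)
        rc = R_c * scale
        ro = rc + (R_o - R_c) * scale  # keep thread depth shrinking with the core

        # axial offset to the nearest thread centerline (helix phase)
        h = z - pitch * theta / (2.0 * np.pi)
        u = np.abs((h + pitch / 2.0) % pitch - pitch / 2.0)

        # cross-section profile boundary: crest | flank | root
        d_crest = _segment_distance(r, u, ro, 0.0 * u, ro, np.minimum(w1, w0))
        d_flank = _segment_distance(r, u, ro, np.minimum(w1, w0) * np.ones_like(u), rc, w0 * np.ones_like(u))
        d_root = _segment_distance(r, u, rc, w0 * np.ones_like(u), rc, (pitch / 2.0) * np.ones_like(u))
        dist = np.minimum(np.minimum(d_crest, d_flank), d_root)

        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.clip((w0 - u) / max(w0 - w1, 1e-12), 0.0, 1.0)
        r_limit = rc + (ro - rc) * frac
        inside_profile = r <= r_limit
        sd_profile = np.where(inside_profile, -dist, dist)

        # clip the shaft to the axial slab [0, L]
        dz_out = np.maximum(-z, z - L)
        sd_shaft = np.maximum(sd_profile, dz_out)

        # head cylinder over [0, head_length]
        if Lh > 0:
            drad = r - R_h
            dax = np.maximum(-z, z - Lh)
            outside = np.hypot(np.maximum(drad, 0.0), np.maximum(dax, 0.0))
            sd_head = np.where((drad < 0) & (dax < 0), np.maximum(drad, dax), outside)
            sd = np.minimum(sd_shaft, sd_head)
            # off-center drive notch cut into the head: breaks the
            # screw's helical near-symmetry so pose is fully determined
            cz, cy = 0.35 * Lh, R_h - 0.2
            hz, hy, hx = 0.55 * Lh, 0.9, 0.45
            qz, qy, qx = np.abs(z - cz) - hz, np.abs(y - cy) - hy, np.abs(x) - hx
            box_out = np.sqrt(np.maximum(qz, 0.0) ** 2 + np.maximum(qy, 0.0) ** 2 + np.maximum(qx, 0.0) ** 2)
            box_sd = box_out + np.minimum(np.maximum(qz, np.maximum(qy, qx)), 0.0)
            return np.maximum(sd, -box_sd)
        return sd_shaft

    return f


def posed_sdf(sdf: Callable, transform) -> Callable:
    """Signed distance field of a rigidly moved solid.

    ``transform`` (a :class:`~osseoquant.registration.RigidTransform`)
    maps the solid's canonical pose into the grid frame; points are
    pulled back through its inverse before evaluating ``sdf``.
    """
    R = transform.matrix
    c = np.asarray(transform.center_mm)
    t = np.asarray(transform.translation_mm)

    def f(z, y, x):
        z, y, x = np.broadcast_arrays(np.asarray(z, float), np.asarray(y, float), np.asarray(x, float))
        p = np.stack([z, y, x], axis=-1)
        q = (p - c - t) @ R + c  # row-vector convention: p @ R == R.T applied
        return sdf(q[..., 0], q[..., 1], q[..., 2])

    return f


def default_pose(spec: ScrewSpec):
    """Canonical slightly off-axis placement of the phantom screw.

    A perfectly grid-aligned screw is an artifact no scanner produces:
    its flat faces coincide with voxel-center planes, so sub-voxel
    surface recession would be quantized to whole voxel layers.  A ~2
    degree tilt plus a sub-voxel offset restores the generic position of
    real scans (and doubles as registration ground truth).
    """
    from .registration import RigidTransform

    return RigidTransform(
        rotation_deg=(0.0, 2.0, -1.5),
        translation_mm=(0.013, 0.007, -0.011),
        center_mm=(spec.length / 2.0, 0.0, 0.0),
    )


def default_reference_pose(spec: ScrewSpec):
    """Generic-position pose of the reference scan (distinct from
    :func:`default_pose` so registration has something to recover)."""
    from .registration import RigidTransform

    return RigidTransform(
        rotation_deg=(0.0, -1.7, 1.2),
        translation_mm=(0.008, -0.0055, 0.0035),
        center_mm=(spec.length / 2.0, 0.0, 0.0),
    )


def _evaluate_on_grid(fn, shape, spacing, origin, chunk_voxels: int = 4_000_000):
    """Evaluate ``fn(z, y, x)`` on a voxel grid in axis-0 slabs."""
    out = np.empty(shape, dtype=np.float32)
    ny, nx = shape[1], shape[2]
    yy = (origin[1] + spacing[1] * np.arange(ny))[:, None]
    xx = (origin[2] + spacing[2] * np.arange(nx))[None, :]
    step = max(1, chunk_voxels // max(ny * nx, 1))
    for z0 in range(0, shape[0], step):
        z1 = min(z0 + step, shape[0])
        zz = (origin[0] + spacing[0] * np.arange(z0, z1))[:, None, None]
        out[z0:z1] = fn(zz, yy[None, :, :], xx[None, :, :])
    return out


def _screw_grid(spec: ScrewSpec, spacing, margin_mm: float):
    """Grid (shape, spacing, origin) enclosing the screw plus a margin."""
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    spacing = tuple(float(s) for s in spacing)
    if spec.thread_depth > 0 and max(spacing) > spec.thread_depth / 2.0:
        raise ValueError(
            f"spacing {max(spacing):g} mm cannot resolve the thread "
            f"(depth {spec.thread_depth:g} mm); need spacing <= thread_depth/2"
        )
    r_max = max(spec.head_diameter, spec.outer_diameter) / 2.0
    pad = margin_mm + 2 * max(spacing)
    lo = (-pad, -(r_max + pad), -(r_max + pad))
    hi = (spec.length + pad, r_max + pad, r_max + pad)
    shape = tuple(int(np.ceil((h - l) / s)) + 1 for l, h, s in zip(lo, hi, spacing))
    return shape, spacing, lo


def generate_screw(
    spec: ScrewSpec,
    spacing: float | tuple[float, float, float],
    margin_mm: float = 0.0,
    pose=None,
    scheme: LabelScheme = DEFAULT_SCHEME,
) -> LabeledVolume:
    """Voxelize the analytic screw (center-in-solid rule).

    The grid encloses the canonical screw plus ``margin_mm`` on every
    side; the world origin is set so the screw head plane is ``z = 0``
    and the axis passes through ``(y, x) = (0, 0)``.  With ``pose`` (a
    rigid transform) the solid is moved before voxelization — supply a
    margin that accommodates it.  Labels are 0 / residual_metal.
    """
    shape, spacing, origin = _screw_grid(spec, spacing, margin_mm)
    fn = screw_sdf(spec)
    if pose is not None:
        fn = posed_sdf(fn, pose)
    sdf = _evaluate_on_grid(fn, shape, spacing, origin)
    labels = np.where(sdf < 0, scheme["residual_metal"], 0).astype(np.uint8)
    return LabeledVolume(labels, spacing, origin, scheme)


def apply_degradation(
    screw: LabeledVolume,
    spec: DegradationSpec,
    sdf: Callable | np.ndarray | None = None,
) -> LabeledVolume:
    """Split a screw mask into residual metal and degradation layer.

    Residual metal is the set of screw voxels deeper than
    ``recession_depth`` below the original surface; the degradation layer
    is a shell of ``layer_thickness`` grown outward from the residual
    metal (it may swell slightly beyond the original surface, as corrosion
    products do).

    With ``sdf`` (the analytic field the screw was voxelized from) the
    recession is applied on the continuous field, which remains exact for
    sub-voxel depths.  Without it, depth below the surface is the
    anisotropy-aware Euclidean distance transform of the mask — faithful
    for any input mask, but quantized to the voxel grid, so depths below
    one voxel leave the mask unchanged.
    """
    scheme = screw.scheme
    mask = screw.mask("implant") | screw.mask("residual_metal")
    if not mask.any():
        raise ValueError("screw mask is empty")
    d = spec.recession_depth

    if sdf is not None:
        if callable(sdf):
            values = _evaluate_on_grid(sdf, screw.shape, screw.spacing, screw.origin)
        else:
            values = np.asarray(sdf)
            if values.shape != screw.shape:
                raise ValueError("precomputed sdf values must match the screw grid")
        residual = values < -d
        layer = (values < spec.layer_thickness - d) & ~residual if spec.layer_thickness > 0 else np.zeros_like(residual)
    else:
        depth = ndimage.distance_transform_edt(mask, sampling=screw.spacing)
        residual = depth > d
        if spec.layer_thickness > 0:
            dist_out = ndimage.distance_transform_edt(~residual, sampling=screw.spacing)
            grown = residual | (dist_out <= spec.layer_thickness)
            # clip to the original screw plus an outward band of layer_thickness
            band = mask | (ndimage.distance_transform_edt(~mask, sampling=screw.spacing) <= spec.layer_thickness)
            layer = grown & band & ~residual
        else:
            layer = np.zeros_like(residual)

    if not residual.any():
        warnings.warn("recession_depth exceeds the maximum inscribed radius; residual metal is empty")

    labels = np.zeros(screw.shape, dtype=np.uint8)
    labels[layer] = scheme["degradation_layer"]
    labels[residual] = scheme["residual_metal"]
    return screw.like(labels)


# ---------------------------------------------------------------------------
# bone environment


def generate_bone_environment(
    spec: BoneEnvironmentSpec,
    grid: LabeledVolume,
    min_margin_mm: float = 5.0,
):
    """Fill bone compartments around a placed screw and emit sub-ROI masks.

    ``grid`` is a labeled volume whose non-background voxels are the
    (possibly degraded) screw; bone is added around it with the screw
    carved out.  Returns ``(volume, RoiSet)`` where the ROI set holds the
    four pairwise-disjoint anatomical compartments: dpROI (trabecular
    distal of the physis), ppROI (trabecular proximal), cROI (cortical
    bone: entry cortex plus the tube lining the cavity) and iROI
    (intramedullary cavity).
    """
    from .roi import RoiSet  # local import: roi depends on volume_io only

    scheme = grid.scheme
    spacing = grid.spacing
    screw = grid.labels != 0

    zz, yy, xx = grid.world_coordinates()
    r = np.hypot(yy, xx)
    r_screw = 0.5 * 3.5  # transverse reach checked against the actual mask below
    half_extent = min(
        -grid.origin[1], grid.origin[1] + spacing[1] * (grid.shape[1] - 1),
        -grid.origin[2], grid.origin[2] + spacing[2] * (grid.shape[2] - 1),
    )
    if screw.any():
        idx = np.argwhere(screw)
        reach = max(
            abs(grid.origin[1] + idx[:, 1].min() * spacing[1]),
            abs(grid.origin[1] + idx[:, 1].max() * spacing[1]),
            abs(grid.origin[2] + idx[:, 2].min() * spacing[2]),
            abs(grid.origin[2] + idx[:, 2].max() * spacing[2]),
        )
        r_screw = reach
    if half_extent - r_screw < min_margin_mm:
        raise ValueError(
            f"peri-implant margin {half_extent - r_screw:.2f} mm < required {min_margin_mm} mm"
        )

    r_bone = half_extent - 0.25  # outer bone boundary; thin soft-tissue rim
    in_bone_cyl = r <= r_bone

    z = zz  # broadcastable (nz,1,1)
    c0, c1 = 0.0, spec.cortical_thickness
    m0, m1 = c1, c1 + spec.medullary_extent
    p0 = spec.physis_plane_offset
    p1 = p0 + PHYSIS_GAP_MM
    if not (m1 < p0):
        raise ValueError("physis_plane_offset must lie beyond cortex + medullary cavity")

    slab_cortex = (z >= c0) & (z < c1)
    slab_medull = (z >= m0) & (z < m1)
    slab_prox = (z >= m1) & (z < p0)
    slab_phys = (z >= p0) & (z < p1)
    slab_dist = z >= p1

    tube_wall = slab_medull & (r > r_bone - spec.cortical_thickness) & in_bone_cyl
    cortical = (slab_cortex & in_bone_cyl) | tube_wall
    medullary = slab_medull & (r <= r_bone - spec.cortical_thickness)
    prox_trab = slab_prox & in_bone_cyl
    dist_trab = slab_dist & in_bone_cyl

    cortical = np.broadcast_to(cortical, grid.shape).copy()
    medullary = np.broadcast_to(medullary, grid.shape).copy()
    prox_trab = np.broadcast_to(prox_trab, grid.shape).copy()
    dist_trab = np.broadcast_to(dist_trab, grid.shape).copy()
    physis = np.broadcast_to(slab_phys & in_bone_cyl, grid.shape).copy()

    rng = np.random.default_rng(spec.rng_seed)
    sigma = [spec.trabecular_strut_thickness / (2.0 * s) for s in spacing]
    noise = ndimage.gaussian_filter(rng.standard_normal(grid.shape).astype(np.float32), sigma=sigma)

    labels = grid.labels.copy()
    bone_code = scheme["bone"]

    labels[cortical & ~screw] = bone_code
    for compartment in (prox_trab, dist_trab):
        sel = compartment & ~screw
        n = int(sel.sum())
        if n == 0:
            continue
        vals = noise[sel]
        # quantile threshold hits the requested fill fraction exactly
        thr = np.quantile(vals, 1.0 - spec.trabecular_fill_fraction)
        bone_here = np.zeros_like(sel)
        bone_here[sel] = vals > thr
        labels[bone_here] = bone_code
    # medullary cavity and physis gap stay background

    rois = RoiSet(
        masks={
            "dpROI": dist_trab & ~screw,
            "ppROI": prox_trab & ~screw,
            "cROI": cortical & ~screw,
            "iROI": medullary & ~screw,
        },
        spacing=spacing,
    )
    return grid.like(labels), rois


def insert_gas_pockets(
    vol: LabeledVolume,
    spec: DegradationSpec,
    rois=None,
) -> tuple[LabeledVolume, PhantomGroundTruth]:
    """Rasterize spherical gas pockets into a labeled volume.

    Precedence: gas overwrites bone and background only — never residual
    metal or the degradation layer.  A pocket centered inside residual
    metal is an error.  The returned ground truth records the rasterized
    per-class volumes and, when ``rois`` is given, the gas volume inside
    each sub-ROI (from the rasterized voxels, hence exact).
    """
    scheme = vol.scheme
    labels = vol.labels.copy()
    vv = vol.voxel_volume
    zz, yy, xx = vol.world_coordinates()
    replaceable = (labels == scheme["background"]) | (labels == scheme["bone"])

    for center, radius in spec.gas_pockets:
        cz, cy, cx = center
        iz = int(round((cz - vol.origin[0]) / vol.spacing[0]))
        iy = int(round((cy - vol.origin[1]) / vol.spacing[1]))
        ix = int(round((cx - vol.origin[2]) / vol.spacing[2]))
        if (0 <= iz < vol.shape[0] and 0 <= iy < vol.shape[1] and 0 <= ix < vol.shape[2]
                and labels[iz, iy, ix] == scheme["residual_metal"]):
            raise ValueError(f"gas pocket center {center} lies inside residual metal")
        sphere = ((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) <= radius ** 2
        labels[sphere & replaceable] = scheme["gas"]

    out = vol.like(labels)
    truth = PhantomGroundTruth(
        class_volumes_mm3={name: float((labels == code).sum()) * vv for name, code in scheme.to_dict().items()},
        gas_volume_per_roi_mm3=(
            {name: float(((labels == scheme["gas"]) & rois[name]).sum()) * vv for name in rois.names}
            if rois is not None else {}
        ),
    )
    return out, truth


def generate_phantom(
    seed: int = 0,
    spacing: float = 0.05,
    screw_spec: ScrewSpec | None = None,
    bone_spec: BoneEnvironmentSpec | None = None,
    degradation_spec: DegradationSpec | None = None,
    pose=None,
    reference_pose=None,
    margin_mm: float = 5.5,
) -> PhantomResult:
    """Full phantom: screw + degradation + bone + gas, with ground truth.

    ``seed`` drives every random choice (the trabecular field); all other
    structure is analytic.  Both the implanted screw and the reference
    scan sit at small generic (slightly off-axis) poses — a perfectly
    grid-aligned solid is an artifact no scanner produces and would
    quantize sub-voxel recession to whole voxel layers.  The ground
    truth records the relative transform mapping the reference scan onto
    the implanted screw, which is exactly what registration must
    recover.  Surface recession is applied on the posed analytic field,
    so it stays exact for sub-voxel depths.
    """
    screw_spec = screw_spec or ScrewSpec()
    bone_spec = bone_spec if bone_spec is not None else BoneEnvironmentSpec(rng_seed=seed)
    degradation_spec = degradation_spec or DegradationSpec()
    pose = pose if pose is not None else default_pose(screw_spec)
    reference_pose = reference_pose if reference_pose is not None else default_reference_pose(screw_spec)

    reference = generate_screw(screw_spec, spacing, margin_mm=0.8, pose=reference_pose)
    shape, spacing3, origin = _screw_grid(screw_spec, spacing, margin_mm)
    values = _evaluate_on_grid(posed_sdf(screw_sdf(screw_spec), pose), shape, spacing3, origin)
    screw_vol = LabeledVolume(
        np.where(values < 0, DEFAULT_SCHEME["residual_metal"], 0).astype(np.uint8),
        spacing3, origin, DEFAULT_SCHEME,
    )
    degraded = apply_degradation(screw_vol, degradation_spec, sdf=values)
    with_bone, rois = generate_bone_environment(bone_spec, degraded)
    volume, truth = insert_gas_pockets(with_bone, degradation_spec, rois=rois)
    truth.recession_depth_mm = degradation_spec.recession_depth
    truth.applied_transform = pose.compose(reference_pose.inverse())
    return PhantomResult(volume=volume, rois=rois, reference_screw=reference, ground_truth=truth)
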