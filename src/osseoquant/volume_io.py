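"""Labeled-volume containers and lossless I/O.

A :class:`LabeledVolume` is the universal currency of the pipeline: a 3D
integer label grid plus anisotropic voxel spacing (mm) and a world origin
(mm, center of voxel ``(0, 0, 0)``).  Axis order is array order: ``labels``
axis ``k`` has spacing ``spacing[k]``; the world position of voxel index
``i`` is ``origin + i * spacing``.

Two on-disk formats are supported:

* multi-page TIFF (uint8 labels) with a JSON sidecar ``<name>.json``
  carrying spacing/origin/scheme — TIFF resolution tags are dialect-prone,
  so the sidecar is the single source of truth;
* MetaImage (``.mhd`` + ``.raw``), where the header carries the geometry.

Both round-trip labels bit-exactly and geometry at full float precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

__all__ = [
    "LabelScheme",
    "LabeledVolume",
    "DEFAULT_SCHEME",
    "read_volume",
    "write_volume",
    "write_report",
    "REPORT_COLUMNS",
]

REQUIRED_CLASSES = ("background", "residual_metal", "degradation_layer", "bone", "gas")


@dataclass(frozen=True)
class LabelScheme:
    """Mapping from tissue-class names to integer label codes.

    The required classes are background (code 0), residual_metal,
    degradation_layer, bone and gas.  ``implant`` is a *derived* class:
    residual metal plus the attached corrosion-product layer.
    """

    codes: Mapping[str, int] = field(
        default_factory=lambda: {
            "background": 0,
            "residual_metal": 1,
            "degradation_layer": 2,
            "bone": 3,
            "gas": 4,
        }
    )

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_CLASSES if c not in self.codes]
        if missing:
            raise ValueError(f"label scheme missing required classes: {missing}")
        if self.codes["background"] != 0:
            raise ValueError("background code must be 0")
        values = list(self.codes.values())
        if len(set(values)) != len(values):
            raise ValueError("label codes must be unique")
        object.__setattr__(self, "codes", dict(self.codes))

    def __getitem__(self, name: str) -> int:
        return self.codes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.codes

    @property
    def implant_codes(self) -> tuple[int, int]:
        """Codes making up the derived 'implant' class (metal + layer)."""
        return (self.codes["residual_metal"], self.codes["degradation_layer"])

    def to_dict(self) -> dict[str, int]:
        return dict(self.codes)


DEFAULT_SCHEME = LabelScheme()


@dataclass
class LabeledVolume:
    """3D integer label grid with physical geometry.

    Parameters
    ----------
    labels
        3D integer array; one class code per voxel.
    spacing
        Voxel edge lengths per array axis, mm.  Strictly positive.
    origin
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    scheme
        The label scheme the codes refer to.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scheme: LabelScheme = field(default_factory=LabelScheme)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer) and self.labels.dtype != bool:
            raise ValueError(f"labels must have integer dtype, got {self.labels.dtype}")
        if self.labels.dtype == bool:
            self.labels = self.labels.astype(np.uint8)
        if min(self.labels.shape) < 1:
            raise ValueError("grid dimensions must be >= 1 on all axes")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have length 3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        present = np.unique(self.labels)
        known = set(self.scheme.codes.values())
        unknown = [int(c) for c in present if int(c) not in known]
        if unknown:
            raise ValueError(f"voxel codes {unknown} not in label scheme {self.scheme.to_dict()}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel, mm^3."""
        return float(np.prod(self.spacing))

    @property
    def physical_volume(self) -> float:
        """Physical volume of the whole grid, mm^3."""
        return float(self.labels.size) * self.voxel_volume

    def mask(self, *class_names: str) -> np.ndarray:
        """Boolean mask of the union of the named classes.

        The derived name ``"implant"`` expands to residual metal plus the
        degradation layer.
        """
        codes: list[int] = []
        for name in class_names:
            if name == "implant":
                codes.extend(self.scheme.implant_codes)
            elif name in self.scheme:
                codes.append(self.scheme[name])
            else:
                raise KeyError(f"unknown class {name!r}")
        return np.isin(self.labels, codes)

    def like(self, labels: np.ndarray) -> "LabeledVolume":
        """New volume with the same geometry and scheme but different labels."""
        return LabeledVolume(labels, self.spacing, self.origin, self.scheme)

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centers (open grids)."""
        axes = [
            self.origin[k] + self.spacing[k] * np.arange(self.shape[k], dtype=float)
            for k in range(3)
        ]
        return np.ix_(*axes)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _validate_mhd_header(path: Path) -> None:
    # ITK silently takes |spacing| of a negative header value; reject it
    # explicitly instead so corrupt geometry never passes unnoticed
    for line in path.read_text(errors="ignore").splitlines():
        key, _, value = line.partition("=")
        if key.strip() == "ElementSpacing":
            spacing = [float(v) for v in value.split()]
            if any(s <= 0 for s in spacing):
                raise ValueError(f"non-positive spacing in header of {path}: {spacing}")


def write_volume(vol: LabeledVolume, path: str | Path, format: str = "metaimage") -> None:
    """Write a labeled volume losslessly.

    ``format='tiff_stack'`` writes a multi-page uint8 TIFF plus a JSON
    sidecar ``<path>.json`` with spacing, origin and scheme.
    ``format='metaimage'`` writes MHD/RAW with geometry in the header and
    the scheme in a JSON sidecar.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if format == "tiff_stack":
        if vol.labels.min() < 0 or vol.labels.max() > 255:
            raise ValueError("tiff_stack format stores uint8 labels; codes must be in [0, 255]")
        tifffile.imwrite(path, vol.labels.astype(np.uint8))
        meta = {
            "spacing_mm": list(vol.spacing),
            "origin_mm": list(vol.origin),
            "scheme": vol.scheme.to_dict(),
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    elif format == "metaimage":
        img = sitk.GetImageFromArray(vol.labels.astype(np.uint8))
        # SimpleITK orders spacing/origin (x, y, z) = reversed array axes.
        img.SetSpacing(tuple(reversed(vol.spacing)))
        img.SetOrigin(tuple(reversed(vol.origin)))
        sitk.WriteImage(img, str(path))
        _sidecar_path(path).write_text(json.dumps({"scheme": vol.scheme.to_dict()}, indent=2, sort_keys=True))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_volume(path: str | Path, format: str | None = None) -> LabeledVolume:
    """Read a labeled volume written by :func:`write_volume`.

    The format is inferred from the extension when not given.  Missing
    spacing metadata is an error, never a silent default of 1 mm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "metaimage" if path.suffix.lower() in (".mhd", ".mha") else "tiff_stack"

    sidecar = _sidecar_path(path)
    if format == "tiff_stack":
        labels = tifffile.imread(path)
        if not np.issubdtype(np.asarray(labels).dtype, np.integer):
            raise ValueError(f"expected integer pixel type, got {np.asarray(labels).dtype}")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"missing spacing sidecar {sidecar}; TIFF stacks carry geometry in a JSON sidecar"
            )
        meta = json.loads(sidecar.read_text())
        if "spacing_mm" not in meta:
            raise ValueError(f"sidecar {sidecar} lacks 'spacing_mm'")
        scheme = LabelScheme(meta["scheme"]) if "scheme" in meta else LabelScheme()
        return LabeledVolume(
            labels,
            tuple(meta["spacing_mm"]),
            tuple(meta.get("origin_mm", (0.0, 0.0, 0.0))),
            scheme,
        )
    elif format == "metaimage":
        if path.suffix.lower() == ".mhd":
            _validate_mhd_header(path)
        img = sitk.ReadImage(str(path))
        labels = sitk.GetArrayFromImage(img)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError(f"expected integer pixel type, got {labels.dtype}")
        spacing = tuple(reversed(img.GetSpacing()))
        origin = tuple(reversed(img.GetOrigin()))
        if any(s <= 0 for s in spacing):
            raise ValueError(f"non-positive spacing in header: {spacing}")
        scheme = LabelScheme()
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if "scheme" in meta:
                scheme = LabelScheme(meta["scheme"])
        return LabeledVolume(labels, spacing, origin, scheme)
    raise ValueError(f"unknown format {format!r}")


REPORT_COLUMNS = ("sample", "t_weeks", "roi", "metric", "value", "units", "flags")


def write_report(rows: Iterable[Mapping[str, object]], path: str | Path) -> pd.DataFrame:
    """Write metric records as a deterministic CSV report.

    Rows are sorted by (sample, t_weeks, roi, metric) so repeated runs on
    identical inputs produce byte-identical files.  Returns the sorted
    frame for convenience.
    """
    df = pd.DataFrame(list(rows), columns=list(REPORT_COLUMNS))
    if len(df):
        df = df.sort_values(["sample", "t_weeks", "roi", "metric"], kind="stable").reset_index(drop=True)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    return df
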