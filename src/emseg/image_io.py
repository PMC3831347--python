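"""Volume / label-map I/O, tissue and run configuration loading.

All volumes are NIfTI on disk (float32 for intensities, int32 for labels)
and ``float64`` / integer numpy arrays in memory.  Grids are indexed
``(x, y, z)`` in the file's native axis order; spacing and origin are passed
through from the header without reorientation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import yaml

logger = logging.getLogger("emseg")

__all__ = [
    "Volume",
    "LabelVolume",
    "ImageSession",
    "RunConfig",
    "VolumeLoadError",
    "ConfigError",
    "read_volume",
    "write_volume",
    "read_label_volume",
    "write_label_volume",
    "load_tissue_config",
    "default_tissue_config",
    "phantom_tissue_config",
    "save_tissue_config",
]


class VolumeLoadError(ValueError):
    """Raised when a volume on disk cannot be loaded as a valid 3-D grid."""


class ConfigError(ValueError):
    """Raised when a tissue/run configuration file fails validation."""


def _as_triple(value, name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in value)
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class Volume:
    """A 3-D scalar grid with physical spacing (mm) and origin."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.isfinite(self.data).all():
            n = int(self.data.size - np.isfinite(self.data).sum())
            raise ValueError(f"{n} non-finite voxels in volume data")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def like(self, data: np.ndarray) -> "Volume":
        """New Volume with the same grid metadata and different data."""
        return Volume(data, spacing=self.spacing, origin=self.origin,
                      axis_order=self.axis_order)

    def same_grid(self, other: "Volume") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))


@dataclass
class LabelVolume:
    """A 3-D integer grid of class codes plus a code -> name table."""

    data: np.ndarray
    names: dict[int, str]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.array_equal(self.data, np.round(self.data)):
                raise ValueError("label data must be integer-valued")
            self.data = self.data.astype(np.int32)
        if self.data.ndim != 3:
            raise ValueError("label data must be 3-D")
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")
        present = set(np.unique(self.data).tolist())
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"label codes {sorted(missing)} missing from name table")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def mask(self, name: str) -> np.ndarray:
        codes = [c for c, n in self.names.items() if n == name]
        if not codes:
            raise KeyError(f"no label named {name!r}")
        return np.isin(self.data, codes)


@dataclass
class ImageSession:
    """A multi-modal, possibly repeated scan set.

    ``channels`` maps modality name -> list of repeat Volumes.  A *fused*
    session has exactly one volume per modality on a common grid.
    """

    modalities: list[str]
    channels: dict[str, list[Volume]]

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValueError("session needs at least one modality")
        for m in self.modalities:
            if m not in self.channels or not self.channels[m]:
                raise ValueError(f"modality {m!r} has no volumes")

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    def n_repeats(self, modality: str) -> int:
        return len(self.channels[modality])

    @property
    def reference(self) -> Volume:
        """First scan of the first modality — the session's reference grid."""
        return self.channels[self.modalities[0]][0]

    def is_fused(self) -> bool:
        return all(len(self.channels[m]) == 1 for m in self.modalities)

    def fused_volume(self, modality: str) -> Volume:
        reps = self.channels[modality]
        if len(reps) != 1:
            raise ValueError(f"modality {modality!r} not fused ({len(reps)} repeats)")
        return reps[0]

    def stack(self) -> np.ndarray:
        """(M, nx, ny, nz) array of fused per-modality intensities."""
        ref = self.reference
        vols = [self.fused_volume(m) for m in self.modalities]
        for v in vols:
            if v.shape != ref.shape:
                raise ValueError("fused session volumes must share one grid")
        return np.stack([v.data for v in vols], axis=0)

    @classmethod
    def from_stack(cls, modalities: Sequence[str], stack: np.ndarray,
                   spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> "ImageSession":
        stack = np.asarray(stack, dtype=np.float64)
        if stack.ndim != 4 or stack.shape[0] != len(modalities):
            raise ValueError("stack must be (M, nx, ny, nz) matching modalities")
        channels = {m: [Volume(stack[i], spacing=spacing, origin=origin)]
                    for i, m in enumerate(modalities)}
        return cls(list(modalities), channels)

    def with_stack(self, stack: np.ndarray) -> "ImageSession":
        ref = self.reference
        return ImageSession.from_stack(self.modalities, stack,
                                       spacing=ref.spacing, origin=ref.origin)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path) -> Volume:
    """Load a 3-D (or 4-D with trailing singleton) NIfTI volume."""
    path = Path(path)
    if not path.exists():
        raise VolumeLoadError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeLoadError(f"{path}: expected a 3-D payload, got shape {data.shape}")
    n_bad = int(data.size - np.isfinite(data).sum())
    if n_bad:
        raise VolumeLoadError(f"{path}: {n_bad} non-finite voxels")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume(data, spacing=tuple(float(z) for z in zooms), origin=origin)


def write_volume(vol: Volume, path) -> None:
    """Write a Volume to NIfTI (float32 on disk)."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_label_volume(path, names: Mapping[int, str] | None = None) -> LabelVolume:
    path = Path(path)
    if not path.exists():
        raise VolumeLoadError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeLoadError(f"{path}: expected a 3-D payload, got shape {data.shape}")
    data = np.round(data).astype(np.int32)
    if names is None:
        names = {int(c): str(int(c)) for c in np.unique(data)}
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return LabelVolume(data, dict(names), spacing=tuple(float(z) for z in zooms),
                       origin=origin)


def write_label_volume(labels: LabelVolume, path) -> None:
    img = nib.Nifti1Image(labels.data.astype(np.int32),
                          _affine(labels.spacing, labels.origin))
    img.header.set_zooms(labels.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Tissue configuration


def _parse_tissue_rows(doc: dict, source: str):
    from .priors import SUPER_CLASSES, TissueConfig

    if not isinstance(doc, dict) or "tissues" not in doc:
        raise ConfigError(f"{source}: expected a mapping with a 'tissues' list")
    modalities = [str(m) for m in doc.get("modalities", [])]
    rows = []
    seen: set[str] = set()
    for raw in doc["tissues"]:
        try:
            name = str(raw["name"])
            super_class = str(raw["super_class"])
            weight = float(raw["weight"])
            use_in_bias = bool(raw["bias"])
            quantiles = {str(m): (float(q[0]), float(q[1]))
                         for m, q in raw["quantiles"].items()}
        except (KeyError, TypeError, ValueError, IndexError) as exc:
            raise ConfigError(f"{source}: malformed tissue row {raw!r}: {exc}") from exc
        if name in seen:
            raise ConfigError(f"{source}: duplicate tissue name {name!r}")
        seen.add(name)
        if super_class not in SUPER_CLASSES:
            raise ConfigError(
                f"{source}: unknown super-class {super_class!r} for {name!r} "
                f"(expected one of {SUPER_CLASSES})")
        if weight <= 0:
            raise ConfigError(f"{source}: weight must be > 0 for {name!r}")
        for m, (lo, hi) in quantiles.items():
            if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
                raise ConfigError(
                    f"{source}: quantile bounds out of [0,1] for {name!r}/{m}")
            if lo > hi:
                raise ConfigError(
                    f"{source}: q_lower {lo} > q_upper {hi} for {name!r}/{m}")
        rows.append(TissueConfig(name=name, super_class=super_class, weight=weight,
                                 use_in_bias=use_in_bias, quantiles=quantiles))
    if not rows:
        raise ConfigError(f"{source}: no tissue rows")
    return modalities, rows


def load_tissue_config(path):
    """Load and validate a tissue configuration file.

    Returns the list of :class:`~emseg.priors.TissueConfig` rows in file order.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    _, rows = _parse_tissue_rows(doc, str(path))
    return rows


def save_tissue_config(rows, path, modalities: Sequence[str] | None = None) -> None:
    if modalities is None:
        modalities = sorted({m for r in rows for m in r.quantiles})
    doc = {
        "modalities": list(modalities),
        "tissues": [
            {"name": r.name, "super_class": r.super_class, "weight": r.weight,
             "bias": r.use_in_bias,
             "quantiles": {m: [lo, hi] for m, (lo, hi) in r.quantiles.items()}}
            for r in rows
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _packaged_config(filename: str):
    ref = importlib.resources.files("emseg.data").joinpath(filename)
    doc = yaml.safe_load(ref.read_text())
    _, rows = _parse_tissue_rows(doc, filename)
    return rows


def default_tissue_config():
    """The shipped 17-class extended tissue configuration."""
    return _packaged_config("tissue_config_17.yaml")


def phantom_tissue_config():
    """The shipped 4-class configuration matching the default phantom."""
    return _packaged_config("phantom_tissue_config.yaml")


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Pipeline knobs.  Everything here is logged with the run."""

    modalities: list[str] = field(default_factory=lambda: ["T1", "T2"])
    outer_max_iter: int = 5
    outer_tol: float = 1e-4
    em_max_iter: int = 30
    em_tol: float = 1e-5
    bias_order: int = 4
    quantile_mask_threshold: float = 0.01
    quantile_scope: str = "image"        # "image" or "head"
    use_context: bool = True
    bias_space: str = "log"              # "log" or "linear"
    registration_mode: str = "none"      # "none" | "affine" | "deformable"
    registration_metric: str = "msq"     # "msq" | "mi"
    intra_register: bool = False
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.outer_max_iter < 1 or self.em_max_iter < 1:
            raise ConfigError("iteration counts must be >= 1")
        if self.outer_tol <= 0 or self.em_tol <= 0:
            raise ConfigError("tolerances must be > 0")
        if self.quantile_scope not in ("image", "head"):
            raise ConfigError(f"quantile_scope must be 'image' or 'head', got {self.quantile_scope!r}")
        if self.bias_space not in ("log", "linear"):
            raise ConfigError(f"bias_space must be 'log' or 'linear', got {self.bias_space!r}")
        if self.registration_mode not in ("none", "affine", "deformable"):
            raise ConfigError(f"bad registration_mode {self.registration_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Hash of every knob that affects the computation (out_dir excluded,
        so identical runs to different directories share a digest)."""
        doc = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def setup_run_logging(out_dir=None, seed: int | None = None) -> logging.Logger:
    """Route the package logger to stderr and optionally a run-directory file."""
    lg = logging.getLogger("emseg")
    lg.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in lg.handlers):
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        lg.addHandler(h)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out_dir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
        lg.addHandler(fh)
    if seed is not None:
        lg.info("random seed: %d", seed)
    return lg
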