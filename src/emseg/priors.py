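"""Tissue configuration schema, prior atlases, weighted prior normalization,
super-class collapse and hard segmentation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # avoid an import cycle with image_io
    from .image_io import LabelVolume, Volume

logger = logging.getLogger("emseg")

#: The tissue hierarchy.  WM&GM holds deep-gray structures whose intensity
#: profile sits between white and gray matter; VB is venous blood; Background
#: covers air plus the "Not-" nuisance classes outside the brain.
SUPER_CLASSES = ("GM", "WM", "CSF", "WM&GM", "VB", "Background")

#: Evaluation mapping from super-class to the three canonical tissues.
#: Deep gray (WM&GM) counts as GM; VB and Background fall into "Other" and
#: are excluded from three-tissue agreement scores.
THREE_TISSUE_MAP = {
    "CSF": "Csf", "GM": "Gm", "WM": "Wm",
    "WM&GM": "Gm", "VB": "Other", "Background": "Other",
}
THREE_TISSUE_ORDER = ("Csf", "Gm", "Wm", "Other")


@dataclass
class TissueConfig:
    """One row of the tissue table: name, hierarchy, prior weight,
    bias-correction eligibility and per-modality quantile bounds."""

    name: str
    super_class: str
    weight: float = 1.0
    use_in_bias: bool = False
    quantiles: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.super_class not in SUPER_CLASSES:
            raise ValueError(f"unknown super-class {self.super_class!r}")
        if self.weight <= 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")
        for m, (lo, hi) in self.quantiles.items():
            if lo > hi:
                raise ValueError(f"q_lower > q_upper for {self.name!r}/{m}")

    def bounds_for(self, modality: str) -> tuple[float, float]:
        """Quantile bounds for a modality; absent modality means unconstrained."""
        return self.quantiles.get(modality, (0.0, 1.0))


@dataclass
class PriorAtlas:
    """Per-class prior probability maps plus their tissue configuration.

    ``maps`` lives on the atlas grid; ``warped`` (if set) is the
    registration-resampled copy on the subject grid.  ``template`` is an
    optional intensity image on the atlas grid used as the moving image for
    atlas-to-subject registration.
    """

    configs: list[TissueConfig]
    maps: np.ndarray                       # (K, nx, ny, nz), >= 0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    warped: np.ndarray | None = None
    template: "Volume | None" = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 4:
            raise ValueError("prior maps must be (K, nx, ny, nz)")
        if self.maps.shape[0] != len(self.configs):
            raise ValueError("class count mismatch between maps and configs")
        if len(self.configs) < 2:
            raise ValueError("need at least 2 tissue classes")
        if (self.maps < 0).any():
            raise ValueError("prior maps must be non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.configs)

    @property
    def class_names(self) -> list[str]:
        return [c.name for c in self.configs]

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.configs], dtype=np.float64)

    def index_of(self, name: str) -> int:
        return self.class_names.index(name)

    def air_index(self) -> int:
        """Deterministic fallback class for degenerate zero-prior voxels."""
        for i, c in enumerate(self.configs):
            if c.name.lower() == "air":
                return i
        for i, c in enumerate(self.configs):
            if c.super_class == "Background":
                return i
        return 0

    def active_maps(self, use_warped: bool) -> np.ndarray:
        if use_warped:
            if self.warped is None:
                raise ValueError("atlas has no warped priors")
            return self.warped
        return self.maps

    def head_mask(self, threshold: float = 0.01, use_warped: bool | None = None) -> np.ndarray:
        """Voxels where the summed non-Air prior exceeds ``threshold``."""
        if use_warped is None:
            use_warped = self.warped is not None
        maps = self.active_maps(use_warped)
        air = self.air_index()
        keep = [k for k in range(self.n_classes) if k != air]
        return maps[keep].sum(axis=0) > threshold


def normalize_priors(atlas: PriorAtlas, use_warped: bool = False) -> np.ndarray:
    """Weighted per-voxel prior normalization.

    p(l) = w_l * t_l / sum_j w_j * t_j over the raw (or warped) maps.
    Voxels where every weighted prior is zero are degenerate and get the Air
    class deterministically.
    """
    maps = atlas.active_maps(use_warped)
    w = atlas.weights[:, None, None, None]
    num = w * maps
    denom = num.sum(axis=0)
    degenerate = denom == 0
    out = np.empty_like(num)
    safe = np.where(degenerate, 1.0, denom)
    out[:] = num / safe
    if degenerate.any():
        air = atlas.air_index()
        out[:, degenerate] = 0.0
        out[air, degenerate] = 1.0
        logger.info("normalize_priors: %d degenerate zero-prior voxels -> %s",
                    int(degenerate.sum()), atlas.configs[air].name)
    return out


def collapse_to_superclass(stack: np.ndarray, atlas: PriorAtlas,
                           scheme: str = "six-class") -> tuple[np.ndarray, list[str]]:
    """Sum member-class probabilities into super-classes.

    ``scheme='six-class'`` groups by the hierarchy directly; ``'three-tissue'``
    maps WM&GM into GM and pools VB/Background into "Other" so per-voxel
    probability mass is conserved.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.shape[0] != atlas.n_classes:
        raise ValueError("stack class count does not match atlas")
    if scheme == "six-class":
        groups = [sc for sc in SUPER_CLASSES
                  if any(c.super_class == sc for c in atlas.configs)]
        member = {sc: [i for i, c in enumerate(atlas.configs) if c.super_class == sc]
                  for sc in groups}
    elif scheme == "three-tissue":
        for needed in ("CSF", "GM", "WM"):
            if not any(c.super_class == needed for c in atlas.configs):
                raise ValueError(f"three-tissue scheme needs super-class {needed}")
        member = {name: [] for name in THREE_TISSUE_ORDER}
        for i, c in enumerate(atlas.configs):
            member[THREE_TISSUE_MAP[c.super_class]].append(i)
        groups = [g for g in THREE_TISSUE_ORDER if member[g]]
        member = {g: member[g] for g in groups}
    else:
        raise ValueError(f"unknown collapse scheme {scheme!r}")
    out = np.stack([stack[idx].sum(axis=0) for idx in member.values()], axis=0)
    return out, list(groups)


def hard_segmentation(stack: np.ndarray, names: Sequence[str] | None = None,
                      spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    """Arg-max class per voxel; ties break to the lowest class index."""
    from .image_io import LabelVolume

    stack = np.asarray(stack)
    codes = np.argmax(stack, axis=0).astype(np.int32)
    if names is None:
        names = [str(i) for i in range(stack.shape[0])]
    table = {i: str(n) for i, n in enumerate(names)}
    return LabelVolume(codes, table, spacing=spacing, origin=origin)
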