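"""Synthetic multi-modal phantom sessions with ground truth.

The geometry is analytic — nested ellipsoids for air / CSF shell / GM shell /
WM core plus optional deep-gray blobs — rendered as piecewise-constant
per-modality intensities, corrupted by a seeded smooth multiplicative bias
field of exact peak amplitude ``rf`` percent and additive Gaussian noise with
standard deviation ``pn`` percent of the WM mean, in that order.  Imperfect
prior atlases are simulated by translating and blurring the one-hot ground
truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image_io import ImageSession, LabelVolume, Volume, phantom_tissue_config
from .priors import PriorAtlas, TissueConfig

logger = logging.getLogger("emseg")

__all__ = ["PhantomSpec", "PhantomSession", "generate_labels",
           "render_modalities", "apply_bias", "add_noise", "make_prior_atlas",
           "make_session"]

#: default per-class, per-modality mean intensities (arbitrary units)
DEFAULT_MEANS = {
    "Air": {"T1": 4.0, "T2": 4.0},
    "Csf": {"T1": 30.0, "T2": 120.0},
    "Gm": {"T1": 80.0, "T2": 90.0},
    "Wm": {"T1": 120.0, "T2": 55.0},
}

#: default ellipsoid radii as fractions of the grid shape (outer boundary of
#: each shell); classes are carved outside-in
DEFAULT_RADII = {"Csf": 0.42, "Gm": 0.34, "Wm": 0.24}


@dataclass
class PhantomSpec:
    """Everything needed to build a deterministic synthetic session."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modalities: list[str] = field(default_factory=lambda: ["T1", "T2"])
    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_MEANS.items()})
    blobs: list[tuple[str, tuple[float, float, float], float]] = field(
        default_factory=list)   # (class name, center offset frac, radius frac)
    pn: float = 0.0             # noise SD as percent of the WM mean
    rf: float = 0.0             # peak percent deviation of the bias field
    prior_blur: float = 0.0     # voxels
    prior_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pn < 0 or self.rf < 0:
            raise ValueError("pn and rf must be >= 0")
        if self.prior_blur < 0:
            raise ValueError("prior blur must be >= 0")
        if self.n_repeats < 1:
            raise ValueError("need at least one repeat")
        for cls, table in self.means.items():
            for m, v in table.items():
                if v <= 0:
                    raise ValueError(f"mean intensity must be > 0 ({cls}/{m})")

    @property
    def class_names(self) -> list[str]:
        names = ["Air"] + list(self.radii)
        names += [b[0] for b in self.blobs if b[0] not in names]
        return names


@dataclass
class PhantomSession:
    """A generated session bundled with every piece of ground truth."""

    spec: PhantomSpec
    session: ImageSession
    clean: ImageSession
    labels: LabelVolume
    atlas: PriorAtlas
    bias_fields: dict[str, Volume]   # true multiplicative fields per modality


def _ellipsoid_mask(shape, spacing, center_frac, radii_frac) -> np.ndarray:
    """Boolean mask of voxels inside an axis-aligned ellipsoid.

    Centers and radii are fractions of the grid extent, so geometry scales
    with resolution.
    """
    grids = np.indices(shape).astype(np.float64)
    acc = np.zeros(shape)
    for ax in range(3):
        c = center_frac[ax] * (shape[ax] - 1)
        r = radii_frac[ax] * shape[ax]
        acc += ((grids[ax] - c) / r) ** 2
    return acc <= 1.0


def generate_labels(spec: PhantomSpec) -> LabelVolume:
    """Deterministic nested-ellipsoid label map; every class must be nonempty."""
    shape = tuple(spec.shape)
    labels = np.zeros(shape, dtype=np.int32)
    names = {0: "Air"}
    code = 1
    center = (0.5, 0.5, 0.5)
    for cls, radius in spec.radii.items():
        if radius > 0:
            mask = _ellipsoid_mask(shape, spec.spacing, center, (radius,) * 3)
        else:
            mask = np.zeros(shape, dtype=bool)
        labels[mask] = code
        names[code] = cls
        code += 1
    for cls, off, radius in spec.blobs:
        c = tuple(0.5 + o for o in off)
        mask = _ellipsoid_mask(shape, spec.spacing, c, (radius,) * 3)
        labels[mask] = code
        names[code] = cls
        code += 1
    for c, cls in names.items():
        if not (labels == c).any():
            raise ValueError(f"class {cls} empty")
    return LabelVolume(labels, names, spacing=spec.spacing)


def render_modalities(labels: LabelVolume, spec: PhantomSpec) -> ImageSession:
    """Noise-free, bias-free piecewise-constant rendering (one repeat each)."""
    codes = sorted(labels.names)
    stacks = []
    for m in spec.modalities:
        img = np.zeros(labels.shape, dtype=np.float64)
        for c in codes:
            cls = labels.names[c]
            if cls not in spec.means or m not in spec.means[cls]:
                raise ValueError(f"no mean intensity for class {cls!r}, modality {m!r}")
            img[labels.data == c] = spec.means[cls][m]
        stacks.append(img)
    return ImageSession.from_stack(spec.modalities, np.stack(stacks, axis=0),
                                   spacing=labels.spacing, origin=labels.origin)


def apply_bias(vol: Volume, rf: float, seed: int) -> tuple[Volume, Volume]:
    """Multiply by a seeded smooth field with max |field - 1| = rf/100 over
    the foreground.  Returns (biased volume, true field).

    Foreground = voxels brighter than 5% of the maximum (the head, excluding
    dim air); the field component is mean-centered over the foreground so the
    corrupting field averages to ~1 there, which keeps the absolute intensity
    scale of the phantom meaningful after correction.
    """
    if rf < 0:
        raise ValueError("rf must be >= 0")
    if rf == 0:
        ones = vol.like(np.ones(vol.shape))
        return vol.like(vol.data.copy()), ones
    rng = np.random.default_rng(seed)
    shape = vol.shape
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1) for n in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    # low-frequency components: linear + quadratic monomials + one cosine per axis
    comps = [X, Y, Z, X * Y, Y * Z, X * Z, X**2, Y**2, Z**2,
             np.cos(np.pi * X), np.cos(np.pi * Y), np.cos(np.pi * Z)]
    coeff = rng.standard_normal(len(comps))
    raw = sum(c * comp for c, comp in zip(coeff, comps))
    fg = vol.data > 0.05 * vol.data.max()
    if not fg.any():
        fg = np.ones(shape, dtype=bool)
    g = raw - raw[fg].mean()
    peak = np.abs(g[fg]).max()
    if peak == 0:
        raise ValueError("degenerate bias component draw")
    fld = 1.0 + (rf / 100.0) * g / peak
    return vol.like(vol.data * fld), vol.like(fld)


def add_noise(vol: Volume, pn: float, reference_mean: float, seed: int) -> Volume:
    """Zero-mean Gaussian noise with SD = pn/100 * reference_mean, seeded."""
    if pn < 0:
        raise ValueError("pn must be >= 0")
    if pn == 0:
        return vol.like(vol.data.copy())
    rng = np.random.default_rng(seed)
    sd = pn / 100.0 * reference_mean
    return vol.like(vol.data + rng.normal(0.0, sd, size=vol.shape))


def make_prior_atlas(labels: LabelVolume, blur: float = 0.0,
                     offset: Sequence[float] = (0.0, 0.0, 0.0),
                     configs: list[TissueConfig] | None = None,
                     template: Volume | None = None) -> PriorAtlas:
    """One-hot priors from ground truth, degraded by translation + blur.

    The per-voxel sum is renormalized to exactly 1; voxels losing all prior
    support (shifted-in borders) become Air.
    """
    if blur < 0:
        raise ValueError("blur must be >= 0")
    if configs is None:
        configs = phantom_tissue_config()
    by_name = {c.name: i for i, c in enumerate(configs)}
    present = [labels.names[c] for c in sorted(labels.names)]
    missing = [n for n in present if n not in by_name]
    if missing:
        raise ValueError(f"no tissue config for classes {missing}")
    K = len(configs)
    maps = np.zeros((K,) + labels.shape)
    for code in sorted(labels.names):
        k = by_name[labels.names[code]]
        maps[k] += labels.data == code
    offset = tuple(float(o) for o in offset)
    if any(o != 0 for o in offset):
        for k in range(K):
            maps[k] = ndimage.shift(maps[k], offset, order=1, mode="constant",
                                    cval=0.0)
        if template is not None:
            template = template.like(
                ndimage.shift(template.data, offset, order=1, mode="nearest"))
    if blur > 0:
        for k in range(K):
            maps[k] = ndimage.gaussian_filter(maps[k], blur)
        if template is not None:
            template = template.like(ndimage.gaussian_filter(template.data, blur))
    np.clip(maps, 0.0, None, out=maps)
    total = maps.sum(axis=0)
    degenerate = total == 0
    safe = np.where(degenerate, 1.0, total)
    maps /= safe
    if degenerate.any():
        air = next((i for i, c in enumerate(configs) if c.name.lower() == "air"), 0)
        maps[:, degenerate] = 0.0
        maps[air, degenerate] = 1.0
    return PriorAtlas(configs=configs, maps=maps, spacing=labels.spacing,
                      origin=labels.origin, template=template)


def _child_seed(base: int, *salt: int) -> int:
    ss = np.random.SeedSequence([base, *salt])
    return int(ss.generate_state(1)[0])


def make_session(spec: PhantomSpec,
                 configs: list[TissueConfig] | None = None) -> PhantomSession:
    """Full generator: labels -> clean rendering -> bias -> noise -> atlas.

    Repeats of one modality share the bias field (same coil) but draw
    independent noise.  Everything is a pure function of ``spec``.
    """
    labels = generate_labels(spec)
    clean = render_modalities(labels, spec)
    bias_fields: dict[str, Volume] = {}
    channels: dict[str, list[Volume]] = {}
    for j, m in enumerate(spec.modalities):
        base = clean.fused_volume(m)
        biased, fld = apply_bias(base, spec.rf, _child_seed(spec.seed, 1, j))
        bias_fields[m] = fld
        ref_mean = spec.means["Wm"][m]
        reps = [add_noise(biased, spec.pn, ref_mean, _child_seed(spec.seed, 2, j, r))
                for r in range(spec.n_repeats)]
        channels[m] = reps
    session = ImageSession(list(spec.modalities), channels)
    tmpl = clean.fused_volume(spec.modalities[0])
    atlas = make_prior_atlas(labels, blur=spec.prior_blur,
                             offset=spec.prior_offset, configs=configs,
                             template=tmpl.like(tmpl.data.copy()))
    return PhantomSession(spec=spec, session=session, clean=clean,
                          labels=labels, atlas=atlas, bias_fields=bias_fields)
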