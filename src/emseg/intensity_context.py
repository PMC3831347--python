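"""Region-specific intensity-context priors.

Each tissue carries per-modality quantile bounds; the bounds are mapped to
intensity thresholds on the current images, turned into a per-tissue binary
indicator (a conjunction across modalities, open intervals), and used to
mask and renormalize the spatial prior stack.  Voxels where every masked
prior vanishes fall back to the unconstrained prior (counted, logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image_io import ImageSession, Volume
from .priors import PriorAtlas

logger = logging.getLogger("emseg")

__all__ = ["ContextBounds", "quantile_threshold", "compute_bounds",
           "indicator", "indicator_stack", "constrain_priors"]


@dataclass
class ContextBounds:
    """Per-tissue, per-modality intensity intervals derived from quantiles."""

    tissues: list[str]
    modalities: list[str]
    lower: np.ndarray  # (K, M)
    upper: np.ndarray  # (K, M)

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=np.float64)
        self.upper = np.asarray(self.upper, dtype=np.float64)
        expected = (len(self.tissues), len(self.modalities))
        if self.lower.shape != expected or self.upper.shape != expected:
            raise ValueError("bounds arrays must be (n_tissues, n_modalities)")
        if (self.lower > self.upper).any():
            raise ValueError("lower bound exceeds upper bound")

    def interval(self, tissue: str, modality: str) -> tuple[float, float]:
        i = self.tissues.index(tissue)
        j = self.modalities.index(modality)
        return float(self.lower[i, j]), float(self.upper[i, j])

    def as_table(self) -> list[dict]:
        return [
            {"tissue": t, "modality": m,
             "lower": float(self.lower[i, j]), "upper": float(self.upper[i, j])}
            for i, t in enumerate(self.tissues)
            for j, m in enumerate(self.modalities)
        ]


def quantile_threshold(vol, mask: np.ndarray, q: float) -> float:
    """Empirical q-quantile (linear interpolation) of masked intensities."""
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty quantile mask")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile must be in [0,1], got {q}")
    return float(np.quantile(data[mask], q))


def compute_bounds(session: ImageSession, atlas: PriorAtlas,
                   mask: np.ndarray) -> ContextBounds:
    """Intensity bounds for every (tissue, modality) from the quantile table."""
    tissues = atlas.class_names
    modalities = list(session.modalities)
    K, M = len(tissues), len(modalities)
    lower = np.empty((K, M))
    upper = np.empty((K, M))
    for j, m in enumerate(modalities):
        data = session.fused_volume(m).data
        for i, cfg in enumerate(atlas.configs):
            q_lo, q_hi = cfg.bounds_for(m)
            lower[i, j] = quantile_threshold(data, mask, q_lo)
            upper[i, j] = quantile_threshold(data, mask, q_hi)
    return ContextBounds(tissues=tissues, modalities=modalities,
                         lower=lower, upper=upper)


def indicator(session: ImageSession, bounds: ContextBounds, tissue: str) -> np.ndarray:
    """Binary support map for one tissue: 1 iff the voxel's intensity lies
    strictly inside the (lower, upper) interval for every modality."""
    i = bounds.tissues.index(tissue)
    out = np.ones(session.reference.shape, dtype=bool)
    for j, m in enumerate(bounds.modalities):
        data = session.fused_volume(m).data
        out &= (data > bounds.lower[i, j]) & (data < bounds.upper[i, j])
    return out.astype(np.uint8)


def indicator_stack(session: ImageSession, bounds: ContextBounds) -> np.ndarray:
    """(K, nx, ny, nz) stack of per-tissue indicators."""
    return np.stack([indicator(session, bounds, t) for t in bounds.tissues], axis=0)


def constrain_priors(stack: np.ndarray, indicators: np.ndarray
                     ) -> tuple[np.ndarray, int]:
    """Mask the prior stack by the indicators and renormalize per voxel.

    Voxels where every masked prior is zero keep the unconstrained prior
    (the constraint is conservative, never fatal).  Returns the constrained
    stack and the number of fallback voxels.
    """
    stack = np.asarray(stack, dtype=np.float64)
    indicators = np.asarray(indicators)
    if stack.shape != indicators.shape:
        raise ValueError("prior stack and indicator stack shapes differ")
    masked = stack * indicators
    denom = masked.sum(axis=0)
    fallback = denom == 0
    safe = np.where(fallback, 1.0, denom)
    out = masked / safe
    if fallback.any():
        out[:, fallback] = stack[:, fallback]
    untouched = (indicators != 0).all(axis=0)  # no mass removed: exact no-op
    if untouched.any():
        out[:, untouched] = stack[:, untouched]
    n_fallback = int(fallback.sum())
    if n_fallback:
        logger.info("constrain_priors: %d voxels fell back to unconstrained priors",
                    n_fallback)
    return out, n_fallback
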