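"""Smooth intensity-inhomogeneity (bias) field estimation and removal.

The field is additive in a working intensity space — by default the log
domain, which turns physically multiplicative scanner bias into an additive
component — and is modeled per modality as a low-order 3-D polynomial fitted
by precision-weighted least squares to the residual between the observed
intensity and the posterior-blended class mean.  Only tissues flagged
bias-eligible contribute weight.  The fitted field has zero mean over the
mask (identifiability) and extrapolates smoothly outside it.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .em_core import MixtureState
from .image_io import ImageSession, Volume
from .priors import PriorAtlas

logger = logging.getLogger("emseg")

__all__ = ["BiasField", "BiasEstimationError", "polynomial_basis",
           "estimate_bias", "correct", "to_working_space", "from_working_space"]


class BiasEstimationError(RuntimeError):
    pass


@dataclass
class BiasField:
    """Per-modality polynomial bias fields in a working intensity space."""

    modalities: list[str]
    coefficients: dict[str, np.ndarray]
    fields: dict[str, np.ndarray]        # voxelized Phi per modality
    order: int
    space: str = "log"

    def __post_init__(self) -> None:
        for m in self.modalities:
            if m not in self.fields:
                raise ValueError(f"missing field for modality {m!r}")
            if not np.isfinite(self.fields[m]).all():
                raise ValueError(f"non-finite bias field for modality {m!r}")


def _exponents(order: int) -> list[tuple[int, int, int]]:
    return [e for e in itertools.product(range(order + 1), repeat=3)
            if sum(e) <= order]


def polynomial_basis(shape, order: int) -> np.ndarray:
    """(B, N) monomial design over the full grid, coordinates scaled to [-1, 1].

    Total degree <= order; the constant term comes first.
    """
    axes = []
    for n in shape:
        if n > 1:
            axes.append(np.linspace(-1.0, 1.0, n))
        else:
            axes.append(np.zeros(1))
    X, Yc, Z = np.meshgrid(*axes, indexing="ij")
    coords = [X.ravel(), Yc.ravel(), Z.ravel()]
    exps = sorted(_exponents(order), key=lambda e: (sum(e), e))
    rows = [coords[0] ** i * coords[1] ** j * coords[2] ** k for i, j, k in exps]
    return np.stack(rows, axis=0)


def estimate_bias(session, state: MixtureState, posteriors: np.ndarray,
                  atlas: PriorAtlas, order: int = 4,
                  mask: np.ndarray | None = None, space: str = "log",
                  mean_mask: np.ndarray | None = None) -> BiasField:
    """Weighted least-squares polynomial fit of the residual field per modality.

    Residual r_i = y_i - blended bias-eligible class mean; weight w_i = sum
    over bias-eligible tissues of p_il / sigma^2_l (per-modality marginal
    variance).  The fitted field has zero mean over ``mean_mask`` (defaults
    to the fit mask); passing the full grid instead pins the global intensity
    scale better when the corrupting field averages to one over the volume.
    """
    if isinstance(session, ImageSession):
        Y = session.stack()
        modalities = list(session.modalities)
    else:
        Y = np.asarray(session, dtype=np.float64)
        if Y.ndim == 3:
            Y = Y[None]
        modalities = [str(i) for i in range(Y.shape[0])]
    grid = Y.shape[1:]
    N = int(np.prod(grid))
    K = posteriors.shape[0]
    P = np.asarray(posteriors, dtype=np.float64).reshape(K, N)
    if mask is None:
        mask_f = np.ones(N, dtype=bool)
    else:
        mask_f = np.asarray(mask, dtype=bool).reshape(N)
        if not mask_f.any():
            raise BiasEstimationError("empty bias mask")

    eligible = np.array([c.use_in_bias for c in atlas.configs], dtype=bool)
    if not eligible.any():
        raise BiasEstimationError("no tissue has use_in_bias = true")

    if mean_mask is None:
        mean_f = mask_f
    else:
        mean_f = np.asarray(mean_mask, dtype=bool).reshape(N)

    A = polynomial_basis(grid, order)            # (B, N)
    Am = A[:, mask_f].T                          # (n_mask, B)

    coefficients: dict[str, np.ndarray] = {}
    fields: dict[str, np.ndarray] = {}
    elig_mass = P[eligible].sum(axis=0)
    for j, m in enumerate(modalities):
        y = Y[j].reshape(N)
        # blend over bias-eligible tissues only, so flag-false classes can
        # never influence the fit (their weight is zero anyway)
        blended = np.where(elig_mass > 0,
                           (state.means[eligible, j] @ P[eligible])
                           / np.maximum(elig_mass, np.finfo(float).tiny),
                           y)
        resid = y - blended
        var = np.maximum(state.covariances[:, j, j], np.finfo(float).tiny)
        w = (P[eligible] / var[eligible, None]).sum(axis=0)
        w = w * mask_f
        wsum = w.sum()
        if wsum <= 0:
            raise BiasEstimationError(
                f"no bias-eligible posterior mass for modality {m!r}")
        sw = np.sqrt(w[mask_f])
        coef, *_ = np.linalg.lstsq(Am * sw[:, None], resid[mask_f] * sw,
                                   rcond=None)
        phi = coef @ A                           # (N,)
        phi = phi - phi[mean_f].mean()           # identifiability
        coefficients[m] = coef
        fields[m] = phi.reshape(grid)
    return BiasField(modalities=modalities, coefficients=coefficients,
                     fields=fields, order=order, space=space)


def correct(session, bias: BiasField):
    """Subtract the per-modality field in working space."""
    if isinstance(session, ImageSession):
        stack = session.stack()
        out = np.stack([stack[j] - bias.fields[m]
                        for j, m in enumerate(session.modalities)], axis=0)
        return session.with_stack(out)
    stack = np.asarray(session, dtype=np.float64)
    if stack.ndim == 3:
        stack = stack[None]
    return np.stack([stack[j] - bias.fields[m]
                     for j, m in enumerate(bias.modalities)], axis=0)


def _default_eps(data: np.ndarray, mask: np.ndarray | None) -> float:
    ref = data[mask] if mask is not None else data
    med = float(np.median(np.abs(ref)))
    if med <= 0:
        med = float(np.abs(ref).max()) or 1.0
    return 1e-3 * med


def to_working_space(vol: Volume, mask: np.ndarray | None = None,
                     eps: float | None = None) -> tuple[Volume, float]:
    """Log transform with a positive offset: u = log(max(v, 0) + eps).

    Returns the transformed volume and the offset actually used so the
    transform is exactly invertible.
    """
    if eps is None:
        eps = _default_eps(vol.data, mask)
    if eps <= 0:
        raise ValueError("offset must be positive")
    u = np.log(np.maximum(vol.data, 0.0) + eps)
    return vol.like(u), eps


def from_working_space(vol: Volume, eps: float) -> Volume:
    """Exact inverse of :func:`to_working_space` for non-negative inputs."""
    return vol.like(np.exp(vol.data) - eps)
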