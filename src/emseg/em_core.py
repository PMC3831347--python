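"""Multi-modal Gaussian-mixture EM engine.

The E-step multiplies a full-covariance multivariate normal likelihood per
class with the (constrained, spatially varying) prior stack and renormalizes
per voxel; the M-step re-estimates posterior-weighted means and covariances.
Mixing is handled entirely by the spatial priors — there are no free global
weights.  All density work happens in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .image_io import ImageSession

logger = logging.getLogger("emseg")

__all__ = ["MixtureState", "EMError", "e_step", "m_step", "run_em",
           "initialize_state"]

#: Relative per-class posterior-mass threshold below which a class is
#: considered collapsed and keeps its previous parameters.
MASS_EPS_REL = 1e-8


class EMError(RuntimeError):
    pass


@dataclass
class MixtureState:
    """Per-class multivariate Gaussian parameters."""

    means: np.ndarray                 # (K, M)
    covariances: np.ndarray           # (K, M, M), symmetric PD
    class_names: list[str] = field(default_factory=list)
    collapsed: np.ndarray | None = None  # (K,) bool

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.covariances = np.asarray(self.covariances, dtype=np.float64)
        if self.means.ndim != 2:
            raise ValueError("means must be (K, M)")
        K, M = self.means.shape
        if self.covariances.shape != (K, M, M):
            raise ValueError("covariances must be (K, M, M)")
        if not np.isfinite(self.means).all() or not np.isfinite(self.covariances).all():
            raise ValueError("non-finite mixture parameters")
        if not self.class_names:
            self.class_names = [str(i) for i in range(K)]
        if self.collapsed is None:
            self.collapsed = np.zeros(K, dtype=bool)

    @property
    def n_classes(self) -> int:
        return self.means.shape[0]

    @property
    def n_modalities(self) -> int:
        return self.means.shape[1]


def _session_stack(session) -> np.ndarray:
    if isinstance(session, ImageSession):
        return session.stack()
    arr = np.asarray(session, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError("session must be an ImageSession or an (M, nx, ny, nz) array")
    return arr


def _class_log_pdf(Y: np.ndarray, mean: np.ndarray, cov: np.ndarray,
                   name: str) -> np.ndarray:
    """log N(y; mean, cov) for flattened observations Y (N, M)."""
    M = Y.shape[1]
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise EMError(f"singular covariance for class {name!r}") from exc
    diff = Y - mean
    sol = np.linalg.solve(chol, diff.T)          # (M, N)
    maha = np.einsum("mn,mn->n", sol, sol)
    log_det = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (maha + log_det + M * np.log(2.0 * np.pi))


def e_step(session, state: MixtureState, priors: np.ndarray
           ) -> tuple[np.ndarray, float]:
    """Posterior stack and total log-likelihood for the current parameters.

    priors is a (K, nx, ny, nz) per-voxel probability stack (each voxel a
    simplex).  Zero prior forces zero posterior regardless of likelihood.
    """
    Y = _session_stack(session)
    M = Y.shape[0]
    grid = Y.shape[1:]
    N = int(np.prod(grid))
    K = state.n_classes
    priors = np.asarray(priors, dtype=np.float64)
    if priors.shape != (K,) + grid:
        raise ValueError(f"prior stack shape {priors.shape} != {(K,) + grid}")
    if state.n_modalities != M:
        raise ValueError("state modality count does not match session")

    Yf = Y.reshape(M, N).T                        # (N, M)
    log_joint = np.empty((K, N))
    with np.errstate(divide="ignore"):
        log_prior = np.log(priors.reshape(K, N))
    for k in range(K):
        log_joint[k] = _class_log_pdf(Yf, state.means[k], state.covariances[k],
                                      state.class_names[k]) + log_prior[k]
    log_norm = logsumexp(log_joint, axis=0)       # (N,)
    post = np.exp(log_joint - log_norm)
    ll = float(log_norm.sum())
    return post.reshape((K,) + grid), ll


def m_step(session, posteriors: np.ndarray,
           previous: MixtureState | None = None,
           class_names: list[str] | None = None) -> MixtureState:
    """Posterior-weighted mean vectors and regularized covariances.

    Classes with vanishing posterior mass are flagged collapsed and retain
    their previous parameters (or global statistics when initializing).
    """
    Y = _session_stack(session)
    M = Y.shape[0]
    N = int(np.prod(Y.shape[1:]))
    posteriors = np.asarray(posteriors, dtype=np.float64)
    K = posteriors.shape[0]
    P = posteriors.reshape(K, N)
    Yf = Y.reshape(M, N).T

    if class_names is None:
        class_names = (previous.class_names if previous is not None
                       else [str(i) for i in range(K)])

    data_var = float(np.mean(np.var(Yf, axis=0)))
    delta = 1e-6 * max(data_var, np.finfo(float).tiny)
    reg = delta * np.eye(M)

    global_mean = Yf.mean(axis=0)
    global_cov = np.cov(Yf.T, bias=True).reshape(M, M) + reg

    mass = P.sum(axis=1)
    eps = MASS_EPS_REL * N
    means = np.empty((K, M))
    covs = np.empty((K, M, M))
    collapsed = np.zeros(K, dtype=bool)
    for k in range(K):
        if mass[k] <= eps:
            collapsed[k] = True
            if previous is not None:
                means[k] = previous.means[k]
                covs[k] = previous.covariances[k]
            else:
                means[k] = global_mean
                covs[k] = global_cov
            logger.warning("m_step: class %s collapsed (mass %.3g); parameters retained",
                           class_names[k], mass[k])
            continue
        mu = (P[k] @ Yf) / mass[k]
        diff = Yf - mu
        cov = (diff.T * P[k]) @ diff / mass[k] + reg
        means[k] = mu
        covs[k] = 0.5 * (cov + cov.T)
    return MixtureState(means=means, covariances=covs,
                        class_names=list(class_names), collapsed=collapsed)


def initialize_state(session, priors: np.ndarray,
                     class_names: list[str] | None = None) -> MixtureState:
    """One M-step treating the (constrained) prior stack as responsibilities."""
    return m_step(session, priors, previous=None, class_names=class_names)


def run_em(session, state: MixtureState, priors: np.ndarray,
           max_iter: int = 30, tol: float = 1e-5
           ) -> tuple[MixtureState, np.ndarray, list[float]]:
    """Alternate E/M until the relative log-likelihood change drops below
    ``tol`` or ``max_iter`` is reached.  Returns (state, posteriors, trace)."""
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    trace: list[float] = []
    post = None
    for it in range(max_iter):
        post, ll = e_step(session, state, priors)
        trace.append(ll)
        if len(trace) > 1:
            prev = trace[-2]
            rel = abs(ll - prev) / max(abs(prev), np.finfo(float).tiny)
            if rel < tol:
                break
        state = m_step(session, post, previous=state)
    logger.info("EM: %d iterations, final log-likelihood %.6g", len(trace),
                trace[-1])
    return state, post, trace
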