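"""Deliberately naive reference implementations used as oracles.

Everything here is written as literal per-voxel loops, independent of the
package's vectorized code paths.
"""

import numpy as np


def naive_e_step(Y, means, covs, priors):
    """Per-voxel posterior and total log-likelihood by direct evaluation.

    Y: (M, nx, ny, nz); means: (K, M); covs: (K, M, M); priors: (K, nx, ny, nz).
    """
    M = Y.shape[0]
    grid = Y.shape[1:]
    K = means.shape[0]
    post = np.zeros((K,) + grid)
    ll = 0.0
    for ix in np.ndindex(grid):
        y = np.array([Y[(m,) + ix] for m in range(M)])
        dens = np.zeros(K)
        for k in range(K):
            d = y - means[k]
            cov = covs[k]
            inv = np.linalg.inv(cov)
            norm = 1.0 / np.sqrt(((2 * np.pi) ** M) * np.linalg.det(cov))
            dens[k] = norm * np.exp(-0.5 * d @ inv @ d) * priors[(k,) + ix]
        total = dens.sum()
        ll += np.log(total)
        for k in range(K):
            post[(k,) + ix] = dens[k] / total
    return post, ll


def naive_m_step(Y, post):
    """Posterior-weighted means and (unregularized) covariances per class."""
    M = Y.shape[0]
    grid = Y.shape[1:]
    K = post.shape[0]
    means = np.zeros((K, M))
    covs = np.zeros((K, M, M))
    for k in range(K):
        mass = 0.0
        mu = np.zeros(M)
        for ix in np.ndindex(grid):
            p = post[(k,) + ix]
            y = np.array([Y[(m,) + ix] for m in range(M)])
            mass += p
            mu += p * y
        mu /= mass
        cov = np.zeros((M, M))
        for ix in np.ndindex(grid):
            p = post[(k,) + ix]
            y = np.array([Y[(m,) + ix] for m in range(M)])
            d = y - mu
            cov += p * np.outer(d, d)
        means[k] = mu
        covs[k] = cov / mass
    return means, covs


def naive_constrain(stack, indicators):
    """Literal per-voxel evaluation of the constrained-prior formula."""
    K = stack.shape[0]
    grid = stack.shape[1:]
    out = np.zeros_like(stack)
    for ix in np.ndindex(grid):
        num = np.array([stack[(k,) + ix] * indicators[(k,) + ix] for k in range(K)])
        s = num.sum()
        if s == 0:
            for k in range(K):
                out[(k,) + ix] = stack[(k,) + ix]
        else:
            for k in range(K):
                out[(k,) + ix] = num[k] / s
    return out


def naive_mhd(bd_a, bd_b, spacing, variant="max"):
    """All-pairs nearest-boundary mean distances from boundary voxel lists."""
    sp = np.asarray(spacing)
    pa = np.argwhere(bd_a) * sp
    pb = np.argwhere(bd_b) * sp
    d_ab = np.mean([np.min(np.linalg.norm(pb - p, axis=1)) for p in pa])
    d_ba = np.mean([np.min(np.linalg.norm(pa - p, axis=1)) for p in pb])
    if variant == "max":
        return max(d_ab, d_ba)
    return 0.5 * (d_ab + d_ba)


def naive_boundary(mask):
    """Face-adjacency boundary with out-of-grid treated as background."""
    out = np.zeros_like(mask, dtype=bool)
    shape = mask.shape
    for ix in np.ndindex(shape):
        if not mask[ix]:
            continue
        for ax in range(3):
            for step in (-1, 1):
                j = list(ix)
                j[ax] += step
                if not (0 <= j[ax] < shape[ax]) or not mask[tuple(j)]:
                    out[ix] = True
    return out


def naive_quantile(values, q):
    """Sort-and-linearly-interpolate empirical quantile."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    pos = q * (n - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def naive_ellipsoid_count(shape, center_frac, radius_frac):
    """Brute-force point-in-ellipsoid voxel count."""
    count = 0
    for ix in np.ndindex(tuple(shape)):
        acc = 0.0
        for ax in range(3):
            c = center_frac[ax] * (shape[ax] - 1)
            r = radius_frac * shape[ax]
            acc += ((ix[ax] - c) / r) ** 2
        if acc <= 1.0:
            count += 1
    return count
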