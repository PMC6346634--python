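"""2Dt (bivariate Student's t) dispersal-kernel mathematics.

The kernel used throughout the package is the classical single-parameter 2Dt
with shape fixed at 1:

    S(r; u) = 1 / (pi * u * (1 + r^2/u)^2)        [seeds m^-2 per seed produced]

where ``r`` is the Euclidean distance (m) from a source tree and ``u`` (m^2)
is the scale — the field's "dispersal parameter" once converted to the mean
dispersal distance ``(pi/2) * sqrt(u)``.  No shape parameter is fitted: with a
single scale the radial CDF, quantile function and mean all have closed forms,

    F(r) = 1 - 1/(1 + r^2/u),   median = sqrt(u),   mean = (pi/2) sqrt(u),

which this module exposes together with inverse-CDF sampling and the
tree-by-trap seed-shadow matrix.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "kernel_density",
    "kernel_radial_cdf",
    "mean_distance",
    "u_from_mean",
    "sample_distance",
    "shadow_matrix",
]


def _check_u(u) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if np.any(~(u > 0)) or np.any(~np.isfinite(u)):
        raise ValueError(f"dispersal scale u must be positive and finite, got {u!r}")
    return u


def kernel_density(r, u):
    """Seed density (m^-2) at distance ``r`` (m) per unit fecundity.

    Vectorised over ``r`` and ``u`` (broadcasting).  ``r = inf`` maps to 0,
    which the shadow-matrix code exploits to zero out cross-plot pairs.
    """
    u = _check_u(u)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance r must be non-negative")
    with np.errstate(divide="ignore"):
        out = 1.0 / (np.pi * u * (1.0 + r * r / u) ** 2)
    return out if out.ndim else float(out)


def kernel_radial_cdf(r, u):
    """P(dispersal distance <= r): ``1 - 1/(1 + r^2/u)``."""
    u = _check_u(u)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance r must be non-negative")
    out = 1.0 - 1.0 / (1.0 + r * r / u)
    return out if out.ndim else float(out)


def mean_distance(u):
    """Mean dispersal distance (m) of the kernel: ``(pi/2) * sqrt(u)``."""
    u = _check_u(u)
    out = 0.5 * np.pi * np.sqrt(u)
    return out if out.ndim else float(out)


def u_from_mean(dbar):
    """Invert :func:`mean_distance`: ``u = (2 * dbar / pi)^2`` (m^2)."""
    dbar = np.asarray(dbar, dtype=float)
    if np.any(~(dbar > 0)):
        raise ValueError("mean distance must be positive")
    out = (2.0 * dbar / np.pi) ** 2
    return out if out.ndim else float(out)


def sample_distance(u, rng: np.random.Generator, size=None):
    """Draw dispersal distances by inverse-CDF: ``r = sqrt(u * q / (1 - q))``."""
    u = _check_u(u)
    q = rng.uniform(size=size)
    out = np.sqrt(u * q / (1.0 - q))
    return out if np.ndim(out) else float(out)


def shadow_matrix(tree_xy, trap_xy, u, tree_plot=None, trap_plot=None) -> np.ndarray:
    """Seed-shadow matrix S with S[s, i] = kernel density at trap s from tree i.

    Parameters
    ----------
    tree_xy : (n_trees, 2) array of tree coordinates (m).
    trap_xy : (n_traps, 2) array of trap coordinates (m).
    u : scalar or (n_trees,) array — per-tree kernel scale (m^2); per-tree
        values support species x regime parameterisation in multi-plot stands.
    tree_plot, trap_plot : optional integer plot labels.  When given, pairs in
        different plots get S = 0 (coordinates are plot-local, so cross-plot
        distances are meaningless).

    Empty tree or trap sets yield a correspondingly empty matrix.
    """
    tree_xy = np.atleast_2d(np.asarray(tree_xy, dtype=float))
    trap_xy = np.atleast_2d(np.asarray(trap_xy, dtype=float))
    if tree_xy.size == 0:
        return np.zeros((trap_xy.shape[0], 0))
    diff = trap_xy[:, None, :] - tree_xy[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    if tree_plot is not None and trap_plot is not None:
        cross = np.asarray(trap_plot)[:, None] != np.asarray(tree_plot)[None, :]
        dist = np.where(cross, np.inf, dist)
    return kernel_density(dist, u)
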