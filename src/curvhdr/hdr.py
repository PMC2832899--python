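"""Highest-density-region gates.

For each grown curvature region the events inside are re-estimated with
their own kernel density estimate (two-stage diagonal plug-in bandwidths)
and the gate component is the level-``tau`` highest density region: the
region enclosed by the density contour chosen so that a fraction ``1 - tau``
of the subset lies at or above the level.  The level is the
``ceil(tau * m)``-th smallest of the density values at the subset points
(order-statistic estimator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .density import GridSpec, kde_on_grid, linear_bin
from .errors import InsufficientDataError, ValidationError

__all__ = ["HDRGate", "plugin_bandwidth", "hdr_level", "hdr_gate"]

_SQRT2PI = np.sqrt(2.0 * np.pi)
_RK = 1.0 / (2.0 * np.sqrt(np.pi))  # roughness of the Gaussian kernel

MIN_SUBSET = 10
HDR_GRID_NODES = {1: 101, 2: 101, 3: 21}
PAD_FACTOR = 3.7


def _phi_deriv(u: np.ndarray, r: int) -> np.ndarray:
    """r-th derivative of the standard normal density (r even here)."""
    phi = np.exp(-0.5 * u * u) / _SQRT2PI
    if r == 0:
        he = np.ones_like(u)
    elif r == 2:
        he = u**2 - 1.0
    elif r == 4:
        he = u**4 - 6.0 * u**2 + 3.0
    elif r == 6:
        he = u**6 - 15.0 * u**4 + 45.0 * u**2 - 15.0
    else:  # pragma: no cover
        raise ValueError(r)
    return he * phi


def _psi_binned(x: np.ndarray, r: int, g: float, nbins: int = 401) -> float:
    """Binned estimate of the integrated density-derivative functional.

    ``psi_r = E[f^(r)(X)]`` estimated as the double kernel sum
    ``m^-2 sum_ij phi_g^(r)(x_i - x_j)``, accelerated by linear binning.
    """
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise InsufficientDataError("degenerate subset axis")
    grid = GridSpec([lo], [hi], (nbins,))
    c = linear_bin(x[:, None], grid).ravel()
    delta = float(grid.spacing[0])
    t = np.arange(-(nbins - 1), nbins) * delta
    w = _phi_deriv(t / g, r) / g ** (r + 1)
    conv = np.convolve(c, w)[nbins - 1 : 2 * nbins - 1]
    m = c.sum()
    return float(c @ conv / (m * m))


def _stagewise_psi4(x: np.ndarray) -> tuple[float, float] | None:
    """Two-stage plug-in estimates of (psi_4, psi_0) for one axis.

    Stage 1 starts from the normal-reference psi_8, stage 2 re-estimates
    psi_6 then psi_4 with optimal pilot bandwidths.  Returns ``None`` when a
    functional comes out with the wrong sign (caller falls back to the
    normal-scale rule).
    """
    m = len(x)
    sd = float(np.std(x, ddof=1))
    if sd <= 0:
        return None
    psi8 = 105.0 / (32.0 * np.sqrt(np.pi) * sd**9)
    g6 = (30.0 / (_SQRT2PI * psi8 * m)) ** (1.0 / 9.0)
    psi6 = _psi_binned(x, 6, g6)
    if psi6 >= 0:
        return None
    g4 = (-6.0 / (_SQRT2PI * psi6 * m)) ** (1.0 / 7.0)
    psi4 = _psi_binned(x, 4, g4)
    if psi4 <= 0:
        return None
    psi2 = -1.0 / (4.0 * np.sqrt(np.pi) * sd**3)
    g0 = (-2.0 * (1.0 / _SQRT2PI) / (psi2 * m)) ** (1.0 / 3.0)
    psi0 = _psi_binned(x, 0, g0)
    if psi0 <= 0:
        return None
    return psi4, psi0


def plugin_bandwidth(subset: np.ndarray) -> np.ndarray:
    """Per-axis bandwidths from a two-stage diagonal plug-in selector.

    The diagonal AMISE (product-density approximation, cross terms dropped)
    is solved in closed form: with ``c_j = psi4_j * prod_{k != j} R(f_k)``,

        h_j = t / c_j^(1/4),
        t   = [ R(K)^d * prod_j c_j^(1/4) / m ]^(1/(d+4)),

    which scales as ``m^(-1/(d+4))``.  Falls back to the normal-scale rule
    ``sd_j * [4/((d+2) m)]^(1/(d+4))`` on any axis ladder failure.
    """
    x = np.atleast_2d(np.asarray(subset, dtype=float))
    if x.shape[0] < MIN_SUBSET:
        raise InsufficientDataError(
            f"plug-in bandwidth needs >= {MIN_SUBSET} points, got {x.shape[0]}"
        )
    m, d = x.shape
    widths = x.max(axis=0) - x.min(axis=0)
    if np.any(widths <= 1e-8 * (1.0 + np.abs(x).max())):
        # e.g. a saturation rail that slipped past debris removal
        raise InsufficientDataError("subset is degenerate along an axis")
    stats = [_stagewise_psi4(x[:, j]) for j in range(d)]
    if any(s is None for s in stats):
        sds = np.std(x, axis=0, ddof=1)
        if np.any(sds <= 0):
            raise InsufficientDataError("degenerate subset axis")
        return sds * (4.0 / ((d + 2) * m)) ** (1.0 / (d + 4))
    psi4 = np.array([s[0] for s in stats])
    psi0 = np.array([s[1] for s in stats])
    cj = psi4 * np.array([np.prod(np.delete(psi0, j)) for j in range(d)])
    t = (_RK**d * np.prod(cj**0.25) / m) ** (1.0 / (d + 4))
    return t / cj**0.25


def hdr_level(density_at_points: np.ndarray, tau: float) -> float:
    """Order-statistic HDR threshold: the ceil(tau*m)-th smallest value.

    At this level at least a fraction ``1 - tau`` of the points carry
    density at or above the threshold, so the enclosed region estimates the
    ``1 - tau`` probability-mass contour.
    """
    vals = np.asarray(density_at_points, dtype=float).ravel()
    if vals.size < 1:
        raise ValidationError("need at least one density value")
    if not 0.0 < tau < 1.0:
        raise ValidationError("tau must lie in (0, 1)")
    k = int(np.ceil(tau * vals.size))
    k = min(max(k, 1), vals.size)
    return float(np.partition(vals, k - 1)[k - 1])


@dataclass(frozen=True)
class HDRGate:
    """Level-``tau`` HDR gate fitted to one event subset."""

    components: tuple
    tau: float
    level: float
    bandwidths: np.ndarray
    subset_size: int


def hdr_gate(subset: np.ndarray, tau: float, grid_nodes: int | None = None) -> HDRGate:
    """Fit the level-``tau`` HDR gate to a standardized event subset.

    A KDE with plug-in bandwidths is evaluated on a local grid over the
    subset's bounding box (padded by 3.7 bandwidths per axis); the level is
    the order-statistic threshold of the density interpolated at the subset
    points; components come from contouring the superlevel set.  A single
    subset can legitimately yield more than one component.
    """
    x = np.atleast_2d(np.asarray(subset, dtype=float))
    if not 0.0 < tau < 1.0:
        raise ValidationError("tau must lie in (0, 1)")
    m, d = x.shape
    if m < MIN_SUBSET:
        raise InsufficientDataError(f"HDR gate needs >= {MIN_SUBSET} points")
    h = plugin_bandwidth(x)
    nodes = grid_nodes or HDR_GRID_NODES[d]
    lo = x.min(axis=0) - PAD_FACTOR * h
    hi = x.max(axis=0) + PAD_FACTOR * h
    grid = GridSpec(lo, hi, (nodes,) * d)
    counts = linear_bin(x, grid)
    fhat = kde_on_grid(counts, grid, h)
    vals = geometry._interp_on_grid(fhat, grid, x)
    level = hdr_level(vals, tau)
    comps = geometry.density_level_regions(fhat, level, grid, d)
    return HDRGate(
        components=tuple(comps),
        tau=float(tau),
        level=level,
        bandwidths=np.asarray(h, dtype=float),
        subset_size=m,
    )
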