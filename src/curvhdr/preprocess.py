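"""Event-table preprocessing: debris removal, variance-stabilising transform,
per-channel standardisation, and exact inversion back to original units.

Flow cytometers report fluorescence on a wide, strongly right-skewed scale
with saturation pile-up at the detector limits.  Gating operates on
``asinh``-transformed, standardised coordinates; the finished gate is mapped
back to the original units so it can be drawn over the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DegenerateChannelError,
    InsufficientDataError,
    SpaceMismatchError,
    ValidationError,
)

__all__ = [
    "EventTable",
    "ScaleState",
    "DebrisPolicy",
    "asinh_transform",
    "remove_boundary_debris",
    "standardize",
    "to_original_units",
]

SPACE_ORIGINAL = "original"
SPACE_TRANSFORMED = "transformed"
SPACE_STANDARDIZED = "standardized"


@dataclass(frozen=True)
class EventTable:
    """An n x d matrix of per-event channel measurements.

    Parameters
    ----------
    values
        ``(n, d)`` float array, one row per event.
    channel_names
        ``d`` unique channel labels (e.g. ``("FSC-H", "SSC-H")``).
    space_tag
        One of ``original | transformed | standardized``.
    """

    values: np.ndarray
    channel_names: tuple[str, ...]
    space_tag: str = SPACE_ORIGINAL

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if v.ndim != 2 or v.shape[0] < 1:
            raise ValidationError("event table must be a nonempty 2-d array")
        if not 1 <= v.shape[1] <= 3:
            raise ValidationError(f"dimension must be 1..3, got {v.shape[1]}")
        if len(self.channel_names) != v.shape[1]:
            raise ValidationError("channel_names length must match dimension")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        if not np.all(np.isfinite(v)):
            raise ValidationError("event table contains non-finite values")
        if self.space_tag not in (SPACE_ORIGINAL, SPACE_TRANSFORMED, SPACE_STANDARDIZED):
            raise ValidationError(f"unknown space_tag {self.space_tag!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def select(self, channels: list[str] | tuple[str, ...]) -> "EventTable":
        """Column subset/reorder by channel name."""
        missing = [c for c in channels if c not in self.channel_names]
        if missing:
            raise ValidationError(
                f"channel(s) {missing} not found; available: {list(self.channel_names)}"
            )
        idx = [self.channel_names.index(c) for c in channels]
        return EventTable(self.values[:, idx], tuple(channels), self.space_tag)


@dataclass(frozen=True)
class DebrisPolicy:
    """Rule for removing saturation pile-ups at the channel boundaries.

    An event is dropped when one of its channel values sits exactly at that
    channel's observed minimum or maximum *and* that exact value occurs in
    more than ``threshold`` of all events (a detector rail, not a cell).
    """

    threshold: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValidationError("debris threshold must lie in (0, 1]")


@dataclass(frozen=True)
class ScaleState:
    """Invertible record of the transform + standardisation applied.

    ``mean``/``sd`` are the per-channel moments of the *transformed* data, so
    forward = ``(transform(x) - mean) / sd`` and inverse is exact.
    """

    mean: np.ndarray
    sd: np.ndarray
    transform: str = "identity"
    debris_mask: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.atleast_1d(np.asarray(self.mean, float)))
        object.__setattr__(self, "sd", np.atleast_1d(np.asarray(self.sd, float)))
        if self.transform not in ("asinh", "identity"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        if np.any(self.sd <= 0):
            raise DegenerateChannelError("standard deviation must be positive")

    def forward(self, raw: np.ndarray) -> np.ndarray:
        x = np.asarray(raw, dtype=float)
        if self.transform == "asinh":
            x = np.arcsinh(x)
        return (x - self.mean) / self.sd

    def inverse(self, std: np.ndarray) -> np.ndarray:
        x = np.asarray(std, dtype=float) * self.sd + self.mean
        if self.transform == "asinh":
            x = np.sinh(x)
        return x


def asinh_transform(x: np.ndarray) -> np.ndarray:
    """Inverse hyperbolic sine, ``sinh^-1(x) = ln(x + sqrt(x^2 + 1))``.

    Strictly monotone, sign-preserving, roughly linear near zero and
    logarithmic in the tails — a good all-purpose skew reducer for
    cytometry channels.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("asinh_transform requires finite input")
    return np.arcsinh(x)


def remove_boundary_debris(
    t: EventTable, policy: DebrisPolicy | None = None
) -> tuple[EventTable, np.ndarray]:
    """Drop saturation pile-ups at the observed per-channel extremes.

    Returns the retained table and a boolean mask over the *input* rows
    (``True`` = retained).  Never removes every event.
    """
    policy = policy or DebrisPolicy()
    if t.space_tag != SPACE_ORIGINAL:
        raise SpaceMismatchError("debris removal operates on original units")
    v = t.values
    n = t.n
    drop = np.zeros(n, dtype=bool)
    for j in range(t.d):
        col = v[:, j]
        for extreme in (col.min(), col.max()):
            at = col == extreme
            if at.sum() > policy.threshold * n:
                drop |= at
    keep = ~drop
    if not keep.any():
        raise ValidationError(
            "debris policy would remove all events (degenerate sample)"
        )
    if drop.any():
        t = replace(t, values=v[keep])
    return t, keep


def standardize(t: EventTable) -> tuple[EventTable, ScaleState]:
    """Centre and scale each channel to sample mean 0, sample sd 1 (ddof=1)."""
    if t.n < 2:
        raise InsufficientDataError("standardize requires at least 2 events")
    mean = t.values.mean(axis=0)
    sd = t.values.std(axis=0, ddof=1)
    bad = np.where(sd <= 0)[0]
    if bad.size:
        names = [t.channel_names[j] for j in bad]
        raise DegenerateChannelError(f"constant channel(s): {names}")
    out = EventTable((t.values - mean) / sd, t.channel_names, SPACE_STANDARDIZED)
    return out, ScaleState(mean=mean, sd=sd)


def _map_vertices(x: np.ndarray, s: ScaleState) -> np.ndarray:
    y = np.asarray(x, dtype=float) * s.sd + s.mean
    if s.transform == "asinh":
        y = np.sinh(y)
    return y


def to_original_units(region, s: ScaleState):
    """Map a standardized-space gate back to original units.

    Every vertex/endpoint is pushed through ``x * sd + mean`` followed by the
    inverse transform (``sinh`` for the asinh pipeline).  Polygon edges and
    mesh faces are densified first when the transform is nonlinear, so the
    back-transformed boundary tracks the true (curved) image of the gate and
    event membership is preserved.
    """
    from . import geometry  # local import: geometry is independent of this module

    if region.space_tag != SPACE_STANDARDIZED:
        raise SpaceMismatchError(
            f"expected a standardized-space region, got {region.space_tag!r}"
        )
    densify = s.transform != "identity"
    comps = []
    for c in region.components:
        if isinstance(c, geometry.Interval):
            lo, hi = _map_vertices(np.array([c.lo, c.hi]), s)
            comps.append(geometry.Interval(float(lo), float(hi)))
        elif isinstance(c, geometry.Polygon):
            ring = c.vertices
            if densify:
                ring = geometry.densify_ring(ring, max_seg=0.02)
            comps.append(geometry.Polygon(_map_vertices(ring, s)))
        elif isinstance(c, geometry.TriMesh):
            m = c
            if densify:
                m = geometry.subdivide_mesh(m, max_edge=0.1)
            comps.append(geometry.TriMesh(_map_vertices(m.vertices, s), m.faces))
        else:  # pragma: no cover
            raise ValidationError(f"unknown component type {type(c).__name__}")
    return geometry.GateRegion(region.d, comps, space_tag=SPACE_ORIGINAL)
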