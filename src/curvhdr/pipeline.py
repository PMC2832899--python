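"""The curvHDR gating filter.

Orchestrates the full procedure: debris removal -> skew-reducing transform
-> standardisation -> significant-curvature detection on a grid -> convex
hulls -> growth by the factor G -> per-region subsetting -> level-tau HDR
refit -> union membership -> back-transform to original units.  Also
composes the result with axis-aligned rectangle gates ("rectangle-curvHDR"
gates), the standard way to cut away debris regions near the sample
boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry, hdr, preprocess
from .density import (
    CurvatureTestConfig,
    GridSpec,
    default_curvature_bandwidth,
    estimate_density_field,
    significant_negative_curvature,
)
from .geometry import indicator_to_regions
from .errors import InsufficientDataError, SpaceMismatchError, ValidationError
from .preprocess import EventTable, ScaleState

logger = logging.getLogger("curvhdr")

__all__ = ["CurvHDRParams", "GateResult", "curvhdr_filter", "intersect_rectangle", "gate_membership"]

CURV_GRID_NODES = {1: 151, 2: 151, 3: 51}
MIN_EVENTS = 100


@dataclass(frozen=True)
class CurvHDRParams:
    """Tuning parameters; unset values resolve to the recommended defaults.

    tau is the HDR level (main tuning knob, default 0.1: the gate keeps the
    region carrying ~90% of each subset's probability mass).  growth_factor
    defaults to 2^d (double the region per dimension); alpha is the
    curvature-test significance level; h_curv defaults to
    [4/((d+6)n)]^(1/(d+8)) on the standardized scale.
    """

    tau: float = 0.1
    growth_factor: float | None = None
    alpha: float = 0.05
    h_curv: float | None = None
    transform: str = "asinh"
    curv_grid_nodes: int | None = None
    hdr_grid_nodes: int | None = None
    debris_threshold: float = 0.01
    adjustment: str = "hochberg"
    min_region_nodes: int = 3
    density_floor_frac: float = 1e-3
    pad_factor: float = 3.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValidationError("tau must lie in (0, 1)")
        if self.growth_factor is not None and self.growth_factor <= 1:
            raise ValidationError("growth factor G must exceed 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.h_curv is not None and self.h_curv <= 0:
            raise ValidationError("h_curv must be positive")
        if self.transform not in ("asinh", "identity"):
            raise ValidationError("transform must be 'asinh' or 'identity'")

    def resolve(self, d: int, n: int) -> dict:
        """Concrete values for every parameter at the given (d, n)."""
        return {
            "tau": self.tau,
            "growth_factor": float(
                self.growth_factor if self.growth_factor is not None else 2**d
            ),
            "alpha": self.alpha,
            "h_curv": float(
                self.h_curv
                if self.h_curv is not None
                else default_curvature_bandwidth(d, n)
            ),
            "transform": self.transform,
            "curv_grid_nodes": int(self.curv_grid_nodes or CURV_GRID_NODES[d]),
            "hdr_grid_nodes": int(self.hdr_grid_nodes or hdr.HDR_GRID_NODES[d]),
            "debris_threshold": self.debris_threshold,
            "adjustment": self.adjustment,
            "min_region_nodes": self.min_region_nodes,
            "density_floor_frac": self.density_floor_frac,
            "pad_factor": self.pad_factor,
            "seed": self.seed,
            "d": d,
            "n": n,
        }


@dataclass
class GateResult:
    """Everything produced by one curvHDR run.

    ``membership`` indexes the *input* table (debris rows are False);
    ``curvature_regions`` records each significant-curvature component with
    its convex hull and grown hull (standardized space) for diagnostics.
    """

    gate: geometry.GateRegion
    gate_std: geometry.GateRegion
    membership: np.ndarray
    indices: np.ndarray
    curvature_regions: list
    hdr_gates: list
    component_masks: list
    params: CurvHDRParams
    scale: ScaleState
    events: EventTable = field(repr=False)
    log: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return len(self.gate_std.components)


def _component_centroid(c) -> tuple:
    pts = geometry._component_points(c)
    return tuple(np.round(pts.mean(axis=0), 9).tolist())


def curvhdr_filter(
    t: EventTable,
    channels: list[str] | None = None,
    params: CurvHDRParams | None = None,
) -> GateResult:
    """Run the full curvHDR gating procedure on an event table.

    Deterministic given the parameter set (including ``params.seed``, which
    drives the randomized ray directions of the trivariate containment
    test).  Finding no significant-curvature region yields an empty gate
    with a warning, not an error.
    """
    params = params or CurvHDRParams()
    if channels:
        t = t.select(list(channels))
    if t.space_tag != preprocess.SPACE_ORIGINAL:
        raise SpaceMismatchError("curvhdr_filter expects original units")
    n_input = t.n
    d = t.d

    retained, keep = preprocess.remove_boundary_debris(
        t, preprocess.DebrisPolicy(params.debris_threshold)
    )
    if retained.n < MIN_EVENTS:
        raise InsufficientDataError(
            f"need >= {MIN_EVENTS} events after debris removal, got {retained.n}"
        )
    if params.transform == "asinh":
        transformed = replace(
            retained,
            values=preprocess.asinh_transform(retained.values),
            space_tag=preprocess.SPACE_TRANSFORMED,
        )
    else:
        transformed = replace(retained, space_tag=preprocess.SPACE_TRANSFORMED)
    std, scale = preprocess.standardize(transformed)
    scale = replace(scale, transform=params.transform, debris_mask=keep)

    r = params.resolve(d, std.n)
    x = std.values
    grid = GridSpec.from_points(
        x, padding=r["pad_factor"] * r["h_curv"], nodes=r["curv_grid_nodes"]
    )
    field_ = estimate_density_field(x, grid, r["h_curv"])
    cfg = CurvatureTestConfig(
        alpha=r["alpha"],
        adjustment=r["adjustment"],
        min_region_nodes=r["min_region_nodes"],
        density_floor_frac=r["density_floor_frac"],
    )
    flags = significant_negative_curvature(field_, std.n, cfg)
    raw_regions = indicator_to_regions(flags, grid, d, r["min_region_nodes"])
    raw_regions.sort(key=_component_centroid)

    warnings_log: list[str] = []
    curvature_records = []
    hdr_gates = []
    components = []
    if not raw_regions:
        msg = "no significant curvature regions found; gate is empty"
        warnings.warn(msg, stacklevel=2)
        warnings_log.append(msg)
    for region in raw_regions:
        hull = geometry.convex_hull(region)
        grown = geometry.grow_region(hull, r["growth_factor"])
        subset_mask = geometry.component_contains(grown, x, seed=params.seed)
        record = {"raw": region, "hull": hull, "grown": grown, "subset_size": int(subset_mask.sum())}
        curvature_records.append(record)
        if subset_mask.sum() < hdr.MIN_SUBSET:
            msg = f"curvature region with {int(subset_mask.sum())} events dropped (< {hdr.MIN_SUBSET})"
            logger.warning(msg)
            warnings_log.append(msg)
            continue
        try:
            gate_k = hdr.hdr_gate(
                x[subset_mask], r["tau"], grid_nodes=r["hdr_grid_nodes"]
            )
        except InsufficientDataError as exc:
            msg = f"curvature region dropped: {exc}"
            logger.warning(msg)
            warnings_log.append(msg)
            continue
        hdr_gates.append(gate_k)
        components.extend(gate_k.components)

    gate_std = geometry.GateRegion(d, components, space_tag=preprocess.SPACE_STANDARDIZED)
    gate = preprocess.to_original_units(gate_std, scale)

    # membership is authoritative in original units and purely geometric, so
    # re-applying the saved gate to the same events reproduces it exactly
    # (debris only influences gate *placement*, not gate membership)
    component_masks = [
        geometry.component_contains(c, t.values, seed=params.seed)
        for c in gate.components
    ]
    membership = (
        np.any(component_masks, axis=0)
        if component_masks
        else np.zeros(n_input, dtype=bool)
    )

    log = dict(r)
    log.update(
        {
            "n_input": n_input,
            "n_debris": int(n_input - retained.n),
            "n_retained": int(retained.n),
            "S": len(raw_regions),
            "n_components": len(components),
            "n_members": int(membership.sum()),
            "channels": list(t.channel_names),
            "warnings": warnings_log,
        }
    )
    logger.info("curvhdr_filter: %s", log)
    return GateResult(
        gate=gate,
        gate_std=gate_std,
        membership=membership,
        indices=np.where(membership)[0],
        curvature_regions=curvature_records,
        hdr_gates=hdr_gates,
        component_masks=component_masks,
        params=params,
        scale=scale,
        events=t,
        log=log,
    )


def _validate_rect(rect, d: int) -> np.ndarray:
    r = np.asarray(rect, dtype=float)
    if r.shape != (d, 2) or not np.all(np.isfinite(r)) or np.any(r[:, 0] >= r[:, 1]):
        raise ValidationError(
            f"rectangle must be a ({d}, 2) array of finite lo < hi bounds"
        )
    return r


def _in_box(values: np.ndarray, rect: np.ndarray) -> np.ndarray:
    return np.all((values >= rect[:, 0]) & (values <= rect[:, 1]), axis=1)


def intersect_rectangle(g, rect, events: EventTable | None = None):
    """Clip a gate with an axis-aligned rectangle (original units).

    d=1: interval intersection; d=2: polygon clipping against the box;
    d=3: membership-level intersection, with the clip box recorded on the
    region.  Returns ``(GateRegion, membership)``; membership is ``None``
    when no events are available.
    """
    import shapely
    import shapely.geometry as sg

    if isinstance(g, GateResult):
        region = g.gate
        events = events if events is not None else g.events
        base_mask = g.membership
    else:
        region = g
        base_mask = None
    rect = _validate_rect(rect, region.d)

    comps = []
    if region.d == 1:
        for c in region.components:
            lo, hi = max(c.lo, rect[0, 0]), min(c.hi, rect[0, 1])
            if lo < hi:
                comps.append(geometry.Interval(lo, hi))
    elif region.d == 2:
        box = sg.box(rect[0, 0], rect[1, 0], rect[0, 1], rect[1, 1])
        for c in region.components:
            inter = c.to_shapely().intersection(box)
            polys = (
                [inter]
                if isinstance(inter, sg.Polygon)
                else list(getattr(inter, "geoms", []))
            )
            for p in polys:
                if isinstance(p, sg.Polygon) and p.area > 0:
                    comps.append(geometry.Polygon(np.asarray(p.exterior.coords)))
    else:
        lo, hi = rect[:, 0], rect[:, 1]
        for c in region.components:
            cmin, cmax = c.vertices.min(axis=0), c.vertices.max(axis=0)
            if np.all(cmin <= hi) and np.all(cmax >= lo):
                comps.append(c)
    clipped = geometry.GateRegion(
        region.d,
        comps,
        space_tag=region.space_tag,
        clip_box=rect if region.d == 3 else None,
    )

    mask = None
    if events is not None:
        if base_mask is None:
            base_mask = gate_membership(region, events)
        mask = base_mask & _in_box(events.values, rect)
    return clipped, mask


def gate_membership(region: geometry.GateRegion, t: EventTable, seed: int = 0) -> np.ndarray:
    """Event membership in a (possibly saved) gate: OR over components."""
    if region.space_tag != t.space_tag:
        raise SpaceMismatchError(
            f"gate is in {region.space_tag!r} space but events are {t.space_tag!r}"
        )
    if region.is_empty:
        return np.zeros(t.n, dtype=bool)
    mask = np.zeros(t.n, dtype=bool)
    for c in region.components:
        mask |= geometry.component_contains(c, t.values, seed=seed)
    if region.clip_box is not None:
        mask &= _in_box(t.values, np.asarray(region.clip_box, dtype=float))
    return mask
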