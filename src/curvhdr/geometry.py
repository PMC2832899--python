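"""Gate geometry: regions, hulls, growth by circle/sphere rolling, and
batch point containment.

Gate components are intervals (d=1), simple closed polygons (d=2) or closed
triangle meshes (d=3).  Regions are extracted from boolean or density grids
by contouring, replaced by convex hulls, and grown to a target area/volume
ratio by offsetting edge midpoints (2D) or face centroids (3D) outward
along their normals by twice a rolling radius found by bisection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .errors import DegenerateGeometryError, FormatError, ValidationError

__all__ = [
    "Interval",
    "Polygon",
    "TriMesh",
    "GateRegion",
    "polygon_area",
    "trimesh_volume",
    "convex_hull",
    "grow_region",
    "points_in_polygon",
    "points_in_polyhedron",
    "indicator_to_regions",
    "density_level_regions",
    "component_contains",
    "component_measure",
    "region_to_dict",
    "region_from_dict",
    "densify_ring",
    "subdivide_mesh",
]

GATE_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# component types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """A nonempty closed interval [lo, hi], the d=1 gate component."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lo) or not np.isfinite(self.hi) or self.lo >= self.hi:
            raise ValidationError(f"invalid interval [{self.lo}, {self.hi}]")


def _signed_ring_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


@dataclass(frozen=True)
class Polygon:
    """Simple closed polygon, stored as a clockwise ring with first == last."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValidationError("polygon vertices must be an (N, 2) array")
        if not np.allclose(v[0], v[-1]):
            v = np.vstack([v, v[0]])
        # drop consecutive duplicates
        keep = np.ones(len(v), dtype=bool)
        keep[1:] = np.any(np.abs(np.diff(v, axis=0)) > 0, axis=1)
        v = v[keep]
        if not np.allclose(v[0], v[-1]):
            v = np.vstack([v, v[0]])
        if len(v) < 4:  # ring of >= 3 distinct vertices plus closure
            raise DegenerateGeometryError("polygon needs >= 3 distinct vertices")
        area = _signed_ring_area(v)
        if abs(area) <= 0:
            raise DegenerateGeometryError("polygon has zero area")
        if area > 0:  # counter-clockwise -> flip to the clockwise convention
            v = v[::-1]
        object.__setattr__(self, "vertices", v)

    def to_shapely(self):
        import shapely.geometry as sg

        return sg.Polygon(self.vertices)


@dataclass(frozen=True)
class TriMesh:
    """Closed, consistently oriented triangle mesh with positive volume."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or f.ndim != 2 or f.shape[1] != 3:
            raise ValidationError("mesh needs (V,3) vertices and (F,3) faces")
        # closed + consistently oriented: every directed edge appears exactly
        # once and its reverse appears exactly once
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        directed = {(int(a), int(b)) for a, b in e}
        if len(directed) != len(e):
            raise ValidationError("mesh has duplicated directed edges")
        for a, b in directed:
            if (b, a) not in directed:
                raise ValidationError("mesh is open or inconsistently oriented")
        vol = _signed_mesh_volume(v, f)
        if vol == 0:
            raise DegenerateGeometryError("mesh encloses zero volume")
        if vol < 0:
            f = f[:, ::-1].copy()
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass(frozen=True)
class GateRegion:
    """A union of gate components plus a coordinate-space tag.

    Overlapping components are kept separate (membership uses set semantics);
    ``clip_box`` records an axis-aligned clip applied at membership level
    (used for trivariate rectangle gates).
    """

    d: int
    components: tuple
    space_tag: str = "standardized"
    clip_box: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        expect = {1: Interval, 2: Polygon, 3: TriMesh}.get(self.d)
        if expect is None:
            raise ValidationError("dimension must be 1..3")
        for c in self.components:
            if not isinstance(c, expect):
                raise ValidationError(
                    f"d={self.d} region cannot hold {type(c).__name__}"
                )

    @property
    def is_empty(self) -> bool:
        return len(self.components) == 0


# ---------------------------------------------------------------------------
# measures
# ---------------------------------------------------------------------------

def polygon_area(p: Polygon) -> float:
    """Polygon area by the shoelace formula (orientation-normalised)."""
    return abs(_signed_ring_area(p.vertices))


def _signed_mesh_volume(v: np.ndarray, f: np.ndarray) -> float:
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    return float(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0)


def trimesh_volume(m: TriMesh) -> float:
    """Enclosed volume: absolute sum of signed origin-tetrahedron volumes."""
    return abs(_signed_mesh_volume(m.vertices, m.faces))


def component_measure(c) -> float:
    """Length / area / volume of a component."""
    if isinstance(c, Interval):
        return c.hi - c.lo
    if isinstance(c, Polygon):
        return polygon_area(c)
    return trimesh_volume(c)


# ---------------------------------------------------------------------------
# hulls and growth
# ---------------------------------------------------------------------------

def _component_points(obj) -> np.ndarray:
    if isinstance(obj, Interval):
        return np.array([[obj.lo], [obj.hi]])
    if isinstance(obj, Polygon):
        return obj.vertices[:-1]
    if isinstance(obj, TriMesh):
        return obj.vertices
    return np.atleast_2d(np.asarray(obj, dtype=float))


def convex_hull(points_or_region):
    """Convex hull of points or of a gate component.

    Returns an :class:`Interval`, :class:`Polygon` or :class:`TriMesh`
    depending on the input dimension.
    """
    pts = _component_points(points_or_region)
    d = pts.shape[1]
    if d == 1:
        lo, hi = float(pts.min()), float(pts.max())
        if lo >= hi:
            raise DegenerateGeometryError("all points coincide")
        return Interval(lo, hi)
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate hull input: {exc}") from exc
    if d == 2:
        ring = pts[hull.vertices]  # counter-clockwise from Qhull
        return Polygon(np.vstack([ring, ring[0]]))
    verts = pts[hull.vertices]
    remap = {old: new for new, old in enumerate(hull.vertices)}
    faces = np.vectorize(remap.get)(hull.simplices)
    tm = _trimesh.Trimesh(verts, faces, process=False)
    tm.fix_normals()
    return TriMesh(tm.vertices, tm.faces)


def _grown_candidate(comp, r: float):
    """Offset region for rolling radius r (hull keeps it convex and ⊇ input)."""
    if isinstance(comp, Polygon):
        ring = comp.vertices[:-1]
        nxt = np.roll(ring, -1, axis=0)
        mid = 0.5 * (ring + nxt)
        edge = nxt - ring
        normal = np.stack([edge[:, 1], -edge[:, 0]], axis=1)
        normal /= np.linalg.norm(normal, axis=1, keepdims=True)
        centroid = ring.mean(axis=0)
        flip = np.einsum("ij,ij->i", mid - centroid, normal) < 0
        normal[flip] *= -1
        pts = np.vstack([mid + 2.0 * r * normal, ring])
        return convex_hull(pts)
    # TriMesh: antipoles of the sphere touching each face at its centroid
    tm = comp.to_trimesh()
    centroids = tm.triangles_center
    normals = tm.face_normals
    pts = np.vstack([centroids + 2.0 * r * normals, comp.vertices])
    return convex_hull(pts)


def grow_region(region, G: float):
    """Grow a convex region so its measure is ``G`` times larger.

    d=1: symmetric widening.  d=2/3: circle/sphere rolling — edge midpoints
    (face centroids) are pushed ``2r`` along the outward normals, the offset
    points are re-hulled together with the original vertices, and ``r`` is
    found by bisection so the area/volume ratio matches ``G`` to 0.5%.
    """
    if not np.isfinite(G) or G <= 1:
        raise ValidationError("growth factor G must exceed 1")
    if isinstance(region, Interval):
        c = 0.5 * (region.lo + region.hi)
        half = 0.5 * G * (region.hi - region.lo)
        return Interval(c - half, c + half)
    if not isinstance(region, (Polygon, TriMesh)):
        raise ValidationError("grow_region expects an Interval, Polygon or TriMesh")

    base = component_measure(region)
    pts = _component_points(region)
    diameter = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))

    def ratio(r: float) -> float:
        return component_measure(_grown_candidate(region, r)) / base

    hi = diameter
    for _ in range(60):
        if ratio(hi) >= G:
            break
        hi *= 2.0
    else:  # pragma: no cover - ratio grows without bound in r
        raise RuntimeError("growth bisection failed to bracket")
    lo = 0.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        rmid = ratio(mid)
        if abs(rmid - G) <= 0.004 * G:
            return _grown_candidate(region, mid)
        if rmid < G:
            lo = mid
        else:
            hi = mid
    return _grown_candidate(region, 0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# containment
# ---------------------------------------------------------------------------

def points_in_polygon(points: np.ndarray, p: Polygon) -> np.ndarray:
    """Even-odd (crossing-number) containment; boundary counts as inside."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ring = p.vertices
    x1, y1 = ring[:-1, 0], ring[:-1, 1]
    x2, y2 = ring[1:, 0], ring[1:, 1]
    dx, dy = x2 - x1, y2 - y1
    scale = max(np.ptp(ring[:, 0]), np.ptp(ring[:, 1]))
    tol = 1e-9 * scale
    seg_len2 = dx * dx + dy * dy
    out = np.zeros(len(pts), dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(dy != 0, dx / np.where(dy != 0, dy, 1.0), 0.0)
    for start in range(0, len(pts), 65536):
        px = pts[start : start + 65536, 0][:, None]
        py = pts[start : start + 65536, 1][:, None]
        crosses = (y1 > py) != (y2 > py)
        xint = x1 + (py - y1) * slope
        inside = ((crosses & (px < xint)).sum(axis=1) % 2).astype(bool)
        # boundary: distance from point to segment <= tol
        t = np.clip(((px - x1) * dx + (py - y1) * dy) / np.where(seg_len2 > 0, seg_len2, 1.0), 0, 1)
        d2 = (px - (x1 + t * dx)) ** 2 + (py - (y1 + t * dy)) ** 2
        on_edge = (d2 <= tol * tol).any(axis=1)
        out[start : start + 65536] = inside | on_edge
    return out


def points_in_polyhedron(
    points: np.ndarray, mesh: TriMesh, seed: int = 0, max_redraws: int = 8
) -> np.ndarray:
    """Ray-casting parity containment test against a closed triangle mesh.

    A single random ray direction is shared by all points; any point whose
    ray grazes a vertex/edge (or hits a near-parallel face) is retested with
    a fresh direction.  Points on the surface count as inside.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    v, f = mesh.vertices, mesh.faces
    v0 = v[f[:, 0]]
    e1 = v[f[:, 1]] - v0
    e2 = v[f[:, 2]] - v0
    scale = float(np.linalg.norm(v.max(axis=0) - v.min(axis=0)))
    tol_surf = 1e-9 * scale
    geps = 1e-10
    rng = np.random.default_rng(seed)

    inside = np.zeros(len(pts), dtype=bool)
    on_surf = np.zeros(len(pts), dtype=bool)
    active = np.ones(len(pts), dtype=bool)

    for _ in range(max_redraws):
        if not active.any():
            break
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        h = np.cross(d, e2)  # (F, 3)
        a = np.einsum("ij,ij->i", e1, h)
        e1n = np.linalg.norm(e1, axis=1) * np.linalg.norm(h, axis=1) + 1e-300
        if np.any(np.abs(a) / e1n < 1e-9):
            continue  # near-parallel to some face: draw a fresh direction
        inv_a = 1.0 / a
        idx = np.where(active)[0]
        for start in range(0, len(idx), 1024):
            sel = idx[start : start + 1024]
            p = pts[sel]
            count = np.zeros(len(sel), dtype=np.int64)
            grazed = np.zeros(len(sel), dtype=bool)
            surf = np.zeros(len(sel), dtype=bool)
            for fstart in range(0, len(f), 2048):
                fs = slice(fstart, fstart + 2048)
                s = p[:, None, :] - v0[None, fs, :]  # (m, F', 3)
                u = np.einsum("mfk,fk->mf", s, h[fs]) * inv_a[fs]
                q = np.cross(s, e1[None, fs, :])
                w = np.einsum("k,mfk->mf", d, q) * inv_a[fs]
                t = np.einsum("fk,mfk->mf", e2[fs], q) * inv_a[fs]
                bary_ok = (u >= -geps) & (w >= -geps) & (u + w <= 1 + geps)
                surf |= (bary_ok & (np.abs(t) <= tol_surf)).any(axis=1)
                hit = bary_ok & (t > tol_surf)
                count += hit.sum(axis=1)
                near_edge = (
                    (np.abs(u) < geps)
                    | (np.abs(w) < geps)
                    | (np.abs(1 - u - w) < geps)
                )
                grazed |= (hit & near_edge).any(axis=1)
            ok = ~grazed
            inside[sel[ok]] = (count[ok] % 2).astype(bool)
            on_surf[sel] |= surf
            active[sel[ok]] = False
    return inside | on_surf


def component_contains(c, points: np.ndarray, seed: int = 0) -> np.ndarray:
    """Boolean membership of ``points`` in a single gate component."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if isinstance(c, Interval):
        x = pts[:, 0]
        return (x >= c.lo) & (x <= c.hi)
    if isinstance(c, Polygon):
        return points_in_polygon(pts, c)
    return points_in_polyhedron(pts, c, seed=seed)


# ---------------------------------------------------------------------------
# grid -> regions
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.where(mask)[0]
    if idx.size == 0:
        return []
    breaks = np.where(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def _mask_to_polygon(mask: np.ndarray, grid) -> Polygon | None:
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    best, best_area = None, 0.0
    for c in contours:
        if len(c) < 4 or not np.allclose(c[0], c[-1]):
            continue
        area = abs(_signed_ring_area(c))
        if area > best_area:
            best, best_area = c, area
    if best is None:
        return None
    real = grid.lows + (best - 1.0) * grid.spacing
    try:
        return Polygon(real)
    except DegenerateGeometryError:
        return None


def _field_to_meshes(volume: np.ndarray, level: float, grid) -> list[TriMesh]:
    padded = np.pad(volume, 1, constant_values=min(0.0, level - 1.0))
    try:
        verts, faces, _, _ = measure.marching_cubes(
            padded, level=level, spacing=tuple(grid.spacing)
        )
    except (ValueError, RuntimeError):
        return []
    verts = verts + (grid.lows - grid.spacing)
    tm = _trimesh.Trimesh(verts, faces, process=True)
    out = []
    for part in tm.split(only_watertight=True):
        if part.faces.shape[0] < 4:
            continue
        try:
            out.append(TriMesh(np.asarray(part.vertices), np.asarray(part.faces)))
        except (ValidationError, DegenerateGeometryError):
            continue
    return out


def indicator_to_regions(
    flags: np.ndarray, grid, d: int | None = None, min_region_nodes: int = 3
) -> list:
    """Connected significant-curvature regions from a boolean grid.

    d=1: maximal runs of flagged nodes as intervals; d=2: marching-squares
    outline of each connected component; d=3: marching-cubes surface of each
    component.  Components supported by fewer than ``min_region_nodes``
    flagged nodes are dropped; holes inside a component are filled.
    """
    flags = np.asarray(flags, dtype=bool)
    d = d or flags.ndim
    if d == 1:
        axis = grid.axes()[0]
        half = 0.5 * grid.spacing[0]
        out = []
        for s, e in _runs(flags.ravel()):
            if e - s + 1 < min_region_nodes:
                continue
            lo, hi = axis[s], axis[e]
            if lo >= hi:  # singleton run: give it one cell of width
                lo, hi = lo - half, hi + half
            out.append(Interval(float(lo), float(hi)))
        return out
    labels, nlab = ndimage.label(flags)
    out = []
    for lab in range(1, nlab + 1):
        mask = labels == lab
        if mask.sum() < min_region_nodes:
            continue
        if d == 2:
            poly = _mask_to_polygon(mask, grid)
            if poly is not None:
                out.append(poly)
        else:
            out.extend(_field_to_meshes(mask.astype(float), 0.5, grid))
    return out


def _interp_on_grid(field: np.ndarray, grid, points: np.ndarray) -> np.ndarray:
    from scipy.interpolate import RegularGridInterpolator

    itp = RegularGridInterpolator(
        grid.axes(), field, bounds_error=False, fill_value=0.0
    )
    return itp(np.atleast_2d(points))


def density_level_regions(fhat: np.ndarray, level: float, grid, d: int | None = None) -> list:
    """Connected components of the superlevel set ``{fhat >= level}``.

    Uses subcell interpolation (linear crossings / marching squares / cubes)
    so component boundaries track the true contour rather than the node
    lattice.  Cavity surfaces (regions *below* the level enclosed by a
    component) are dropped: gates are reported filled.
    """
    if level <= 0:
        raise ValidationError("contour level must be positive")
    fhat = np.asarray(fhat, dtype=float)
    d = d or fhat.ndim
    if level >= fhat.max():
        return []
    if d == 1:
        f = fhat.ravel()
        axis = grid.axes()[0]
        out = []
        for s, e in _runs(f >= level):
            lo = axis[s]
            if s > 0:
                lo = axis[s - 1] + (axis[s] - axis[s - 1]) * (level - f[s - 1]) / (
                    f[s] - f[s - 1]
                )
            hi = axis[e]
            if e < len(f) - 1:
                hi = axis[e] + (axis[e + 1] - axis[e]) * (f[e] - level) / (
                    f[e] - f[e + 1]
                )
            if lo < hi:
                out.append(Interval(float(lo), float(hi)))
        return out
    if d == 2:
        padded = np.pad(fhat, 1)
        out = []
        for c in measure.find_contours(padded, level):
            if len(c) < 4 or not np.allclose(c[0], c[-1]):
                continue
            real = grid.lows + (c - 1.0) * grid.spacing
            try:
                poly = Polygon(real)
            except DegenerateGeometryError:
                continue
            rep = poly.to_shapely().representative_point()
            if _interp_on_grid(fhat, grid, [[rep.x, rep.y]])[0] >= level:
                out.append(poly)
        return out
    meshes = _field_to_meshes(fhat, level, grid)
    if not meshes:
        return []
    nodes = grid.node_coords()
    above = nodes[(fhat >= level).ravel()]
    out = []
    for m in meshes:
        lo, hi = m.vertices.min(axis=0), m.vertices.max(axis=0)
        cand = above[np.all((above >= lo) & (above <= hi), axis=1)]
        if len(cand) > 400:
            cand = cand[:: len(cand) // 400 + 1]
        if len(cand) and points_in_polyhedron(cand, m).any():
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# densification (for nonlinear back-transforms)
# ---------------------------------------------------------------------------

def densify_ring(ring: np.ndarray, max_seg: float) -> np.ndarray:
    """Insert vertices so no edge of a closed ring exceeds ``max_seg``."""
    pieces = []
    for p, q in zip(ring[:-1], ring[1:]):
        k = max(1, int(np.ceil(np.linalg.norm(q - p) / max_seg)))
        t = np.linspace(0, 1, k, endpoint=False)[:, None]
        pieces.append(p + t * (q - p))
    pieces.append(ring[-1:])
    return np.vstack(pieces)


def subdivide_mesh(m: TriMesh, max_edge: float) -> TriMesh:
    """Subdivide faces until every edge is shorter than ``max_edge``."""
    v, f = _trimesh.remesh.subdivide_to_size(m.vertices, m.faces, max_edge)
    return TriMesh(v, f)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def region_to_dict(region: GateRegion) -> dict:
    comps = []
    for c in region.components:
        if isinstance(c, Interval):
            comps.append({"type": "interval", "lo": c.lo, "hi": c.hi})
        elif isinstance(c, Polygon):
            comps.append({"type": "polygon", "vertices": c.vertices.tolist()})
        else:
            comps.append(
                {
                    "type": "trimesh",
                    "vertices": c.vertices.tolist(),
                    "faces": c.faces.tolist(),
                }
            )
    out = {
        "schema_version": GATE_SCHEMA_VERSION,
        "dimension": region.d,
        "space": region.space_tag,
        "components": comps,
    }
    if region.clip_box is not None:
        out["clip_box"] = np.asarray(region.clip_box).tolist()
    return out


def region_from_dict(data: dict) -> GateRegion:
    if data.get("schema_version") != GATE_SCHEMA_VERSION:
        raise FormatError(
            f"unsupported gate schema version {data.get('schema_version')!r}"
        )
    comps = []
    for c in data["components"]:
        kind = c.get("type")
        if kind == "interval":
            comps.append(Interval(float(c["lo"]), float(c["hi"])))
        elif kind == "polygon":
            comps.append(Polygon(np.asarray(c["vertices"], dtype=float)))
        elif kind == "trimesh":
            comps.append(
                TriMesh(
                    np.asarray(c["vertices"], dtype=float),
                    np.asarray(c["faces"], dtype=np.int64),
                )
            )
        else:
            raise FormatError(f"unknown component type {kind!r}")
    clip = data.get("clip_box")
    return GateRegion(
        int(data["dimension"]),
        comps,
        space_tag=data.get("space", "standardized"),
        clip_box=None if clip is None else np.asarray(clip, dtype=float),
    )
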