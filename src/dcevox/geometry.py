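"""Seeded construction of 2-D tissue voxel domains.

A voxel is modelled as a square of side ``L`` (default 250 µm) partitioned
into three compartments:

* the vascular space ``v_p`` — circular vessel cross sections that deliver
  contrast agent,
* the extravascular intracellular space (EIS, ``1 - v_e - v_p``) — packed
  elliptical cells impermeable to gadolinium chelates,
* the extravascular extracellular space (EES, ``v_e``) — everything else,
  the only compartment the agent can diffuse through.

Cells are ellipses inscribed into a Lloyd-relaxed Voronoi partition (plus
greedy pocket filling); vessels are fixed-diameter discs spread over the
voxel by farthest-point sampling so the vasculature is spaced rather than
clustered.  All lengths are in mm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point
from shapely.strtree import STRtree

__all__ = [
    "Ellipse",
    "Vessel",
    "TissueDomain",
    "PackingError",
    "generate_domain",
    "tile_extended_domain",
]


class PackingError(RuntimeError):
    """Raised when the target area fractions cannot be realised."""


@dataclass(frozen=True)
class Ellipse:
    """A cell cross section: centre (mm), semi-axes (mm), rotation (rad)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float

    @property
    def area(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]

    def to_polygon(self, n: int = 64):
        """Polygonal approximation with ``n`` vertices (shapely Polygon)."""
        th = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        x = self.semi_axes[0] * np.cos(th)
        y = self.semi_axes[1] * np.sin(th)
        ca, sa = math.cos(self.angle), math.sin(self.angle)
        return shapely.Polygon(
            np.column_stack(
                [self.center[0] + ca * x - sa * y, self.center[1] + sa * x + ca * y]
            )
        )

    def translated(self, dx: float, dy: float) -> "Ellipse":
        return Ellipse((self.center[0] + dx, self.center[1] + dy), self.semi_axes, self.angle)


@dataclass(frozen=True)
class Vessel:
    """A vessel cross section: centre (mm) and radius (mm)."""

    center: tuple[float, float]
    radius: float

    @property
    def area(self) -> float:
        return math.pi * self.radius**2

    @property
    def perimeter(self) -> float:
        return 2.0 * math.pi * self.radius

    def to_polygon(self, n: int = 64):
        return Point(*self.center).buffer(self.radius, quad_segs=max(2, n // 4))

    def translated(self, dx: float, dy: float) -> "Vessel":
        return Vessel((self.center[0] + dx, self.center[1] + dy), self.radius)


@dataclass
class TissueDomain:
    """Geometry of one voxel (or a tiling of identical voxels).

    ``voxel_side`` is the side of a single tile; the full domain spans
    ``tiles * voxel_side`` in each direction with the origin at the lower
    left.  For an extended 3x3 domain the voxel of interest is the central
    tile ``[L, 2L] x [L, 2L]``.
    """

    voxel_side: float
    cells: list[Ellipse] = field(default_factory=list)
    vessels: list[Vessel] = field(default_factory=list)
    ve_achieved: float = 1.0
    vp_achieved: float = 0.0
    veis_achieved: float = 0.0
    seed: int = 0
    tiles: int = 1

    def __post_init__(self) -> None:
        s = self.ve_achieved + self.vp_achieved + self.veis_achieved
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"area fractions must sum to 1, got {s!r}")
        for f in (self.ve_achieved, self.vp_achieved, self.veis_achieved):
            if not (-1e-12 <= f <= 1.0 + 1e-12):
                raise ValueError("area fractions must lie in [0, 1]")

    # -- derived geometry ------------------------------------------------
    @property
    def extent(self) -> float:
        """Side length of the full (possibly tiled) domain in mm."""
        return self.tiles * self.voxel_side

    @property
    def central_window(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the voxel of interest."""
        L = self.voxel_side
        k = self.tiles // 2
        return (k * L, k * L, (k + 1) * L, (k + 1) * L)

    @property
    def tile_area(self) -> float:
        return self.voxel_side**2

    def vessel_perimeter_per_tile(self) -> float:
        """Total analytic vessel boundary length inside one tile (mm)."""
        return sum(v.perimeter for v in self.vessels) / self.tiles**2

    def geometric_fractions(self) -> tuple[float, float, float]:
        """(ve, vp, veis) recomputed from the stored shapes."""
        A = self.extent**2
        vp = sum(v.area for v in self.vessels) / A
        veis = sum(c.area for c in self.cells) / A
        return 1.0 - vp - veis, vp, veis

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "voxel_side_mm": self.voxel_side,
            "tiles": self.tiles,
            "seed": self.seed,
            "ve_achieved": self.ve_achieved,
            "vp_achieved": self.vp_achieved,
            "veis_achieved": self.veis_achieved,
            "cells": [
                {"center": list(c.center), "semi_axes": list(c.semi_axes), "angle": c.angle}
                for c in self.cells
            ],
            "vessels": [{"center": list(v.center), "radius": v.radius} for v in self.vessels],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TissueDomain":
        doc = json.loads(text)
        return cls(
            voxel_side=doc["voxel_side_mm"],
            cells=[
                Ellipse(tuple(c["center"]), tuple(c["semi_axes"]), c["angle"])
                for c in doc["cells"]
            ],
            vessels=[Vessel(tuple(v["center"]), v["radius"]) for v in doc["vessels"]],
            ve_achieved=doc["ve_achieved"],
            vp_achieved=doc["vp_achieved"],
            veis_achieved=doc["veis_achieved"],
            seed=doc["seed"],
            tiles=doc["tiles"],
        )


def _farthest_point_sites(rng: np.random.Generator, n: int, lo: float, hi: float,
                          n_candidates: int = 4096) -> np.ndarray:
    """Greedy farthest-point sampling of ``n`` sites in [lo, hi]^2."""
    cand = rng.uniform(lo, hi, size=(n_candidates, 2))
    # start from the candidate closest to the box centre for determinism
    mid = 0.5 * (lo + hi)
    first = int(np.argmin(np.hypot(cand[:, 0] - mid, cand[:, 1] - mid)))
    chosen = [first]
    dist = np.hypot(cand[:, 0] - cand[first, 0], cand[:, 1] - cand[first, 1])
    for _ in range(n - 1):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        d_new = np.hypot(cand[:, 0] - cand[nxt, 0], cand[:, 1] - cand[nxt, 1])
        dist = np.minimum(dist, d_new)
    return cand[chosen]


def _lloyd_voronoi_polygons(
    rng: np.random.Generator,
    L: float,
    fixed_sites: np.ndarray,
    n_free: int,
    n_iter: int = 12,
) -> tuple[np.ndarray, list]:
    """Lloyd-relaxed bounded Voronoi tessellation of [0, L]^2.

    ``fixed_sites`` stay put (vessel centres); ``n_free`` additional sites
    are seeded uniformly and relaxed to their region centroids.  Regions are
    bounded by mirroring all sites across the four walls, so the returned
    polygons exactly tile the square.
    """
    from scipy.spatial import Voronoi

    free = rng.uniform(0.02 * L, 0.98 * L, size=(n_free, 2))
    n_fixed = len(fixed_sites)
    for it in range(n_iter + 1):
        sites = np.vstack([fixed_sites, free]) if n_fixed else free
        mirrored = [sites]
        for dim, wall in ((0, 0.0), (0, L), (1, 0.0), (1, L)):
            m = sites.copy()
            m[:, dim] = 2 * wall - m[:, dim]
            mirrored.append(m)
        vor = Voronoi(np.vstack(mirrored))
        polys = []
        for i in range(len(sites)):
            reg = vor.regions[vor.point_region[i]]
            polys.append(shapely.Polygon(vor.vertices[reg]))
        if it == n_iter:
            return sites, polys
        # move free sites to their region centroids
        for k in range(n_free):
            c = polys[n_fixed + k].centroid
            free[k] = (c.x, c.y)


def _polygon_moments(poly) -> tuple[float, float, float]:
    """Area-normalised central second moments (Cxx, Cyy, Cxy) of a polygon."""
    x, y = np.asarray(poly.exterior.coords).T
    cross = x[:-1] * y[1:] - x[1:] * y[:-1]
    a = cross.sum() / 2.0
    cx = ((x[:-1] + x[1:]) * cross).sum() / (6.0 * a)
    cy = ((y[:-1] + y[1:]) * cross).sum() / (6.0 * a)
    sxx = ((x[:-1] ** 2 + x[:-1] * x[1:] + x[1:] ** 2) * cross).sum() / 12.0
    syy = ((y[:-1] ** 2 + y[:-1] * y[1:] + y[1:] ** 2) * cross).sum() / 12.0
    sxy = (
        (x[:-1] * y[1:] + 2 * x[:-1] * y[:-1] + 2 * x[1:] * y[1:] + x[1:] * y[:-1])
        * cross
    ).sum() / 24.0
    return sxx / a - cx**2, syy / a - cy**2, sxy / a - cx * cy


def _inscribe_ellipse(poly) -> Ellipse | None:
    """Largest inscribed ellipse with orientation/axis ratio from moments.

    For a fixed orientation and axis ratio, the largest inscribed ellipse
    maps to the largest inscribed circle of an affinely stretched polygon,
    which the pole-of-inaccessibility algorithm solves directly.
    """
    from shapely.ops import polylabel

    if poly.is_empty or poly.area <= 0:
        return None
    if poly.geom_type != "Polygon":  # erosion can split slivers off
        poly = max(poly.geoms, key=lambda g: g.area)
    cxx, cyy, cxy = _polygon_moments(poly)
    evals, evecs = np.linalg.eigh(np.array([[cxx, cxy], [cxy, cyy]]))
    m_ratio = math.sqrt(max(evals[0], 1e-30) / max(evals[1], 1e-30))
    ang = math.atan2(evecs[1, 1], evecs[0, 1])
    rings = [np.asarray(poly.exterior.coords)] + [
        np.asarray(hole.coords) for hole in poly.interiors
    ]
    best: Ellipse | None = None
    for ratio in [min(1.0, max(0.55, m_ratio)), 0.7, 0.8, 0.9, 1.0]:
        ca, sa = math.cos(-ang), math.sin(-ang)
        tr = [
            np.column_stack([(ca * xy[:, 0] - sa * xy[:, 1]),
                             (sa * xy[:, 0] + ca * xy[:, 1]) / ratio])
            for xy in rings
        ]
        stretched = shapely.Polygon(tr[0], holes=tr[1:])
        if stretched.is_empty or stretched.area <= 0:
            continue
        p = polylabel(stretched, tolerance=0.004 * math.sqrt(stretched.area))
        r = stretched.boundary.distance(p)
        if r <= 0:
            continue
        ux, uy = p.x, p.y * ratio
        cb, sb = math.cos(ang), math.sin(ang)
        center = (cb * ux - sb * uy, sb * ux + cb * uy)
        cand = Ellipse(center, (r, r * ratio), ang)
        if best is None or cand.area > best.area:
            best = cand
    return best


def _grow_cells(
    cells: list[Ellipse],
    vessels: list[Vessel],
    L: float,
    clearance: float,
    max_semi: float,
    n_iter: int = 4,
) -> list[Ellipse]:
    """Iteratively re-inscribe each cell into its actual free neighbourhood.

    The Voronoi partition wastes the polygon corners; letting every cell
    re-inscribe against the current shapes of its neighbours (sequentially,
    so no two cells claim the same gap) recovers most of that space while
    preserving the ``clearance`` separation.
    """
    from scipy.spatial import cKDTree

    vessel_halo = [v.to_polygon(32).buffer(clearance) for v in vessels]
    box = shapely.box(0.5 * clearance, 0.5 * clearance,
                      L - 0.5 * clearance, L - 0.5 * clearance)
    cells = list(cells)
    polys = [c.to_polygon(24) for c in cells]
    for _ in range(n_iter):
        centers = np.array([c.center for c in cells])
        kd = cKDTree(centers)
        for i in range(len(cells)):
            c = cells[i]
            R = 3.0 * max(max_semi, max(c.semi_axes)) + 2 * clearance
            nbrs = [j for j in kd.query_ball_point(c.center, R) if j != i]
            blockers = [polys[j].buffer(clearance) for j in nbrs]
            blockers += [h for h in vessel_halo
                         if h.distance(shapely.Point(c.center)) < R]
            local = shapely.box(c.center[0] - R, c.center[1] - R,
                                c.center[0] + R, c.center[1] + R).intersection(box)
            region = local.difference(shapely.union_all(blockers)) if blockers else local
            if region.is_empty:
                continue
            if region.geom_type != "Polygon":
                pt = shapely.Point(c.center)
                parts = [g for g in region.geoms if g.geom_type == "Polygon"]
                if not parts:
                    continue
                region = min(parts, key=lambda g: g.distance(pt))
            e = _inscribe_ellipse(region)
            if e is None:
                continue
            if e.semi_axes[0] > max_semi:
                s = max_semi / e.semi_axes[0]
                e = Ellipse(e.center, (max_semi, e.semi_axes[1] * s), e.angle)
            drift = math.hypot(e.center[0] - c.center[0], e.center[1] - c.center[1])
            # keep the grown ellipse well inside the neighbourhood that was
            # actually checked for blockers
            if drift + e.semi_axes[0] > R - max_semi - 2 * clearance:
                continue
            if e.area > c.area:
                cells[i] = e
                polys[i] = e.to_polygon(24)
    return cells


def _pocket_fill(
    rng: np.random.Generator,
    L: float,
    cells: list[Ellipse],
    vessels: list[Vessel],
    eis_target_area: float,
    eis_area: float,
    clearance: float,
    min_semi: float,
    max_semi: float,
) -> tuple[list[Ellipse], float]:
    """Greedy filling of interstitial pockets with small round cells.

    A grid of candidate sites tracks the clearance to the nearest placed
    shape (approximated by the distance to a dense sample of shape-boundary
    vertices); the widest pocket is filled first with the largest cell that
    fits, so acceptance never fails and the packing terminates quickly.
    """
    from scipy.spatial import cKDTree

    cells = list(cells)
    inflated = [v.to_polygon(32).buffer(clearance) for v in vessels]
    inflated += [c.to_polygon(24).buffer(clearance) for c in cells]
    kd = cKDTree(np.vstack([np.asarray(p.exterior.coords) for p in inflated]))

    spacing = 1.5e-3 * (L / 0.25)
    ax = np.arange(0.5 * spacing, L, spacing)
    sx, sy = np.meshgrid(ax, ax, indexing="ij")
    sites = np.column_stack([sx.ravel(), sy.ravel()])
    d, _ = kd.query(sites, k=1)
    # stay fully inside the tile (half a clearance from each wall)
    wall = np.minimum.reduce([sites[:, 0], sites[:, 1], L - sites[:, 0], L - sites[:, 1]])
    d = np.minimum(d, wall - 0.5 * clearance)
    d -= 0.3e-3  # safety margin for the vertex-sampled distance field
    # sites inside a shape or its clearance halo are not candidates at all
    occupied = shapely.union_all(inflated)
    d[shapely.contains_xy(occupied, sites[:, 0], sites[:, 1])] = 0.0

    while eis_target_area - eis_area > 0.002 * L * L:
        i = int(np.argmax(d))
        r = min(float(d[i]), max_semi)
        deficit = eis_target_area - eis_area
        r = min(r, math.sqrt(deficit / math.pi) + min_semi)
        if r < min_semi:
            break
        q = float(rng.uniform(0.85, 1.0))
        ang = float(rng.uniform(0.0, math.pi))
        cand = Ellipse((float(sites[i, 0]), float(sites[i, 1])), (r, r * q), ang)
        cells.append(cand)
        eis_area += cand.area
        ring = np.asarray(cand.to_polygon(24).buffer(clearance).exterior.coords)
        local = cKDTree(ring)
        # every site whose stored clearance could now be stale: the new cell
        # lowers d wherever dist_to_centre - (r + clearance) < current d
        cdist = np.hypot(sites[:, 0] - sites[i, 0], sites[:, 1] - sites[i, 1])
        affected = np.flatnonzero(cdist < d + r + clearance + 1e-3)
        if len(affected):
            dn, _ = local.query(sites[affected], k=1)
            inside = shapely.contains_xy(
                shapely.Polygon(ring), sites[affected, 0], sites[affected, 1]
            )
            dn[inside] = 0.0
            d[affected] = np.minimum(d[affected], dn - 0.3e-3)
        d[i] = 0.0
    return cells, eis_area


def generate_domain(
    voxel_side: float = 0.25,
    target_ve: float = 0.39,
    target_vp: float = 0.03,
    cell_diameter_mean: float = 0.014,
    vessel_diameter_mean: float = 0.008,
    seed: int = 0,
    *,
    clearance: float = 2e-3,
) -> TissueDomain:
    """Pack one voxel with vessels and cells to hit the target fractions.

    Vessels are ``round(target_vp * L^2 / vessel_area)`` discs of fixed
    diameter placed by farthest-point sampling, so the vasculature is
    spaced across the voxel.  Cells are built by inscribing ellipses into a
    Lloyd-relaxed Voronoi partition of the remaining space (cell count set
    by ``cell_diameter_mean``), then shrinking all of them by a common
    factor until the intracellular fraction matches
    ``1 - target_ve - vp_achieved``; if the inscribed set cannot reach the
    target on its own, remaining interstitial pockets are filled greedily
    with small round cells.  The construction keeps every inter-cell channel
    at least ``clearance`` wide, which a boundary-conforming mesh can
    resolve; plain random sequential addition of 14 µm ellipses cannot reach
    a 58 % intracellular fraction without leaving sub-micron channels.

    Raises
    ------
    ValueError
        If the requested fractions are impossible.
    PackingError
        If the achievable intracellular fraction falls short of the target.
    """
    if voxel_side <= 0:
        raise ValueError("voxel_side must be positive")
    if not (0 < target_ve and 0 < target_vp):
        raise ValueError("target fractions must be positive")
    if target_ve + target_vp > 1.0:
        raise ValueError("target_ve + target_vp must not exceed 1")

    rng = np.random.default_rng(seed)
    L = voxel_side
    A = L * L

    # --- vessels ---------------------------------------------------------
    r_v = vessel_diameter_mean / 2.0
    n_vessels = int(round(target_vp * A / (math.pi * r_v**2)))
    n_vessels = max(n_vessels, 1)
    margin = r_v + clearance
    sites = _farthest_point_sites(rng, n_vessels, margin, L - margin)
    vessels = [Vessel((float(x), float(y)), r_v) for x, y in sites]
    vp_achieved = sum(v.area for v in vessels) / A
    if abs(vp_achieved - target_vp) > 0.005:
        raise PackingError(
            f"vessel packing reached vp={vp_achieved:.4f}, target {target_vp:.4f}"
        )

    # --- cells: inscribed ellipses in a Lloyd-relaxed Voronoi partition --
    eis_target = 1.0 - target_ve - vp_achieved
    n_cells = max(1, int(round(eis_target * A / (math.pi * (cell_diameter_mean / 2) ** 2))))
    if eis_target * A < 0.25 * math.pi * (0.5 * cell_diameter_mean) ** 2:
        # no meaningful intracellular space requested
        veis_achieved = 0.0
        ve_achieved = 1.0 - vp_achieved
        return TissueDomain(
            voxel_side=L, cells=[], vessels=vessels, ve_achieved=ve_achieved,
            vp_achieved=vp_achieved, veis_achieved=veis_achieved, seed=seed, tiles=1,
        )
    vessel_sites = np.array([v.center for v in vessels])
    _, polys = _lloyd_voronoi_polygons(rng, L, vessel_sites, n_cells)
    inscribed: list[Ellipse] = []
    for poly in polys[len(vessels):]:
        e = _inscribe_ellipse(poly.buffer(-0.5 * clearance))
        if e is not None:
            inscribed.append(e)
    # let cells expand into the corner space their Voronoi polygons wasted
    inscribed = _grow_cells(
        inscribed, vessels, L, clearance, max_semi=0.68 * cell_diameter_mean
    )
    a_max = sum(e.area for e in inscribed)
    lam = math.sqrt(min(1.0, eis_target * A / a_max)) if a_max > 0 else 1.0
    cells = [
        Ellipse(e.center, (lam * e.semi_axes[0], lam * e.semi_axes[1]), e.angle)
        for e in inscribed
        if 2 * lam * max(e.semi_axes) >= 0.15 * cell_diameter_mean
    ]
    # a vessel disc is not guaranteed to sit inside its own Voronoi region:
    # shrink any cell that comes closer to a vessel than half a clearance
    vessel_halo = [v.to_polygon(32).buffer(0.45 * clearance) for v in vessels]
    vtree = STRtree(vessel_halo)
    for k, c in enumerate(cells):
        hit = vtree.query(c.to_polygon(24))
        for vi in hit:
            while vessel_halo[vi].intersects(c.to_polygon(24)) and max(c.semi_axes) > 1e-5:
                c = Ellipse(c.center, (0.95 * c.semi_axes[0], 0.95 * c.semi_axes[1]), c.angle)
            cells[k] = c
    eis_area = sum(c.area for c in cells)

    # --- top-up: fill remaining interstitial pockets with small cells,
    # letting the filled packing re-grow once more if still short ----------
    for round_ in range(4):
        if eis_target * A - eis_area <= 0.002 * A:
            break
        cells, eis_area = _pocket_fill(
            rng, L, cells, vessels, eis_target * A, eis_area, clearance,
            min_semi=0.1 * cell_diameter_mean,
            max_semi=0.45 * cell_diameter_mean,
        )
        if eis_target * A - eis_area <= 0.002 * A:
            break
        cells = _grow_cells(cells, vessels, L, clearance,
                            max_semi=0.68 * cell_diameter_mean, n_iter=2)
        eis_area = sum(c.area for c in cells)
    if eis_area > eis_target * A:
        # trim any regrowth overshoot back to the exact target; a uniform
        # shrink can only widen clearances
        lam = math.sqrt(eis_target * A / eis_area)
        cells = [
            Ellipse(c.center, (lam * c.semi_axes[0], lam * c.semi_axes[1]), c.angle)
            for c in cells
        ]
        eis_area = sum(c.area for c in cells)
    if eis_target * A - eis_area > 0.0095 * A:
        raise PackingError(
            f"cell packing stalled at EIS fraction {eis_area / A:.4f} "
            f"(target {eis_target:.4f})"
        )

    veis_achieved = eis_area / A
    ve_achieved = 1.0 - vp_achieved - veis_achieved
    if abs(ve_achieved - target_ve) > 0.01:
        raise PackingError(
            f"packing reached ve={ve_achieved:.4f}, target {target_ve:.4f}"
        )
    return TissueDomain(
        voxel_side=L,
        cells=cells,
        vessels=vessels,
        ve_achieved=ve_achieved,
        vp_achieved=vp_achieved,
        veis_achieved=veis_achieved,
        seed=seed,
        tiles=1,
    )


def tile_extended_domain(domain: TissueDomain) -> TissueDomain:
    """Surround the voxel with eight identical copies (3x3 periodic tiling).

    The returned domain spans ``[0, 3L]^2`` with the original voxel occupying
    the central tile ``[L, 2L]^2``; area fractions are unchanged.
    """
    if domain.tiles != 1:
        raise ValueError("can only tile a single-voxel domain")
    L = domain.voxel_side
    cells: list[Ellipse] = []
    vessels: list[Vessel] = []
    for i in range(3):
        for j in range(3):
            dx, dy = i * L, j * L
            cells.extend(c.translated(dx, dy) for c in domain.cells)
            vessels.extend(v.translated(dx, dy) for v in domain.vessels)
    return TissueDomain(
        voxel_side=L,
        cells=cells,
        vessels=vessels,
        ve_achieved=domain.ve_achieved,
        vp_achieved=domain.vp_achieved,
        veis_achieved=domain.veis_achieved,
        seed=domain.seed,
        tiles=3,
    )
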