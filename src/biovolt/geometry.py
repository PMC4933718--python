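"""Dual-grid world geometry.

The tissue is modelled on two interacting grids:

* an irregular Voronoi *cell grid* — one polygon per cell, with per-edge
  ("membrane") midpoints, outward normals, areas, and gap-junction pairing
  between the coincident membranes of adjacent cells;
* a regular square *environment grid* whose nodes are tagged internal or
  external to the cell cluster, carrying the continuous extracellular
  electrolyte.

Cluster shape, wounds and region assignments are defined by binary raster
masks (`RegionMask`).  A conservative nearest-node mapping
(`MappingWeights`) transfers moles between membranes and environment nodes
without creating or destroying mass.

Conventions: world origin at the lower-left corner of the mask raster,
raster row 0 = bottom, SI metres throughout.  Cell areas are converted to
volumes with the system height ``h``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.ops import unary_union, voronoi_diagram
from skimage import measure

__all__ = [
    "RegionMask",
    "CellGrid",
    "EnvGrid",
    "MappingWeights",
    "build_cell_grid",
    "cell_grid_from_seeds",
    "build_env_grid",
    "map_membranes_to_env",
    "cut_region",
    "disc_mask",
    "square_mask",
]

# coordinate quantum for matching coincident membrane midpoints, m
_COORD_TOL = 1.0e-10


@dataclass
class RegionMask:
    """Binary raster in world coordinates.

    ``pixels`` is a boolean array with row 0 at the *bottom* of the world;
    ``extent`` is the (width, height) of the raster in metres with the world
    origin at its lower-left corner.  ``role`` tags the intent (cluster
    shape, wound, or profile assignment).
    """

    pixels: np.ndarray
    extent: tuple[float, float]
    role: str = "cluster"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask raster must be 2-D")
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValueError("mask extent must be positive")

    @property
    def pixel_size(self) -> tuple[float, float]:
        ny, nx = self.pixels.shape
        return self.extent[0] / nx, self.extent[1] / ny

    @property
    def area(self) -> float:
        """Raster area of the included region (pixel count times pixel area)."""
        px, py = self.pixel_size
        return float(self.pixels.sum()) * px * py

    def polygon(self) -> Polygon:
        """Included region as a (multi)polygon via marching squares."""
        if not self.pixels.any():
            raise ValueError("no cells: mask is empty")
        px, py = self.pixel_size
        padded = np.pad(self.pixels.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        polys = []
        for c in contours:
            # (row, col) in padded index space -> world, pixel centres at
            # ((col+0.5)px, (row+0.5)py) before padding
            x = (c[:, 1] - 1 + 0.5) * px
            y = (c[:, 0] - 1 + 0.5) * py
            p = Polygon(np.column_stack([x, y]))
            if p.is_valid and p.area > 0:
                polys.append(p)
        if not polys:
            raise ValueError("no cells: mask region degenerate")
        # outer contours contain hole contours; unary_union with buffer(0)
        # keeps orientation handling simple for the shapes we support
        polys.sort(key=lambda p: p.area, reverse=True)
        region = polys[0]
        for p in polys[1:]:
            if region.contains(p.representative_point()):
                region = region.difference(p)
            else:
                region = region.union(p)
        return region

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Raster lookup: which points fall on an included pixel."""
        xy = np.atleast_2d(xy)
        px, py = self.pixel_size
        col = np.floor(xy[:, 0] / px).astype(int)
        row = np.floor(xy[:, 1] / py).astype(int)
        ny, nx = self.pixels.shape
        ok = (col >= 0) & (col < nx) & (row >= 0) & (row < ny)
        out = np.zeros(len(xy), dtype=bool)
        out[ok] = self.pixels[row[ok], col[ok]]
        return out


def disc_mask(diameter: float, n_pixels: int = 200, margin: float = 0.15,
              role: str = "cluster") -> RegionMask:
    """Circular cluster mask of the given diameter (m), centred in the world."""
    side = diameter * (1.0 + 2.0 * margin)
    px = side / n_pixels
    c = np.arange(n_pixels) * px + px / 2.0
    xx, yy = np.meshgrid(c, c)
    r2 = (xx - side / 2) ** 2 + (yy - side / 2) ** 2
    return RegionMask(r2 <= (diameter / 2) ** 2, (side, side), role)


def square_mask(side: float, n_pixels: int = 100, margin: float = 0.1,
                role: str = "cluster") -> RegionMask:
    """Square cluster mask of the given side length (m), centred in the world."""
    world = side * (1.0 + 2.0 * margin)
    px = world / n_pixels
    c = np.arange(n_pixels) * px + px / 2.0
    xx, yy = np.meshgrid(c, c)
    lo, hi = (world - side) / 2.0, (world + side) / 2.0
    inside = (xx >= lo) & (xx <= hi) & (yy >= lo) & (yy <= hi)
    return RegionMask(inside, (world, world), role)


@dataclass
class CellGrid:
    """Voronoi cell mesh with per-membrane geometry.

    Membranes are polygon edges; the i-th cell's membranes are contiguous in
    the flat membrane arrays.  ``gj_pairs`` holds (membrane_a, membrane_b)
    index pairs for the two coincident membranes of each cell-cell
    interface; membranes without a partner are flagged boundary.
    """

    cell_centers: np.ndarray        # (n_cell, 2), m
    cell_areas: np.ndarray          # (n_cell,), m^2 (polygon area)
    cell_volumes: np.ndarray        # (n_cell,), m^3 (= area * h)
    cell_polys: list                # list of (k,2) vertex arrays (CCW)
    membrane_midpoints: np.ndarray  # (n_mem, 2), m
    membrane_normals: np.ndarray    # (n_mem, 2), unit, outward
    membrane_tangents: np.ndarray   # (n_mem, 2), unit
    membrane_lengths: np.ndarray    # (n_mem,), m
    membrane_areas: np.ndarray      # (n_mem,), m^2 (= length * h)
    membrane_to_cell: np.ndarray    # (n_mem,), int
    gj_pairs: np.ndarray            # (n_gj, 2), membrane indices
    boundary_flags: np.ndarray      # (n_mem,), bool
    h: float
    d_gj: float
    world_extent: tuple[float, float]
    cluster_polygon: object = field(repr=False, default=None)

    @property
    def n_cells(self) -> int:
        return len(self.cell_centers)

    @property
    def n_membranes(self) -> int:
        return len(self.membrane_midpoints)

    @property
    def n_gj(self) -> int:
        return len(self.gj_pairs)

    @property
    def gj_cell_pairs(self) -> np.ndarray:
        """(n_gj, 2) cell indices on either side of each gap junction."""
        return self.membrane_to_cell[self.gj_pairs]

    @property
    def cell_surface_areas(self) -> np.ndarray:
        """Total membrane area per cell (sigma_cell), m^2."""
        out = np.zeros(self.n_cells)
        np.add.at(out, self.membrane_to_cell, self.membrane_areas)
        return out

    @property
    def gj_lengths(self) -> np.ndarray:
        """Centre-to-centre distance across each gap junction edge, m."""
        pairs = self.gj_cell_pairs
        d = self.cell_centers[pairs[:, 0]] - self.cell_centers[pairs[:, 1]]
        return np.linalg.norm(d, axis=1)


def _polygon_membranes(poly_xy: np.ndarray, h: float):
    """Per-edge geometry for one CCW polygon: mid, normal, tangent, length."""
    a = poly_xy
    b = np.roll(poly_xy, -1, axis=0)
    edge = b - a
    length = np.linalg.norm(edge, axis=1)
    keep = length > _COORD_TOL
    a, b, edge, length = a[keep], b[keep], edge[keep], length[keep]
    tangent = edge / length[:, None]
    # CCW polygon: outward normal is the tangent rotated -90 degrees
    normal = np.column_stack([tangent[:, 1], -tangent[:, 0]])
    mid = 0.5 * (a + b)
    return mid, normal, tangent, length


def _ccw(coords: np.ndarray) -> np.ndarray:
    """Drop the closing vertex and force counter-clockwise orientation."""
    xy = np.asarray(coords)
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    area2 = np.sum(xy[:, 0] * np.roll(xy[:, 1], -1)
                   - np.roll(xy[:, 0], -1) * xy[:, 1])
    return xy if area2 > 0 else xy[::-1]


def _grid_from_polys(polys: list[Polygon], h: float, d_gj: float,
                     extent, cluster_polygon) -> CellGrid:
    centers, areas, cell_polys = [], [], []
    mids, normals, tangents, lengths, mem_cell = [], [], [], [], []
    for i, p in enumerate(polys):
        xy = _ccw(np.asarray(p.exterior.coords))
        cell_polys.append(xy)
        centers.append([p.centroid.x, p.centroid.y])
        areas.append(p.area)
        m, n, t, l = _polygon_membranes(xy, h)
        mids.append(m)
        normals.append(n)
        tangents.append(t)
        lengths.append(l)
        mem_cell.append(np.full(len(m), i))
    mids = np.concatenate(mids)
    mem_cell = np.concatenate(mem_cell)
    lengths = np.concatenate(lengths)

    # pair coincident membrane midpoints of different cells -> gap junctions
    key = np.round(mids / _COORD_TOL).astype(np.int64)
    seen: dict[tuple, int] = {}
    pairs = []
    partner = np.full(len(mids), -1)
    for m_idx in range(len(mids)):
        k = (key[m_idx, 0], key[m_idx, 1])
        if k in seen and mem_cell[seen[k]] != mem_cell[m_idx]:
            pairs.append((seen[k], m_idx))
            partner[m_idx] = seen[k]
            partner[seen[k]] = m_idx
        else:
            seen[k] = m_idx
    gj_pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)

    areas = np.asarray(areas)
    return CellGrid(
        cell_centers=np.asarray(centers),
        cell_areas=areas,
        cell_volumes=areas * h,
        cell_polys=cell_polys,
        membrane_midpoints=mids,
        membrane_normals=np.concatenate(normals),
        membrane_tangents=np.concatenate(tangents),
        membrane_lengths=lengths,
        membrane_areas=lengths * h,
        membrane_to_cell=mem_cell,
        gj_pairs=gj_pairs,
        boundary_flags=partner < 0,
        h=h,
        d_gj=d_gj,
        world_extent=tuple(extent),
        cluster_polygon=cluster_polygon,
    )


def build_cell_grid(shape_mask: RegionMask, target_cell_radius: float,
                    rng_seed: int, h: float = 10.0e-6,
                    d_gj: float = 26.0e-9,
                    jitter: float = 0.15) -> CellGrid:
    """Build the Voronoi cell grid filling a raster mask.

    Seeds are placed on a jittered hexagonal lattice (jitter amplitude
    ``jitter * target_cell_radius``, seeded RNG, so grids are reproducible),
    Voronoi cells are clipped to the mask polygon, and sliver cells with
    area < 10% of the median are merged into their largest neighbour.
    Membranes lacking a partner membrane on a neighbouring cell are flagged
    boundary.
    """
    if target_cell_radius <= 0:
        raise ValueError("target_cell_radius must be positive")
    region = shape_mask.polygon()  # raises "no cells" on empty mask
    rng = np.random.default_rng(rng_seed)

    # hexagonal lattice with cell area ~ pi r^2
    a = target_cell_radius * np.sqrt(2 * np.pi / np.sqrt(3.0))
    wx, wy = shape_mask.extent
    cols = np.arange(-1, int(np.ceil(wx / a)) + 2)
    rows = np.arange(-1, int(np.ceil(wy / (a * np.sqrt(3) / 2))) + 2)
    seeds = []
    for r in rows:
        y = r * a * np.sqrt(3) / 2
        x0 = (a / 2) if (r % 2) else 0.0
        for c in cols:
            seeds.append((x0 + c * a, y))
    seeds = np.asarray(seeds)
    seeds = seeds + rng.uniform(-jitter, jitter,
                                seeds.shape) * target_cell_radius
    inside = shapely.contains_xy(region, seeds[:, 0], seeds[:, 1])
    seeds = seeds[inside]
    if len(seeds) == 0:
        # radius larger than the mask: degenerate single cell at the centroid
        seeds = np.asarray([[region.centroid.x, region.centroid.y]])

    return cell_grid_from_seeds(seeds, shape_mask, h=h, d_gj=d_gj,
                                region=region)


def cell_grid_from_seeds(seeds: np.ndarray, shape_mask: RegionMask,
                         h: float = 10.0e-6, d_gj: float = 26.0e-9,
                         region: Polygon | None = None) -> CellGrid:
    """Voronoi cell grid from explicit seed points clipped to a mask."""
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if region is None:
        region = shape_mask.polygon()
    wx, wy = shape_mask.extent
    if len(seeds) == 1:
        polys = [region]
    else:
        env = box(-wx, -wy, 2 * wx, 2 * wy)
        vd = voronoi_diagram(MultiPoint(seeds), envelope=env)
        cells = list(vd.geoms)
        tree = shapely.STRtree(cells)
        polys = []
        for s in seeds:
            pt = Point(s)
            idx = tree.query(pt, predicate="within")
            raw = cells[idx[0]] if len(idx) else cells[
                int(tree.nearest(pt))]
            clipped = raw.intersection(region)
            if clipped.is_empty:
                continue
            if clipped.geom_type == "MultiPolygon":
                parts = list(clipped.geoms)
                parts.sort(key=lambda p: (p.contains(pt), p.area))
                clipped = parts[-1]
            if clipped.area > 0:
                polys.append(clipped)
        # merge slivers into their largest neighbour
        if polys:
            med = np.median([p.area for p in polys])
            big = [p for p in polys if p.area >= 0.1 * med]
            small = [p for p in polys if p.area < 0.1 * med]
            for s_poly in small:
                neigh = [i for i, p in enumerate(big)
                         if p.intersects(s_poly)
                         and p.intersection(s_poly).length > 0]
                if neigh:
                    j = max(neigh, key=lambda i: big[i].area)
                    big[j] = unary_union([big[j], s_poly])
                else:
                    big.append(s_poly)
            polys = big
    if not polys:
        raise ValueError("no cells: zero cells result from mask and radius")
    return _grid_from_polys(polys, h, d_gj, shape_mask.extent, region)


@dataclass
class EnvGrid:
    """Regular square environment grid.

    Nodes are stored flattened row-major with row 0 at the bottom.  Internal
    nodes (inside the cluster hull) carry the thin extracellular-cleft
    electrolyte; external nodes carry bulk environment.  ``boundary_nodes``
    is the outer rim of the domain, where Dirichlet conditions apply.
    """

    nx: int
    ny: int
    spacing: float                 # m
    node_xy: np.ndarray            # (n, 2)
    inside_mask: np.ndarray        # (n,) bool
    boundary_nodes: np.ndarray     # (n_b,) int

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny


def build_env_grid(world_extent, n_nodes_per_side: int,
                   cell_grid: CellGrid | None = None) -> EnvGrid:
    """Uniform n x n node grid spanning the world extent.

    Nodes inside the cluster polygon are tagged internal; the outer rim of
    nodes forms the global Dirichlet boundary.  Rejects extents that do not
    cover the cell cluster.
    """
    wx, wy = world_extent
    n = int(n_nodes_per_side)
    if n < 2:
        raise ValueError("need at least 2 nodes per side")
    if cell_grid is not None and cell_grid.n_cells > 0:
        c = cell_grid.cell_centers
        if (c[:, 0].min() < 0 or c[:, 0].max() > wx
                or c[:, 1].min() < 0 or c[:, 1].max() > wy):
            raise ValueError("environment extent smaller than cell cluster")
    dx = wx / (n - 1)
    xs = np.arange(n) * dx
    ys = np.arange(n) * (wy / (n - 1))
    xx, yy = np.meshgrid(xs, ys)
    node_xy = np.column_stack([xx.ravel(), yy.ravel()])
    if cell_grid is not None and cell_grid.cluster_polygon is not None \
            and cell_grid.n_cells > 0:
        inside = shapely.contains_xy(
            unary_union([Polygon(p) for p in cell_grid.cell_polys]),
            node_xy[:, 0], node_xy[:, 1])
    else:
        inside = np.zeros(len(node_xy), dtype=bool)
    idx = np.arange(n * n).reshape(n, n)
    boundary = np.unique(np.concatenate(
        [idx[0, :], idx[-1, :], idx[:, 0], idx[:, -1]]))
    return EnvGrid(nx=n, ny=n, spacing=dx, node_xy=node_xy,
                   inside_mask=np.asarray(inside), boundary_nodes=boundary)


@dataclass
class MappingWeights:
    """Conservative membrane <-> environment-node mapping.

    Nearest-node assignment: each membrane sends its entire mole transfer to
    the single closest environment node (weights per membrane sum to 1 by
    construction, so the forward transfer conserves moles exactly), and
    reads its local extracellular value back from the same node.
    """

    node_of_membrane: np.ndarray   # (n_mem,), int
    n_nodes: int

    def forward(self, per_membrane: np.ndarray) -> np.ndarray:
        """Accumulate per-membrane quantities (e.g. moles) onto env nodes."""
        out = np.zeros(self.n_nodes)
        np.add.at(out, self.node_of_membrane, per_membrane)
        return out

    def reverse(self, node_field: np.ndarray) -> np.ndarray:
        """Membrane-local value of an environment node field."""
        return np.asarray(node_field)[self.node_of_membrane]

    def matrix(self):
        """Sparse (n_nodes x n_mem) forward-transfer matrix."""
        from scipy import sparse
        n_mem = len(self.node_of_membrane)
        return sparse.csr_matrix(
            (np.ones(n_mem), (self.node_of_membrane, np.arange(n_mem))),
            shape=(self.n_nodes, n_mem))


def map_membranes_to_env(cell_grid: CellGrid, env_grid: EnvGrid) -> MappingWeights:
    """Assign every membrane to its nearest environment node."""
    from scipy.spatial import cKDTree
    mids = cell_grid.membrane_midpoints
    wx = (env_grid.nx - 1) * env_grid.spacing
    wy = (env_grid.ny - 1) * env_grid.spacing
    if len(mids) and ((mids[:, 0].min() < -env_grid.spacing)
                      or (mids[:, 0].max() > wx + env_grid.spacing)
                      or (mids[:, 1].min() < -env_grid.spacing)
                      or (mids[:, 1].max() > wy + env_grid.spacing)):
        raise ValueError("membrane outside environment extent")
    tree = cKDTree(env_grid.node_xy)
    _, nearest = tree.query(mids)
    return MappingWeights(node_of_membrane=np.asarray(nearest, dtype=int),
                          n_nodes=env_grid.n_nodes)


def cut_region(cell_grid: CellGrid, wound_mask: RegionMask):
    """Remove the cells whose centres fall in a wound mask.

    Returns ``(new_grid, kept_cells, kept_membranes)`` where the index
    arrays map new entries back to the old grid so that callers (the
    engine) can re-index state arrays consistently.  Exposed membranes of
    surviving neighbours become boundary membranes automatically because
    their partner membranes are gone; the removed footprint reverts to
    continuous environment (it is no longer covered by any cell polygon).
    """
    hit = wound_mask.contains(cell_grid.cell_centers)
    if not hit.any():
        raise ValueError("wound mask overlaps no cell centers")
    if hit.all():
        raise ValueError("wound mask removes all cells")
    kept_cells = np.flatnonzero(~hit)
    polys = [Polygon(cell_grid.cell_polys[i]) for i in kept_cells]
    new_grid = _grid_from_polys(polys, cell_grid.h, cell_grid.d_gj,
                                cell_grid.world_extent,
                                cell_grid.cluster_polygon)
    kept_membranes = np.flatnonzero(
        np.isin(cell_grid.membrane_to_cell, kept_cells))
    return new_grid, kept_cells, kept_membranes
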