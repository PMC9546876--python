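"""Circular multicellular lattice: equal-area polygonal cells in the unit disk.

A simulated cell island is represented as a centroidal Voronoi tessellation of
the unit disk, obtained by seeded Lloyd relaxation of random generator points.
This reproduces the geometry of a ~600 µm circular micropatterned colony:
roughly isotropic polygonal cells of near-equal area, an adjacency graph given
by shared membrane (polygon edges), and a normalized radial coordinate per
cell. Coordinates are dimensionless with disk radius 1; cell indices are
0-based.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon

logger = logging.getLogger(__name__)

#: number of quadrant segments used to polygonize the unit disk; the resulting
#: 256-gon differs from the true disk area by ~1e-4 relative.
_DISK_QUAD_SEGS = 64

#: minimum shared-edge length for two cells to count as neighbors.
_EDGE_EPS = 1e-9


def _unit_disk() -> Polygon:
    return Point(0.0, 0.0).buffer(1.0, quad_segs=_DISK_QUAD_SEGS)


@dataclass
class Lattice:
    """Polygonal tessellation of the unit disk with adjacency and radii.

    Attributes
    ----------
    n_cells : int
        Number of cells.
    polygons : list of (k, 2) ndarray
        Vertex loops of each cell in disk coordinates.
    centroids : (n, 2) ndarray
    areas : (n,) ndarray
    adjacency : list of frozenset of int
        Symmetric, irreflexive shared-edge neighbor sets.
    radius : (n,) ndarray
        Centroid distance normalized by the top-percentile distance, clipped
        to [0, 1].
    on_rim : (n,) ndarray of bool
        True where the cell polygon touches the disk boundary.
    seed : int
    converged : bool
        Whether Lloyd relaxation met its displacement tolerance.
    """

    n_cells: int
    polygons: list
    centroids: np.ndarray
    areas: np.ndarray
    adjacency: list
    radius: np.ndarray
    on_rim: np.ndarray
    seed: int
    converged: bool = True
    _adj_matrix: object = field(default=None, repr=False, compare=False)

    def neighbor_matrix(self):
        """Sparse symmetric 0/1 adjacency matrix (CSR)."""
        if self._adj_matrix is None:
            from scipy.sparse import csr_matrix

            rows, cols = [], []
            for i, nb in enumerate(self.adjacency):
                for j in nb:
                    rows.append(i)
                    cols.append(j)
            data = np.ones(len(rows))
            self._adj_matrix = csr_matrix(
                (data, (rows, cols)), shape=(self.n_cells, self.n_cells)
            )
        return self._adj_matrix

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "n_cells": self.n_cells,
            "seed": self.seed,
            "polygons": [p.tolist() for p in self.polygons],
            "centroids": self.centroids.tolist(),
            "areas": self.areas.tolist(),
            "adjacency": [sorted(nb) for nb in self.adjacency],
            "radius": self.radius.tolist(),
            "on_rim": self.on_rim.astype(int).tolist(),
            "converged": bool(self.converged),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "Lattice":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            n_cells=d["n_cells"],
            polygons=[np.asarray(p) for p in d["polygons"]],
            centroids=np.asarray(d["centroids"]),
            areas=np.asarray(d["areas"]),
            adjacency=[frozenset(nb) for nb in d["adjacency"]],
            radius=np.asarray(d["radius"]),
            on_rim=np.asarray(d["on_rim"], dtype=bool),
            seed=d["seed"],
            converged=d.get("converged", True),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "radius": self.radius,
                "on_rim": self.on_rim.astype(int),
            }
        ).to_csv(path, index=False)


def _clipped_voronoi(points: np.ndarray, disk: Polygon):
    """Voronoi cells of `points` clipped to the disk.

    Generators are mirrored radially across the circle so every original
    region is bounded before clipping.
    """
    n = len(points)
    r = np.linalg.norm(points, axis=1)
    r = np.maximum(r, 1e-12)
    mirrors = points / r[:, None] * (2.0 - r)[:, None]
    vor = Voronoi(np.vstack([points, mirrors]))
    polys = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError(f"unbounded Voronoi region for cell {i}")
        poly = Polygon(vor.vertices[region]).intersection(disk)
        polys.append(poly)
    return polys


def generate_lattice(
    n_cells: int,
    seed: int = 0,
    max_relax_iters: int = 100,
    tol: float = 1e-3,
    radius_percentile: float = 95.0,
) -> Lattice:
    """Generate a relaxed polygonal tessellation of the unit disk.

    Random generator points (area-uniform in the disk, seeded) are relaxed by
    Lloyd iteration — each point moves to the centroid of its disk-clipped
    Voronoi cell — until the maximum displacement falls below ``tol`` or
    ``max_relax_iters`` is exhausted. The fixed point is a centroidal Voronoi
    tessellation with near-equal cell areas.

    Parameters
    ----------
    n_cells : int
        Number of cells; must be >= 1.
    seed : int
        RNG seed; identical arguments give bit-identical output.
    max_relax_iters : int
        Lloyd iteration cap.
    tol : float
        Convergence threshold on maximum centroid displacement (disk-radius
        units); must be > 0.
    radius_percentile : float
        Upper percentile of centroid distances used to normalize radius.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")

    disk = _unit_disk()

    if n_cells == 1:
        verts = np.asarray(disk.exterior.coords)[:-1]
        return Lattice(
            n_cells=1,
            polygons=[verts],
            centroids=np.zeros((1, 2)),
            areas=np.array([disk.area]),
            adjacency=[frozenset()],
            radius=np.zeros(1),
            on_rim=np.array([True]),
            seed=seed,
            converged=True,
        )

    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * math.pi, n_cells)
    rad = 0.97 * np.sqrt(rng.uniform(0.0, 1.0, n_cells))
    points = np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
    # seeded jitter breaks cocircular degeneracies in the Voronoi construction
    points = points + rng.normal(0.0, 1e-9, points.shape)

    converged = False
    polys = None
    for _ in range(max_relax_iters):
        polys = _clipped_voronoi(points, disk)
        new_points = np.array([[p.centroid.x, p.centroid.y] for p in polys])
        shift = np.max(np.linalg.norm(new_points - points, axis=1))
        points = new_points
        if shift < tol:
            converged = True
            break
    polys = _clipped_voronoi(points, disk)
    if not converged:
        logger.warning(
            "Lloyd relaxation did not converge in %d iterations", max_relax_iters
        )

    centroids = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    areas = np.array([p.area for p in polys])
    poly_verts = [np.asarray(p.exterior.coords)[:-1] for p in polys]

    adjacency = _shared_edge_adjacency(polys)
    rim_dist = 1.0 - 0.5 * (2.0 * math.pi / (4 * _DISK_QUAD_SEGS)) ** 2
    on_rim = np.array(
        [np.any(np.linalg.norm(v, axis=1) >= rim_dist - 1e-9) for v in poly_verts]
    )
    radius = normalized_radius_from_centroids(centroids, radius_percentile)

    return Lattice(
        n_cells=n_cells,
        polygons=poly_verts,
        centroids=centroids,
        areas=areas,
        adjacency=adjacency,
        radius=radius,
        on_rim=on_rim,
        seed=seed,
        converged=converged,
    )


def _shared_edge_adjacency(polys) -> list:
    """Neighbor sets from positive-length polygon boundary intersections."""
    n = len(polys)
    adjacency = [set() for _ in range(n)]
    bounds = np.array([p.bounds for p in polys])
    for i in range(n):
        for j in range(i + 1, n):
            if (
                bounds[i, 2] < bounds[j, 0] - _EDGE_EPS
                or bounds[j, 2] < bounds[i, 0] - _EDGE_EPS
                or bounds[i, 3] < bounds[j, 1] - _EDGE_EPS
                or bounds[j, 3] < bounds[i, 1] - _EDGE_EPS
            ):
                continue
            inter = polys[i].intersection(polys[j])
            if inter.length > _EDGE_EPS:
                adjacency[i].add(j)
                adjacency[j].add(i)
    return [frozenset(s) for s in adjacency]


def neighbors(lattice: Lattice, i: int) -> frozenset:
    """Shared-membrane neighbor set of cell ``i`` (symmetric relation)."""
    if not (0 <= i < lattice.n_cells):
        raise IndexError(f"cell index {i} out of range [0, {lattice.n_cells})")
    return lattice.adjacency[i]


def normalized_radius_from_centroids(
    centroids: np.ndarray, percentile: float = 95.0
) -> np.ndarray:
    """Centroid distances normalized by their upper-percentile value.

    Mirrors the imaging convention: each cell's distance from the island
    center is divided by the top-percentile distance, so rim cells land at
    radius ~1 regardless of absolute island size. Values are clipped at 1.
    """
    d = np.linalg.norm(np.asarray(centroids, dtype=float), axis=1)
    if len(d) < 2:
        return np.zeros(len(d))
    p = np.percentile(d, percentile)
    if p <= 0:
        return np.zeros(len(d))
    return np.minimum(1.0, d / p)


def normalized_radius(lattice: Lattice, percentile: float = 95.0) -> np.ndarray:
    """Per-cell normalized radius of a lattice (see module docstring)."""
    return normalized_radius_from_centroids(lattice.centroids, percentile)


def boundary_mask(lattice: Lattice, threshold: float = 0.95) -> np.ndarray:
    """Boolean mask of boundary cells: normalized radius >= threshold.

    The complementary interior mask is its negation.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return lattice.radius >= threshold
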