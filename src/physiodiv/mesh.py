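"""Spherical icosahedral mesh: construction, dual-cell areas, regridding.

The simulation domain is the node set of a subdivided icosahedron on a
sphere of Earth radius.  Each node owns a Voronoi dual cell; fields live
on nodes.  Lat-lon rasters (cell-centered, longitude in [-180, 180),
latitude in degrees north) are exchanged with the mesh by bilinear
interpolation (raster -> mesh) and inverse-distance weighting from the
nearest nodes (mesh -> raster).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import trimesh
import xarray as xr
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import SphericalVoronoi, cKDTree

EARTH_RADIUS = 6.371e6  # m

#: refuse to build meshes beyond this many nodes (memory guard)
MAX_NODES = 3_000_000


@dataclass
class SphericalMesh:
    """Icosahedral node/cell structure on a sphere.

    Attributes
    ----------
    node_coords : (n, 3) float array
        Cartesian positions on the sphere of radius ``radius`` (m).
    node_lonlat : (n, 2) float array
        Longitude in [-180, 180) and latitude in [-90, 90] (degrees).
    neigh_indptr, neigh_indices : int arrays
        CSR adjacency; neighbors of node ``i`` are
        ``neigh_indices[neigh_indptr[i]:neigh_indptr[i+1]]``.
    edge_length : float array
        Great-circle length (m) aligned with ``neigh_indices``.
    cell_area : (n,) float array
        Spherical Voronoi dual-cell area (m^2).
    """

    radius: float
    node_coords: np.ndarray
    node_lonlat: np.ndarray
    neigh_indptr: np.ndarray
    neigh_indices: np.ndarray
    edge_length: np.ndarray
    cell_area: np.ndarray
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def mean_spacing(self) -> float:
        """Mean great-circle distance between adjacent nodes (m)."""
        return float(self.edge_length.mean())

    @property
    def mean_spacing_deg(self) -> float:
        return np.degrees(self.mean_spacing / self.radius)

    def neighbors(self, i: int) -> np.ndarray:
        return self.neigh_indices[self.neigh_indptr[i] : self.neigh_indptr[i + 1]]

    @property
    def edges(self) -> np.ndarray:
        """Directed adjacency pairs (src, dst), each undirected edge twice."""
        src = np.repeat(np.arange(self.n_nodes), np.diff(self.neigh_indptr))
        return np.column_stack([src, self.neigh_indices])

    @property
    def kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.node_coords / self.radius)
        return self._tree

    # -- differential operators -------------------------------------------

    def tangent_gradient(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Least-squares tangent-plane gradient (east, north components).

        Fits ``f ~ f_i + gx*dx + gy*dy`` over each node's neighbors, with
        (dx, dy) the displacement projected on the local east/north unit
        vectors.  Returns two (n,) arrays in units of ``values`` per metre.
        """
        lon = np.radians(self.node_lonlat[:, 0])
        lat = np.radians(self.node_lonlat[:, 1])
        e_east = np.column_stack([-np.sin(lon), np.cos(lon), np.zeros_like(lon)])
        e_north = np.column_stack(
            [-np.sin(lat) * np.cos(lon), -np.sin(lat) * np.sin(lon), np.cos(lat)]
        )
        src = np.repeat(np.arange(self.n_nodes), np.diff(self.neigh_indptr))
        dst = self.neigh_indices
        d = self.node_coords[dst] - self.node_coords[src]
        dx = np.einsum("ij,ij->i", d, e_east[src])
        dy = np.einsum("ij,ij->i", d, e_north[src])
        df = values[dst] - values[src]
        # accumulate 2x2 normal equations per node
        sxx = np.bincount(src, dx * dx, self.n_nodes)
        sxy = np.bincount(src, dx * dy, self.n_nodes)
        syy = np.bincount(src, dy * dy, self.n_nodes)
        bx = np.bincount(src, dx * df, self.n_nodes)
        by = np.bincount(src, dy * df, self.n_nodes)
        det = sxx * syy - sxy * sxy
        det = np.where(np.abs(det) < 1e-30, 1.0, det)
        gx = (syy * bx - sxy * by) / det
        gy = (sxx * by - sxy * bx) / det
        return gx, gy

    def slope_magnitude(self, values: np.ndarray) -> np.ndarray:
        gx, gy = self.tangent_gradient(values)
        return np.hypot(gx, gy)

    # -- neighborhood operators -------------------------------------------

    def nodes_within(self, radius_deg: float) -> tuple[np.ndarray, np.ndarray]:
        """CSR (indptr, indices) of all nodes within an angular radius.

        Includes the node itself.  ``radius_deg`` is the great-circle
        angular radius in degrees.
        """
        chord = 2.0 * np.sin(np.radians(radius_deg) / 2.0)
        pairs = self.kdtree.query_ball_tree(self.kdtree, chord)
        counts = np.fromiter((len(p) for p in pairs), dtype=np.int64, count=self.n_nodes)
        indptr = np.concatenate([[0], np.cumsum(counts)])
        indices = np.concatenate([np.sort(p) for p in pairs]) if self.n_nodes else np.array([], int)
        return indptr, indices

    def cap_average_operator(self, radius_deg: float) -> sp.csr_matrix:
        """Sparse row-stochastic operator averaging over spherical caps.

        Row i averages (area-weighted) the field over all nodes within
        ``radius_deg`` of node i — a moving-average low-pass filter.
        """
        indptr, indices = self.nodes_within(radius_deg)
        w = self.cell_area[indices].astype(float)
        mat = sp.csr_matrix(
            (w, indices, indptr), shape=(self.n_nodes, self.n_nodes)
        )
        rowsum = np.asarray(mat.sum(axis=1)).ravel()
        return sp.diags(1.0 / rowsum) @ mat


def build_icosphere(subdivision_level: int, radius: float = EARTH_RADIUS) -> SphericalMesh:
    """Build the icosahedral mesh at a given subdivision level.

    Node count is ``10 * 4**level + 2``.  Raises ``ValueError`` if the
    requested level would exceed the memory guard (``MAX_NODES``).
    """
    if subdivision_level < 0:
        raise ValueError("subdivision_level must be >= 0")
    n_nodes = 10 * 4**subdivision_level + 2
    if n_nodes > MAX_NODES:
        raise ValueError(
            f"subdivision level {subdivision_level} implies {n_nodes} nodes, "
            f"exceeding the memory guard of {MAX_NODES}; lower the level"
        )
    tm = trimesh.creation.icosphere(subdivisions=subdivision_level, radius=1.0)
    unit = np.asarray(tm.vertices, dtype=float)
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    coords = unit * radius

    lon = np.degrees(np.arctan2(unit[:, 1], unit[:, 0]))
    lon = np.where(lon >= 180.0, lon - 360.0, lon)
    lat = np.degrees(np.arcsin(np.clip(unit[:, 2], -1.0, 1.0)))
    lonlat = np.column_stack([lon, lat])

    e = tm.edges_unique
    src = np.concatenate([e[:, 0], e[:, 1]])
    dst = np.concatenate([e[:, 1], e[:, 0]])
    order = np.lexsort((dst, src))
    src, dst = src[order], dst[order]
    counts = np.bincount(src, minlength=n_nodes)
    indptr = np.concatenate([[0], np.cumsum(counts)])

    dots = np.clip(np.einsum("ij,ij->i", unit[src], unit[dst]), -1.0, 1.0)
    edge_len = radius * np.arccos(dots)

    sv = SphericalVoronoi(coords, radius=radius)
    areas = sv.calculate_areas()

    return SphericalMesh(
        radius=radius,
        node_coords=coords,
        node_lonlat=lonlat,
        neigh_indptr=indptr.astype(np.int64),
        neigh_indices=dst.astype(np.int64),
        edge_length=edge_len,
        cell_area=areas,
    )


# ---------------------------------------------------------------------------
# regridding
# ---------------------------------------------------------------------------


def _check_raster(raster: np.ndarray, lat: np.ndarray, lon: np.ndarray) -> None:
    if raster.shape != (lat.size, lon.size):
        raise ValueError(f"raster shape {raster.shape} != (n_lat={lat.size}, n_lon={lon.size})")
    bad_rows = np.where(~np.isfinite(raster).all(axis=1))[0]
    if bad_rows.size:
        bands = ", ".join(f"{lat[r]:.2f}" for r in bad_rows[:5])
        raise ValueError(f"raster has missing values at latitude band(s): {bands}")


def raster_to_mesh(
    mesh: SphericalMesh, raster: np.ndarray, lat: np.ndarray, lon: np.ndarray
) -> np.ndarray:
    """Bilinear interpolation of a global cell-centered raster onto mesh nodes.

    Longitude is treated as periodic; latitudes beyond the outermost cell
    centers are clamped (nearest row).
    """
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    raster = np.asarray(raster, float)
    _check_raster(raster, lat, lon)
    if lat[0] > lat[-1]:
        lat, raster = lat[::-1], raster[::-1]
    # periodic longitude pad
    lon_p = np.concatenate([[lon[0] - (lon[1] - lon[0])], lon, [lon[-1] + (lon[1] - lon[0])]])
    ras_p = np.concatenate([raster[:, -1:], raster, raster[:, :1]], axis=1)
    interp = RegularGridInterpolator(
        (lat, lon_p), ras_p, method="linear", bounds_error=False, fill_value=None
    )
    pts = np.column_stack(
        [np.clip(mesh.node_lonlat[:, 1], lat[0], lat[-1]), mesh.node_lonlat[:, 0]]
    )
    return interp(pts)


def mesh_to_raster(
    mesh: SphericalMesh,
    values: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    k: int = 3,
) -> np.ndarray:
    """Inverse-distance interpolation from the k nearest mesh nodes."""
    lat2, lon2 = np.meshgrid(np.asarray(lat, float), np.asarray(lon, float), indexing="ij")
    latr, lonr = np.radians(lat2).ravel(), np.radians(lon2).ravel()
    pts = np.column_stack(
        [np.cos(latr) * np.cos(lonr), np.cos(latr) * np.sin(lonr), np.sin(latr)]
    )
    dist, idx = mesh.kdtree.query(pts, k=k)
    dist = np.maximum(dist, 1e-12)
    w = 1.0 / dist
    out = (w * values[idx]).sum(axis=1) / w.sum(axis=1)
    # exact hit: take the node value
    hit = dist[:, 0] < 1e-10
    out[hit] = values[idx[hit, 0]]
    return out.reshape(lat2.shape)


def regrid(
    mesh: SphericalMesh,
    field_values: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    direction: str,
    k: int = 3,
) -> np.ndarray:
    """Exchange a field between a lat-lon raster and the mesh.

    direction="to_mesh" interprets ``field_values`` as a (lat, lon) raster;
    direction="to_raster" interprets it as node values.
    """
    if direction == "to_mesh":
        return raster_to_mesh(mesh, field_values, lat, lon)
    if direction == "to_raster":
        return mesh_to_raster(mesh, field_values, lat, lon, k=k)
    raise ValueError("direction must be 'to_mesh' or 'to_raster'")


# ---------------------------------------------------------------------------
# netCDF serialization
# ---------------------------------------------------------------------------


def mesh_fields_to_dataset(mesh: SphericalMesh, fields: dict[str, np.ndarray]) -> xr.Dataset:
    """Pack node fields into an xarray Dataset with one unstructured dim."""
    data = {name: ("node", np.asarray(v)) for name, v in fields.items()}
    ds = xr.Dataset(
        data,
        coords={
            "lon": ("node", mesh.node_lonlat[:, 0]),
            "lat": ("node", mesh.node_lonlat[:, 1]),
        },
        attrs={"radius_m": mesh.radius, "n_nodes": mesh.n_nodes},
    )
    return ds


def save_mesh_fields(path, mesh: SphericalMesh, fields: dict[str, np.ndarray]) -> None:
    mesh_fields_to_dataset(mesh, fields).to_netcdf(path, engine="scipy")


def load_mesh_fields(path) -> xr.Dataset:
    return xr.load_dataset(path, engine="scipy")


def weighted_quantile(
    values: np.ndarray, quantiles: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Area-weighted quantiles (interpolated empirical CDF)."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return np.interp(np.asarray(quantiles, float), cum, v)


def hypsometric_curve(
    elevation: np.ndarray, cell_area: np.ndarray, n_quantiles: int = 100
) -> np.ndarray:
    """Elevation at n equally spaced area quantiles (the hypsometric curve)."""
    q = (np.arange(n_quantiles) + 0.5) / n_quantiles
    return weighted_quantile(elevation, q, cell_area)


__all__ = [
    "EARTH_RADIUS",
    "MAX_NODES",
    "SphericalMesh",
    "build_icosphere",
    "raster_to_mesh",
    "mesh_to_raster",
    "regrid",
    "mesh_fields_to_dataset",
    "save_mesh_fields",
    "load_mesh_fields",
    "weighted_quantile",
    "hypsometric_curve",
]
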