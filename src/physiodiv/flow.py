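"""Multiple-flow-direction routing, implicit drainage accumulation, basins.

Water (and later sediment) is routed from every land node to all strictly
lower neighbors, with weights proportional to the downslope gradient raised
to a configurable exponent.  The upstream-integrated water flux ``PA`` is
obtained by solving the sparse linear system ``(I - W^T) q = P * area``,
where ``W`` holds the routing weights — the implicit-drainage-area
formulation, here solved serially with a sparse LU factorization that is
cached on the flow solution for reuse (sediment routing uses the same
matrix).

Basins are labeled by the terminal node of each steepest-descent path.
Paths that reach the ocean merge into a single ocean basin; paths ending
at an interior pit above sea level define endorheic basins, for which the
sill (lowest pass on the basin rim) is also computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spl

from .mesh import SphericalMesh

OCEAN_BASIN = -1


@dataclass
class Receivers:
    """CSR receiver structure: downstream nodes, weights, edge lengths."""

    indptr: np.ndarray
    nodes: np.ndarray
    weights: np.ndarray
    edge_length: np.ndarray
    steepest: np.ndarray  # steepest receiver per node, -1 for pits/ocean
    is_ocean: np.ndarray  # bool, elevation <= sea level
    n_nodes: int

    def receivers_of(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        sl = slice(self.indptr[i], self.indptr[i + 1])
        return self.nodes[sl], self.weights[sl]

    @property
    def source_nodes(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_nodes), np.diff(self.indptr))

    @property
    def is_pit(self) -> np.ndarray:
        """Land nodes with no receiver (local depressions)."""
        has_rec = np.diff(self.indptr) > 0
        return ~has_rec & ~self.is_ocean

    def routing_matrix(self) -> sp.csc_matrix:
        """(I - W^T) used by the implicit accumulation solve."""
        src = self.source_nodes
        w = sp.csr_matrix(
            (self.weights, (src, self.nodes)), shape=(self.n_nodes, self.n_nodes)
        )
        return (sp.eye(self.n_nodes, format="csr") - w.T).tocsc()


@dataclass
class BasinTable:
    """Per-basin summary; one row per land basin plus the ocean."""

    table: pd.DataFrame  # basin_id, terminal, endorheic, area_m2, sill_m, spill_node

    def endorheic_ids(self) -> np.ndarray:
        t = self.table
        return t.loc[t["endorheic"], "basin_id"].to_numpy()


@dataclass
class FlowSolution:
    """Receivers, water flux, and basin structure for one surface."""

    receivers: Receivers
    water_flux: np.ndarray | None = None
    basin_id: np.ndarray | None = None
    basins: BasinTable | None = None
    _lu: object = field(default=None, repr=False, compare=False)

    def lu(self):
        if self._lu is None:
            self._lu = spl.splu(self.receivers.routing_matrix())
        return self._lu

    def accumulate(self, source: np.ndarray) -> np.ndarray:
        """Route ``source`` (volume per node) downstream; returns throughput."""
        return self.lu().solve(np.asarray(source, float))


def compute_receivers(
    mesh: SphericalMesh,
    elevation: np.ndarray,
    sea_level: float = 0.0,
    p: float = 1.0,
    flat_tol: float = 1e-9,
) -> Receivers:
    """MFD receivers: all strictly lower neighbors, weight ~ gradient**p.

    Ocean nodes (elevation <= sea_level) route nowhere.  Land nodes with no
    strictly lower neighbor but at least one neighbor at (numerically) equal
    elevation that itself drains are routed across the flat by breadth-first
    distance to the flat's outlets, guaranteeing acyclic routing; remaining
    nodes are pits (legal output).
    """
    elevation = np.asarray(elevation, float)
    if not np.all(np.isfinite(elevation)):
        raise ValueError("elevation must be finite")
    n = mesh.n_nodes
    is_ocean = elevation <= sea_level

    src = np.repeat(np.arange(n), np.diff(mesh.neigh_indptr))
    dst = mesh.neigh_indices
    grad = (elevation[src] - elevation[dst]) / mesh.edge_length
    down = (grad > 0) & ~is_ocean[src]

    s, d = src[down], dst[down]
    g = grad[down] ** p
    elen = mesh.edge_length[down]
    norm = np.bincount(s, g, n)
    w = g / norm[s]

    # steepest receiver (max raw gradient), ties broken by lower node index
    steepest = np.full(n, -1, dtype=np.int64)
    order = np.lexsort((d, -grad[down], s))
    uniq, start = np.unique(s[order], return_index=True)
    steepest[uniq] = d[order[start]]

    # ---- resolve flats: land nodes with no lower neighbor but an equal one
    has_rec = np.bincount(s, minlength=n) > 0
    scale = max(np.ptp(elevation), 1.0)
    dz = elevation[src] - elevation[dst]
    # equal-or-lower within tolerance: routing across flats may never point
    # to a strictly higher node (that could close a cycle with its own
    # strict-descent receiver back into the flat)
    eq = (np.abs(dz) <= flat_tol * scale) & (dz >= 0) & ~is_ocean[src]
    flat_cand = ~has_rec & ~is_ocean
    extra_s, extra_d = [], []
    if flat_cand.any() and eq.any():
        # BFS from flat nodes whose equal-neighbor drains (or is ocean)
        from collections import deque

        eq_src, eq_dst = src[eq], dst[eq]
        drains = has_rec | is_ocean
        resolved = np.zeros(n, bool)
        queue = deque()
        # seed: flat candidates with an equal neighbor that drains
        sel = flat_cand[eq_src] & drains[eq_dst] & ~flat_cand[eq_dst]
        order2 = np.lexsort((eq_dst[sel], eq_src[sel]))
        for a, b in zip(eq_src[sel][order2], eq_dst[sel][order2]):
            if not resolved[a]:
                resolved[a] = True
                extra_s.append(a)
                extra_d.append(b)
                queue.append(a)
        # propagate into the flat interior
        adj_of = {}
        for a, b in zip(eq_src, eq_dst):
            if flat_cand[b]:
                adj_of.setdefault(a, []).append(b)
        while queue:
            cur = queue.popleft()
            for nb in sorted(adj_of.get(cur, [])):
                if not resolved[nb] and flat_cand[nb]:
                    resolved[nb] = True
                    extra_s.append(nb)
                    extra_d.append(cur)
                    queue.append(nb)

    if extra_s:
        extra_s = np.asarray(extra_s, np.int64)
        extra_d = np.asarray(extra_d, np.int64)
        s = np.concatenate([s, extra_s])
        d = np.concatenate([d, extra_d])
        w = np.concatenate([w, np.ones(extra_s.size)])
        # edge length lookup for the added pairs
        el = np.empty(extra_s.size)
        for k_, (a, b) in enumerate(zip(extra_s, extra_d)):
            nb = mesh.neigh_indices[mesh.neigh_indptr[a] : mesh.neigh_indptr[a + 1]]
            el[k_] = mesh.edge_length[mesh.neigh_indptr[a] + np.where(nb == b)[0][0]]
        elen = np.concatenate([elen, el])
        steepest[extra_s] = extra_d

    order3 = np.argsort(s, kind="stable")
    s, d, w, elen = s[order3], d[order3], w[order3], elen[order3]
    counts = np.bincount(s, minlength=n)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    return Receivers(
        indptr=indptr,
        nodes=d.astype(np.int64),
        weights=w.astype(float),
        edge_length=elen.astype(float),
        steepest=steepest,
        is_ocean=is_ocean,
        n_nodes=n,
    )


def _terminals(receivers: Receivers) -> np.ndarray:
    """Terminal node of each steepest-descent path (pointer doubling)."""
    t = receivers.steepest.copy()
    t = np.where(t < 0, np.arange(receivers.n_nodes), t)
    # stop paths at ocean nodes
    t = np.where(receivers.is_ocean, np.arange(receivers.n_nodes), t)
    for _ in range(64):  # 2^64 path length bound
        t2 = t[t]
        if np.array_equal(t2, t):
            return t
        t = t2
    raise RuntimeError("receiver graph contains a cycle (internal consistency error)")


def label_basins(
    mesh: SphericalMesh,
    elevation: np.ndarray,
    receivers: Receivers,
    sea_level: float = 0.0,
) -> tuple[np.ndarray, BasinTable]:
    """Label nodes by drainage terminal; flag endorheic basins and sills.

    All nodes whose steepest-descent path reaches the ocean (including
    ocean nodes themselves) share the ocean label ``OCEAN_BASIN``.  Each
    interior pit above sea level defines one endorheic basin; its sill is
    the lowest pass on the basin boundary.
    """
    elevation = np.asarray(elevation, float)
    n = mesh.n_nodes
    term = _terminals(receivers)
    ocean_terminal = receivers.is_ocean[term]
    basin_id = np.full(n, OCEAN_BASIN, dtype=np.int64)

    pit_terms = np.unique(term[~ocean_terminal])
    nb = pit_terms.size
    if nb:
        lut = np.full(n, OCEAN_BASIN, dtype=np.int64)
        lut[pit_terms] = np.arange(nb)
        basin_id[~ocean_terminal] = lut[term[~ocean_terminal]]

    # areas per basin
    areas = np.bincount(basin_id[basin_id >= 0], mesh.cell_area[basin_id >= 0], nb)

    # sills: min over boundary edges of max(z_i, z_j), vectorized over edges
    src = np.repeat(np.arange(n), np.diff(mesh.neigh_indptr))
    dst = mesh.neigh_indices
    sill = np.full(nb, np.inf)
    spill = np.full(nb, -1, dtype=np.int64)
    cross = (basin_id[src] >= 0) & (basin_id[src] != basin_id[dst])
    if cross.any():
        b = basin_id[src[cross]]
        pass_h = np.maximum(elevation[src[cross]], elevation[dst[cross]])
        out = dst[cross]
        order = np.lexsort((out, pass_h, b))
        b_sorted = b[order]
        uniq, start = np.unique(b_sorted, return_index=True)
        sill[uniq] = pass_h[order[start]]
        spill[uniq] = out[order[start]]

    table = pd.DataFrame(
        dict(
            basin_id=np.arange(nb),
            terminal=pit_terms.astype(np.int64),
            endorheic=np.ones(nb, bool),
            area_m2=areas,
            sill_m=sill,
            spill_node=spill,
        )
    )
    ocean_area = float(mesh.cell_area[basin_id == OCEAN_BASIN].sum())
    ocean_row = pd.DataFrame(
        dict(basin_id=[OCEAN_BASIN], terminal=[-1], endorheic=[False],
             area_m2=[ocean_area], sill_m=[np.nan], spill_node=[-1])
    )
    table = pd.concat([table, ocean_row], ignore_index=True)
    return basin_id, BasinTable(table)


def endorheic_land_fraction(
    mesh: SphericalMesh, basin_id: np.ndarray, is_ocean: np.ndarray
) -> float:
    """Fraction of land area belonging to endorheic basins."""
    land = ~is_ocean
    land_area = mesh.cell_area[land].sum()
    if land_area == 0:
        return 0.0
    endo = land & (basin_id != OCEAN_BASIN)
    return float(mesh.cell_area[endo].sum() / land_area)


def solve_accumulation(
    mesh: SphericalMesh,
    receivers: Receivers,
    runoff: np.ndarray,
    flow: FlowSolution | None = None,
    rtol: float = 1e-10,
) -> np.ndarray:
    """Water flux PA (m^3/yr) by the implicit drainage-area sparse solve.

    Solves ``(I - W^T) q = runoff * cell_area``.  The relative residual is
    checked against ``rtol``; failure raises with the residual norm.
    """
    rhs = np.asarray(runoff, float) * mesh.cell_area
    sol = flow if flow is not None else FlowSolution(receivers=receivers)
    q = sol.accumulate(rhs)
    a = receivers.routing_matrix()
    resid = np.linalg.norm(a @ q - rhs)
    scale = np.linalg.norm(rhs)
    if scale > 0 and resid / scale > rtol:
        raise RuntimeError(
            f"drainage accumulation solve did not converge: relative residual "
            f"{resid / scale:.3e} > {rtol:.1e}"
        )
    return q


def solve_flow(
    mesh: SphericalMesh,
    elevation: np.ndarray,
    runoff: np.ndarray,
    sea_level: float = 0.0,
    p: float = 1.0,
) -> FlowSolution:
    """Full flow solution: receivers, water flux, basins."""
    rec = compute_receivers(mesh, elevation, sea_level=sea_level, p=p)
    sol = FlowSolution(receivers=rec)
    sol.water_flux = solve_accumulation(mesh, rec, runoff, flow=sol)
    sol.basin_id, sol.basins = label_basins(mesh, elevation, rec, sea_level=sea_level)
    return sol


def flow_to_dataset(mesh: SphericalMesh, sol: FlowSolution):
    from .mesh import mesh_fields_to_dataset

    endo_mask = np.zeros(mesh.n_nodes, bool)
    if sol.basins is not None:
        endo_ids = set(sol.basins.endorheic_ids().tolist())
        endo_mask = np.isin(sol.basin_id, list(endo_ids))
    return mesh_fields_to_dataset(
        mesh,
        {
            "water_flux": sol.water_flux,
            "basin_id": sol.basin_id,
            "endorheic": endo_mask.astype(np.int8),
        },
    )


__all__ = [
    "OCEAN_BASIN",
    "Receivers",
    "BasinTable",
    "FlowSolution",
    "compute_receivers",
    "label_basins",
    "endorheic_land_fraction",
    "solve_accumulation",
    "solve_flow",
    "flow_to_dataset",
]
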