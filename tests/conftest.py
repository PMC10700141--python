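import numpy as np
import pytest

from physiodiv.mesh import SphericalMesh, build_icosphere


@pytest.fixture(scope="session")
def mesh3():
    return build_icosphere(3)


@pytest.fixture(scope="session")
def mesh4():
    return build_icosphere(4)


@pytest.fixture(scope="session")
def mesh5():
    return build_icosphere(5)


@pytest.fixture(scope="session")
def mesh6():
    return build_icosphere(6)


def toy_mesh(coords, edges, areas, edge_lengths=None, radius=1.0):
    """Hand-crafted mesh from an undirected edge list (for routing toys)."""
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    edges = np.asarray(edges, int)
    src = np.concatenate([edges[:, 0], edges[:, 1]])
    dst = np.concatenate([edges[:, 1], edges[:, 0]])
    if edge_lengths is None:
        el = np.linalg.norm(coords[src] - coords[dst], axis=1)
    else:
        el = np.concatenate([edge_lengths, edge_lengths]).astype(float)
    order = np.lexsort((dst, src))
    src, dst, el = src[order], dst[order], el[order]
    indptr = np.concatenate([[0], np.cumsum(np.bincount(src, minlength=n))])
    norm = np.linalg.norm(coords, axis=1)
    norm[norm == 0] = 1.0
    unit = coords / norm[:, None]
    lon = np.degrees(np.arctan2(unit[:, 1], unit[:, 0]))
    lat = np.degrees(np.arcsin(np.clip(unit[:, 2], -1, 1)))
    return SphericalMesh(
        radius=radius,
        node_coords=coords,
        node_lonlat=np.column_stack([lon, lat]),
        neigh_indptr=indptr.astype(np.int64),
        neigh_indices=dst.astype(np.int64),
        edge_length=el,
        cell_area=np.asarray(areas, float),
    )


def topo_accumulate(receivers, source):
    """Independent oracle: explicit topological-order (Kahn) accumulation."""
    n = receivers.n_nodes
    indeg = np.zeros(n, dtype=int)
    for i in range(n):
        for j in receivers.receivers_of(i)[0]:
            indeg[j] += 1
    acc = np.asarray(source, float).copy()
    stack = [i for i in range(n) if indeg[i] == 0]
    seen = 0
    while stack:
        i = stack.pop()
        seen += 1
        nodes, weights = receivers.receivers_of(i)
        for j, w in zip(nodes, weights):
            acc[j] += acc[i] * w
            indeg[j] -= 1
            if indeg[j] == 0:
                stack.append(j)
    assert seen == n, "receiver graph has a cycle"
    return acc
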