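import numpy as np
import pytest

from physiodiv.mesh import build_icosphere
from physiodiv.physiography import (
    N_JOINT_CLASSES,
    classify_landforms,
    compute_pdiv,
    compute_pvar,
    compute_tpi,
    compute_tpi_s,
    summarize_slice,
    track_sediment_cover,
)
from physiodiv.surface import SurfaceState

from conftest import toy_mesh


class TestTPI:
    def test_annulus_hand_arithmetic_on_icosahedron(self):
        # node 0 of the icosahedron has exactly 5 neighbors at 63.43 deg;
        # an annulus (30, 70) deg therefore contains exactly those 5 nodes
        m = build_icosphere(0)
        z = np.zeros(12)
        z[0] = 10.0
        z[m.neighbors(0)] = [2.0, 4.0, 5.0, 6.0, 8.0]
        tpi = compute_tpi(m, z, (30.0, 70.0))
        assert tpi[0] == pytest.approx(10.0 - 5.0, rel=1e-12)

    def test_standardization_contract(self, mesh4):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 500, mesh4.n_nodes)
        t = compute_tpi_s(mesh4, z, (0.0, 3 * mesh4.mean_spacing_deg))
        w = mesh4.cell_area / mesh4.cell_area.sum()
        assert abs(float((w * t).sum())) < 1e-9
        assert float(np.sqrt((w * t**2).sum())) == pytest.approx(100.0, abs=1e-9)

    def test_locally_linear_field_has_small_tpi(self, mesh5):
        # x-coordinate of the unit sphere is locally linear; a symmetric
        # annulus mean then matches the center up to curvature terms
        z = 1000.0 * mesh5.node_coords[:, 0] / mesh5.radius
        h = mesh5.mean_spacing_deg
        tpi = compute_tpi(mesh5, z, (1.0 * h, 3.0 * h))
        assert np.abs(tpi).max() < 0.02 * np.ptp(z)

    def test_constant_elevation_warns_and_returns_zeros(self, mesh3):
        with pytest.warns(UserWarning, match="constant"):
            t = compute_tpi_s(mesh3, np.full(mesh3.n_nodes, 7.0),
                              (0.0, 3 * mesh3.mean_spacing_deg))
        assert np.allclose(t, 0.0)

    def test_invalid_annulus_rejected(self, mesh3):
        with pytest.raises(ValueError, match="annulus"):
            compute_tpi(mesh3, np.zeros(mesh3.n_nodes), (5.0, 5.0))


class TestClassify:
    def test_extreme_values_hit_first_and_last_class(self):
        b = dict(slope=[1, 2, 3, 4, 5, 6],
                 water_flux=[10, 20, 30, 40],
                 tpi_s=list(np.linspace(-200, 200, 9)))
        slope = np.array([0.5, 7.0])
        flux = np.array([5.0, 45.0])
        tpi = np.array([-300.0, 300.0])
        c = classify_landforms(slope, flux, tpi, boundaries=b)
        assert list(c[0]) == [1, 1, 1]
        assert list(c[1]) == [7, 5, 10]

    def test_equal_frequency_default_boundaries(self, mesh4):
        rng = np.random.default_rng(1)
        n = mesh4.n_nodes
        slope = rng.random(n)
        flux = rng.random(n)
        tpi = rng.normal(size=n)
        c = classify_landforms(slope, flux, tpi, cell_area=mesh4.cell_area)
        # continuous fields, equal cell weights: near-equal occupancy
        for j, k in enumerate((7, 5, 10)):
            counts = np.bincount(c[:, j] - 1, minlength=k)
            assert counts.min() > 0.8 * n / k
            assert counts.max() < 1.2 * n / k

    def test_constant_field_degenerates_to_class_one_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            c = classify_landforms(np.ones(20), np.arange(20.0),
                                   np.arange(20.0))
        assert (c[:, 0] == 1).all()

    def test_non_monotone_boundaries_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            classify_landforms(
                np.ones(3), np.ones(3), np.ones(3),
                boundaries=dict(slope=[1, 2, 2, 4, 5, 6],
                                water_flux=[1, 2, 3, 4],
                                tpi_s=list(range(9))))


def _tetra_mesh():
    coords = np.array([[1.0, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]])
    coords /= np.sqrt(3)
    edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    return toy_mesh(coords, edges, areas=np.full(4, np.pi), radius=1.0)


class TestPDiv:
    def test_uniform_landscape_zero_diversity(self, mesh3):
        classes = np.ones((mesh3.n_nodes, 3), dtype=np.int64)
        pdiv = compute_pdiv(mesh3, classes, radius_deg=2 * mesh3.mean_spacing_deg)
        assert np.allclose(pdiv, 0.0)

    def test_three_equal_classes_give_equitability_one(self):
        # icosahedron: node + 5 neighbors within 70 deg; assign 3 joint
        # classes with frequencies 2/2/2 -> d_SW = ln 3, P_DIV = 1
        m = build_icosphere(0)
        classes = np.ones((12, 3), dtype=np.int64)
        nb = m.neighbors(0)
        classes[0, 2] = 1
        classes[nb[0], 2] = 1
        classes[nb[1], 2] = 2
        classes[nb[2], 2] = 2
        classes[nb[3], 2] = 3
        classes[nb[4], 2] = 3
        pdiv = compute_pdiv(m, classes, radius_deg=70.0, mode="paper")
        assert pdiv[0] == pytest.approx(1.0, rel=1e-12)

    def test_four_equal_classes_exceed_one_under_literal_normalization(self):
        # documented consequence of normalizing by ln(3): four equally
        # frequent joint classes give ln(4)/ln(3) ~ 1.262
        m = _tetra_mesh()
        classes = np.column_stack([np.arange(1, 5), np.ones(4, int), np.ones(4, int)])
        pdiv = compute_pdiv(m, classes, radius_deg=179.0, mode="paper")
        assert np.allclose(pdiv, np.log(4) / np.log(3))
        pdiv2 = compute_pdiv(m, classes, radius_deg=179.0, mode="classes")
        assert np.allclose(pdiv2, np.log(4) / np.log(N_JOINT_CLASSES))

    def test_mode_validation(self, mesh3):
        with pytest.raises(ValueError, match="mode"):
            compute_pdiv(mesh3, np.ones((mesh3.n_nodes, 3), int),
                         radius_deg=2 * mesh3.mean_spacing_deg, mode="bogus")


class TestPVar:
    def test_constant_pdiv_zero_variety(self, mesh3):
        land = np.ones(mesh3.n_nodes, bool)
        out = compute_pvar(mesh3, np.full(mesh3.n_nodes, 0.4), land)
        assert out["Q1"] == out["Q2"] == out["Q3"]
        assert out["pvar"] == 0.0

    def test_uniform_pdiv_interquartile_half(self, mesh4):
        rng = np.random.default_rng(0)
        pdiv = rng.random(mesh4.n_nodes)
        out = compute_pvar(mesh4, pdiv, np.ones(mesh4.n_nodes, bool))
        assert out["pvar"] == pytest.approx(0.5, abs=0.03)

    def test_area_scale_invariance(self, mesh3):
        rng = np.random.default_rng(1)
        pdiv = rng.random(mesh3.n_nodes)
        land = rng.random(mesh3.n_nodes) > 0.4
        a = compute_pvar(mesh3, pdiv, land)
        mesh_scaled = build_icosphere(3, radius=mesh3.radius)
        mesh_scaled.cell_area = 2 * mesh3.cell_area
        b = compute_pvar(mesh_scaled, pdiv, land)
        assert a["Q1"] == b["Q1"] and a["Q3"] == b["Q3"]

    def test_empty_land_rejected(self, mesh3):
        with pytest.raises(ValueError):
            compute_pvar(mesh3, np.zeros(mesh3.n_nodes),
                         np.zeros(mesh3.n_nodes, bool))


def _state(mesh, age, dep=None, ero=None, z=None):
    n = mesh.n_nodes
    return SurfaceState(
        elevation=z if z is not None else np.full(n, 100.0),
        cum_erosion=ero if ero is not None else np.zeros(n),
        cum_deposition=dep if dep is not None else np.zeros(n),
        age=age,
    )


class TestSedimentCover:
    def test_no_deposition_keeps_cover_zero(self, mesh3):
        states = [_state(mesh3, a) for a in (100.0, 95.0, 90.0)]
        scov = track_sediment_cover(states, mesh3)
        assert (scov["scov"] == 0.0).all()

    def test_basin_filling_raises_cover_stepwise(self, mesh3):
        n = mesh3.n_nodes
        # pick a contiguous patch holding ~10% of the area
        unit = mesh3.node_coords / mesh3.radius
        d = np.arccos(np.clip(unit @ unit[0], -1, 1))
        order = np.argsort(d)
        target = 0.1 * mesh3.cell_area.sum()
        patch = np.zeros(n, bool)
        acc = 0.0
        for i in order:
            patch[i] = True
            acc += mesh3.cell_area[i]
            if acc >= target:
                break
        frac = mesh3.cell_area[patch].sum() / mesh3.cell_area.sum()
        dep = np.where(patch, 5.0, 0.0)
        states = [
            _state(mesh3, 100.0),
            _state(mesh3, 95.0),
            _state(mesh3, 90.0, dep=dep),
            _state(mesh3, 85.0),
        ]
        scov = track_sediment_cover(states, mesh3)
        assert scov["scov"].iloc[0] == 0.0
        assert scov["scov"].iloc[1] == 0.0
        assert scov["scov"].iloc[2] == pytest.approx(frac, rel=1e-12)
        assert scov["scov"].iloc[3] == pytest.approx(frac, rel=1e-12)

    def test_monotone_without_erosion_and_bounded(self, mesh3):
        rng = np.random.default_rng(5)
        states = []
        for k, age in enumerate((120.0, 110.0, 100.0, 90.0)):
            dep = rng.random(mesh3.n_nodes) * 0.8  # below threshold sometimes
            states.append(_state(mesh3, age, dep=dep))
        scov = track_sediment_cover(states, mesh3)
        assert (np.diff(scov["scov"]) >= 0).all()
        assert scov["scov"].between(0, 1).all()

    def test_erosion_can_remove_cover(self, mesh3):
        n = mesh3.n_nodes
        dep = np.full(n, 2.0)
        ero = np.full(n, 3.0)
        states = [_state(mesh3, 100.0, dep=dep), _state(mesh3, 95.0, ero=ero)]
        scov = track_sediment_cover(states, mesh3)
        assert scov["scov"].iloc[0] == 1.0
        assert scov["scov"].iloc[1] == 0.0

    def test_unordered_ages_rejected(self, mesh3):
        states = [_state(mesh3, 90.0), _state(mesh3, 95.0)]
        with pytest.raises(ValueError, match="chronological"):
            track_sediment_cover(states, mesh3)


def test_summarize_slice_end_to_end(mesh4):
    from physiodiv.flow import solve_flow
    from physiodiv.surface import effective_slope
    from physiodiv.synthetic import generate_forcing_sequence

    f = generate_forcing_sequence(dict(n_slices=1, mesh=mesh4), seed=6)[0]
    flow = solve_flow(mesh4, f.elevation, f.runoff)
    s = summarize_slice(mesh4, f.elevation, flow.water_flux,
                        effective_slope(flow, f.elevation), age=f.age, scov=0.2)
    assert s.q1 <= s.q2 <= s.q3
    assert s.pvar == pytest.approx(s.q3 - s.q1)
    assert (s.pdiv >= 0).all()
    assert s.scov == 0.2
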