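"""Nodal map assembly, Laplace interpolation, thresholding, S-QRS, SNR."""
import numpy as np
import pytest
from scipy.spatial.distance import cdist

from scarconcord import (EgmSample, NodeScalarMap, PaceSite, assign_egm_to_nodes,
                         binarize_map, classify_sqrs, egm_snr, relax_interpolate)
from scarconcord.eam import EamError
from scarconcord.mesh import MeshError

from conftest import PathMesh


class TestAssignEgm:
    def test_multiple_samples_average(self, tetra_mesh):
        v = tetra_mesh.vertices[0]
        samples = [EgmSample(v, 1.0), EgmSample(v + 0.01, 3.0)]
        vmap, _ = assign_egm_to_nodes(samples, tetra_mesh)
        assert vmap.values[0] == pytest.approx(2.0)

    def test_single_sample_flags_one_vertex(self, tetra_mesh):
        vmap, latmap = assign_egm_to_nodes(
            [EgmSample(tetra_mesh.vertices[2], 1.2, lat_ms=30.0)], tetra_mesh)
        assert vmap.known.tolist() == [False, False, True, False]
        assert latmap.values[2] == 30.0

    def test_empty_samples_rejected(self, tetra_mesh):
        with pytest.raises(EamError):
            assign_egm_to_nodes([], tetra_mesh)

    def test_matches_brute_force_grouping(self, small_phantom):
        _, _, _, mesh, _ = small_phantom
        rng = np.random.default_rng(0)
        pos = mesh.vertices[rng.integers(0, mesh.n_vertices, 200)] + rng.normal(0, 0.3, (200, 3))
        volts = rng.uniform(0.1, 5.0, 200)
        samples = [EgmSample(p, v) for p, v in zip(pos, volts)]
        vmap, _ = assign_egm_to_nodes(samples, mesh)
        nearest = cdist(pos, mesh.vertices).argmin(axis=1)
        for k in np.unique(nearest):
            assert vmap.values[k] == pytest.approx(volts[nearest == k].mean())
        assert vmap.n_known == len(np.unique(nearest))


class TestRelaxInterpolate:
    def test_single_known_value_fills_constant(self, small_phantom):
        _, _, _, mesh, _ = small_phantom
        partial = NodeScalarMap.empty(mesh.n_vertices)
        partial.values[10] = 2.5
        partial.known[10] = True
        out = relax_interpolate(partial, mesh)
        np.testing.assert_allclose(out.values, 2.5, atol=1e-10)

    def test_path_graph_endpoints_give_linear_ramp(self):
        n = 17
        mesh = PathMesh(n)
        partial = NodeScalarMap.empty(n)
        partial.values[[0, n - 1]] = [0.0, 1.0]
        partial.known[[0, n - 1]] = True
        out = relax_interpolate(partial, mesh)
        np.testing.assert_allclose(out.values, np.arange(n) / (n - 1), atol=1e-8)

    def test_discrete_maximum_principle(self, small_phantom):
        _, _, _, mesh, _ = small_phantom
        rng = np.random.default_rng(1)
        for _ in range(10):
            partial = NodeScalarMap.empty(mesh.n_vertices)
            k = rng.integers(1, 40)
            idx = rng.choice(mesh.n_vertices, size=k, replace=False)
            partial.values[idx] = rng.uniform(-5, 5, k)
            partial.known[idx] = True
            out = relax_interpolate(partial, mesh)
            lo, hi = partial.values[idx].min(), partial.values[idx].max()
            assert out.values.min() >= lo - 1e-9 and out.values.max() <= hi + 1e-9

    def test_known_vertices_unchanged_and_idempotent(self, small_phantom):
        _, _, _, mesh, _ = small_phantom
        rng = np.random.default_rng(2)
        partial = NodeScalarMap.empty(mesh.n_vertices)
        idx = rng.choice(mesh.n_vertices, size=25, replace=False)
        partial.values[idx] = rng.uniform(0, 5, 25)
        partial.known[idx] = True
        out = relax_interpolate(partial, mesh)
        np.testing.assert_array_equal(out.values[idx], partial.values[idx])
        again = relax_interpolate(out, mesh)
        np.testing.assert_allclose(again.values, out.values, atol=1e-8)
        # Laplace residual at interpolated vertices
        adj = mesh.adjacency()
        deg = np.asarray(adj.sum(axis=1)).ravel()
        resid = out.values - (adj @ out.values) / deg
        assert np.max(np.abs(resid[~partial.known])) < 1e-8

    def test_linearity_in_boundary_values(self, small_phantom):
        _, _, _, mesh, _ = small_phantom
        rng = np.random.default_rng(3)
        idx = rng.choice(mesh.n_vertices, size=15, replace=False)
        known = np.zeros(mesh.n_vertices, dtype=bool)
        known[idx] = True
        f = np.full(mesh.n_vertices, np.nan)
        g = np.full(mesh.n_vertices, np.nan)
        f[idx] = rng.uniform(-1, 1, 15)
        g[idx] = rng.uniform(-1, 1, 15)
        interp = lambda v: relax_interpolate(NodeScalarMap(v, known), mesh).values  # noqa: E731
        combo = np.full(mesh.n_vertices, np.nan)
        combo[idx] = 2.0 * f[idx] - 3.0 * g[idx]
        np.testing.assert_allclose(interp(combo), 2.0 * interp(f) - 3.0 * interp(g),
                                   atol=1e-8)

    def test_direct_and_jacobi_relaxation_agree(self):
        mesh = PathMesh(12)
        partial = NodeScalarMap.empty(12)
        partial.values[[0, 11]] = [1.0, 4.0]
        partial.known[[0, 11]] = True
        a = relax_interpolate(partial, mesh, method="direct")
        b = relax_interpolate(partial, mesh, method="jacobi")
        np.testing.assert_allclose(a.values, b.values, atol=1e-7)

    def test_no_known_vertices_rejected(self, tetra_mesh):
        with pytest.raises(EamError):
            relax_interpolate(NodeScalarMap.empty(4), tetra_mesh)

    def test_unreachable_component_named(self):
        # two disjoint path graphs glued into one adjacency; the second has
        # no known vertex
        from scipy.sparse import block_diag

        class TwoComponents:
            n_vertices = 8

            def adjacency(self):
                return block_diag([PathMesh(4).adjacency(), PathMesh(4).adjacency()]).tocsr()

        partial = NodeScalarMap.empty(8)
        partial.values[0] = 1.0
        partial.known[0] = True
        with pytest.raises(EamError, match="component"):
            relax_interpolate(partial, TwoComponents())

    def test_length_mismatch_rejected(self, tetra_mesh):
        with pytest.raises(MeshError):
            relax_interpolate(NodeScalarMap.empty(7), tetra_mesh)


class TestBinarize:
    def test_strictly_below_threshold(self):
        m = NodeScalarMap(np.array([1.49, 1.50, 1.51]), np.ones(3, dtype=bool))
        assert binarize_map(m, 1.5).labels.tolist() == [1, 0, 0]

    def test_zero_threshold_all_normal(self):
        m = NodeScalarMap(np.array([0.2, 1.0, 4.0]), np.ones(3, dtype=bool))
        assert binarize_map(m, 0.0).count() == 0

    def test_abnormal_set_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        m = NodeScalarMap(rng.uniform(0, 5, 100), np.ones(100, dtype=bool))
        prev = binarize_map(m, 0.5).labels
        for t in (1.0, 2.0, 3.5):
            cur = binarize_map(m, t).labels
            assert np.all(prev <= cur)
            prev = cur

    def test_non_finite_rejected(self):
        m = NodeScalarMap(np.array([1.0, np.nan]), np.array([True, False]))
        with pytest.raises(EamError):
            binarize_map(m, 1.5)


class TestClassifySqrs:
    def test_exactly_forty_is_normal(self):
        sites = [PaceSite(np.zeros(3), True, s_qrs_ms=40.0)]
        assert classify_sqrs(sites).categories == ["normal"]

    def test_published_proportions(self):
        # 103 captured sites: 56 at or below 40 ms, 47 above
        sites = ([PaceSite(np.zeros(3), True, s_qrs_ms=30.0)] * 56
                 + [PaceSite(np.zeros(3), True, s_qrs_ms=60.0)] * 47
                 + [PaceSite(np.zeros(3), False)] * 10)
        out = classify_sqrs(sites)
        assert out.n_captured == 103 and out.n_no_capture == 10
        assert round(100 * out.prop_normal, 1) == 54.4
        assert round(100 * out.prop_slow, 1) == 45.6

    def test_counts_conserved(self):
        rng = np.random.default_rng(5)
        sites = []
        for _ in range(60):
            if rng.random() < 0.2:
                sites.append(PaceSite(np.zeros(3), False))
            else:
                sites.append(PaceSite(np.zeros(3), True, s_qrs_ms=float(rng.uniform(0, 120))))
        out = classify_sqrs(sites)
        assert out.n_normal + out.n_slow + out.n_no_capture == out.n_sites == 60

    def test_very_slow_flag(self):
        sites = [PaceSite(np.zeros(3), True, s_qrs_ms=v) for v in (85.0, 80.0, 79.0, 20.0)]
        out = classify_sqrs(sites)
        assert out.n_very_slow == 2 and out.n_slow == 3

    def test_negative_delay_rejected(self):
        with pytest.raises(EamError):
            PaceSite(np.zeros(3), True, s_qrs_ms=-1.0)

    def test_sqrs_requires_capture(self):
        with pytest.raises(EamError):
            PaceSite(np.zeros(3), False, s_qrs_ms=50.0)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_sqrs([], slow_ms=80.0, very_slow_ms=40.0)


class TestEgmSnr:
    @pytest.mark.parametrize("amp,noise,expected",
                             [(0.1, 0.1, 1.0), (4.478, 0.1, 44.78), (0.2, 0.1, 2.0)])
    def test_ratio(self, amp, noise, expected):
        assert egm_snr(amp, noise) == pytest.approx(expected)

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(EamError):
            egm_snr(1.0, 0.0)
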