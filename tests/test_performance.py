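import numpy as np
import pytest

import jawscape as jw
from jawscape.meshing import FunctionalNodes
from oracles import triangle_exact_inertia

from conftest import circle_loop, ellipse_loop, rect_loop


def unit_mass(mesh: jw.TriMesh) -> jw.TriMesh:
    from dataclasses import replace

    return replace(mesh, density=1.0 / mesh.total_area)


@pytest.fixture(scope="module")
def bar_mesh():
    """3 x 0.3 rectangle meshed at ~2500 elements with unit total mass."""
    return unit_mass(jw.triangulate(rect_loop(3.0, 0.3), 2500))


def manual_nodes(mesh: jw.TriMesh, joint_xy, bite_xy) -> FunctionalNodes:
    ji = int(np.argmin(np.linalg.norm(mesh.nodes - np.asarray(joint_xy), axis=1)))
    bi = int(np.argmin(np.linalg.norm(mesh.nodes - np.asarray(bite_xy), axis=1)))
    return FunctionalNodes(joint=ji, bite=bi, muscle=ji, normals=np.zeros((len(mesh.boundary_nodes), 2)))


class TestMomentOfInertia:
    def test_rectangle_closed_form(self, bar_mesh):
        """Unit-mass 3 x 0.3 plate about its short-edge midpoint:
        I = m (L^2/3 + w^2/12) = 3.0075."""
        I = jw.moment_of_inertia(bar_mesh, (0.0, 0.15))
        assert I == pytest.approx(3.0075, rel=0.005)

    def test_parallel_axis(self):
        mesh = unit_mass(jw.triangulate(rect_loop(1.0, 1.0), 2000))
        c = mesh.mass_centroid()
        Ic = jw.moment_of_inertia(mesh, c)
        for d_vec in ((0.4, 0.0), (0.2, 0.3)):
            p = c + np.asarray(d_vec)
            Ip = jw.moment_of_inertia(mesh, p)
            assert Ip >= Ic
            assert Ip == pytest.approx(Ic + np.dot(d_vec, d_vec), rel=0.005)

    def test_scaling_law(self, bar_mesh):
        from dataclasses import replace

        s = 2.5
        scaled = replace(bar_mesh, nodes=s * bar_mesh.nodes, density=bar_mesh.density / s**2)
        I0 = jw.moment_of_inertia(bar_mesh, (0.0, 0.15))
        I1 = jw.moment_of_inertia(scaled, (0.0, s * 0.15))
        assert I1 == pytest.approx(s**2 * I0, rel=1e-9)

    def test_centroid_lumping_close_to_exact(self, bar_mesh):
        """The centroid-lumped sum is a small approximation to the exact
        per-triangle polar moment integral."""
        axis = (0.0, 0.15)
        exact = sum(
            triangle_exact_inertia(*bar_mesh.nodes[tri], m, axis)
            for tri, m in zip(bar_mesh.elements, bar_mesh.element_mass)
        )
        lumped = jw.moment_of_inertia(bar_mesh, axis)
        assert lumped == pytest.approx(exact, rel=2e-3)

    def test_empty_mesh_rejected(self, bar_mesh):
        from dataclasses import replace

        empty = replace(bar_mesh, elements=bar_mesh.elements[:0])
        with pytest.raises(ValueError):
            jw.moment_of_inertia(empty, (0, 0))


class TestRotationalEfficiency:
    def test_bar_closed_form(self, bar_mesh):
        """v = L sqrt(2/I) = 3 sqrt(2/3.0075) ~ 2.447 for the unit-mass bar
        rotating about its short-edge midpoint."""
        fn = manual_nodes(bar_mesh, (0.0, 0.15), (3.0, 0.15))
        r = jw.rotational_efficiency(bar_mesh, fn)
        assert r.v == pytest.approx(3.0 * np.sqrt(2.0 / 3.0075), rel=0.005)
        assert r.v == pytest.approx(r.L * np.sqrt(2.0 * r.E_rot / r.I), rel=1e-10)

    def test_energy_integration_oracle(self, bar_mesh):
        """v from the formula matches v from solving E = sum 1/2 m (w r)^2
        for w and taking v = L w."""
        fn = manual_nodes(bar_mesh, (0.0, 0.15), (3.0, 0.15))
        r = jw.rotational_efficiency(bar_mesh, fn)
        joint = bar_mesh.nodes[fn.joint]
        r2 = np.sum((bar_mesh.element_centroid - joint) ** 2, axis=1)
        # KE(w) = 0.5 w^2 sum(m r^2) = 1  =>  w = sqrt(2 / sum(m r^2))
        w = np.sqrt(2.0 / np.sum(bar_mesh.element_mass * r2))
        assert r.v == pytest.approx(r.L * w, rel=1e-6)

    def test_scale_invariance_at_fixed_mass(self, bar_mesh):
        from dataclasses import replace

        s = 3.0
        scaled = replace(bar_mesh, nodes=s * bar_mesh.nodes, density=bar_mesh.density / s**2)
        fn = manual_nodes(bar_mesh, (0, 0.15), (3, 0.15))  # same nodes, scaled
        v0 = jw.rotational_efficiency(bar_mesh, fn).v
        v1 = jw.rotational_efficiency(scaled, fn).v
        assert v1 == pytest.approx(v0, rel=1e-9)

    def test_posterior_mass_beats_anterior_mass(self):
        """Concentrating mass near the joint (deep posterior) gives faster
        jaw closure than the mirrored anterior-deep shape."""
        vs = {}
        for name, (da, dp) in {"ant": (0.40, 0.12), "post": (0.12, 0.40)}.items():
            loop = jw.generate_jaw(jw.JawParams(depth_anterior=da, depth_posterior=dp), K=400)
            mesh = unit_mass(jw.scale_to_area(jw.triangulate(loop, 1200), 1.0))
            fn = jw.identify_functional_nodes(loop, mesh)
            vs[name] = jw.rotational_efficiency(mesh, fn).v
        assert vs["post"] > vs["ant"]


class TestRelativeArea:
    def test_unit_circle(self):
        h = jw.efa_normalize(jw.efa_forward(circle_loop(3.0, 720), H=10))
        loop = jw.efa_inverse(h, 600)
        assert jw.relative_area(loop, h).rel_area == pytest.approx(np.pi, abs=2e-3)

    def test_two_to_one_ellipse(self):
        """Normalization divides by the first-harmonic semi-major axis of
        the arc-length traversal, so the expected area is pi*a*b/E*^2 with
        E* from the independent quadrature oracle (not pi/2, which would
        assume constant-angle traversal)."""
        from oracles import ellipse_efa_first_harmonic

        h = jw.efa_normalize(jw.efa_forward(ellipse_loop(2.0, 1.0, 720), H=10))
        loop = jw.efa_inverse(h, 600)
        e_star = np.linalg.svd(ellipse_efa_first_harmonic(2.0, 1.0), compute_uv=False)[0]
        assert jw.relative_area(loop, h).rel_area == pytest.approx(
            2 * np.pi / e_star**2, abs=5e-3
        )

    def test_invariant_to_input_pose(self):
        base = jw.generate_jaw(jw.JawParams(), K=400)
        ang = 1.1
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = jw.OutlineLoop(base.points @ R.T + np.array([2.0, 7.0]))
        areas = []
        for lp in (base, moved):
            h = jw.efa_normalize(jw.efa_forward(lp, 30))
            areas.append(jw.relative_area(jw.efa_inverse(h, 400), h).rel_area)
        assert areas[0] == pytest.approx(areas[1], rel=1e-6)

    def test_self_intersecting_rejected(self):
        bow = jw.OutlineLoop(np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float))
        with pytest.raises(ValueError):
            jw.relative_area(bow)


class TestBootstrapRE:
    @pytest.fixture(scope="class")
    def setup(self):
        loop = jw.generate_jaw(jw.JawParams(), K=400)
        mesh = jw.scale_to_area(jw.triangulate(loop, 1200), 1.0)
        return mesh, jw.identify_functional_nodes(loop, mesh)

    def test_zero_jitter_degenerate(self, setup):
        mesh, nodes = setup
        cfg = jw.BootstrapConfig(n_iter=8, node_jitter_frac=0.0, seed=5)
        r = jw.bootstrap_re(mesh, nodes, cfg)
        assert np.ptp(r.values) == 0.0
        point = jw.rotational_efficiency(mesh, nodes).v
        assert r.mean == pytest.approx(point, rel=1e-12)

    def test_seed_determinism(self, setup):
        mesh, nodes = setup
        cfg = jw.BootstrapConfig(n_iter=40, seed=9)
        r1 = jw.bootstrap_re(mesh, nodes, cfg)
        r2 = jw.bootstrap_re(mesh, nodes, cfg)
        np.testing.assert_array_equal(r1.values, r2.values)

    def test_ci_width_shrinks_with_jitter(self, setup):
        mesh, nodes = setup
        widths = []
        for jit in (0.05, 0.02, 0.005):
            cfg = jw.BootstrapConfig(n_iter=300, node_jitter_frac=jit, seed=2)
            r = jw.bootstrap_re(mesh, nodes, cfg)
            widths.append(r.ci_high - r.ci_low)
        assert widths[0] > widths[1] > widths[2]
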