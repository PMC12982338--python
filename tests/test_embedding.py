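"""Beam-in-solid embedding and dynamic/static axonal strain."""

import numpy as np
import pytest

import axonstrain as ax
from axonstrain.embedding import axonal_strain_static, strain_from_stretch

from conftest import affine_history, random_affine_matrix, rigid_history


class TestEmbedding:
    def test_straight_fiber_in_row_mesh(self):
        mesh = ax.make_box_mesh(10, 1, 1, 1.0)
        tracts = ax.TractSet()
        tracts.add("T", ax.Fiber(np.column_stack([
            np.arange(11, dtype=float), np.full(11, 0.5), np.full(11, 0.5)])))
        emb = ax.embed_fibers(mesh, tracts)
        assert emb.n_beams == 10
        # node k on the shared face of elements k-1/k goes to the lower index
        expected_hosts = [0] + list(range(10))
        assert emb.node_element.tolist() == expected_hosts
        # xi_x spans -1 -> +1 across each element
        assert emb.node_xi[0, 0] == pytest.approx(-1.0)
        assert emb.node_xi[1, 0] == pytest.approx(1.0)
        assert emb.node_xi[-1, 0] == pytest.approx(1.0)

    def test_fiber_outside_mesh_dropped_and_recorded(self, box_mesh):
        tracts = ax.TractSet()
        tracts.add("IN", ax.Fiber(np.array([[0.2, 0.5, 0.5], [2.5, 0.5, 0.5]])))
        tracts.add("OUT", ax.Fiber(np.array([[10.0, 10, 10], [12.0, 10, 10]])))
        emb = ax.embed_fibers(box_mesh, tracts)
        assert emb.dropped == [("OUT", 0)]
        assert emb.n_fibers == 1

    def test_near_boundary_node_snapped(self, box_mesh):
        tracts = ax.TractSet()
        tracts.add("T", ax.Fiber(np.array([[-0.2, 0.5, 0.5], [2.0, 0.5, 0.5]])))
        emb = ax.embed_fibers(box_mesh, tracts, snap_tol_mm=0.5)
        assert emb.n_fibers == 1
        assert emb.snapped == 1

    def test_reference_lengths_positive(self, box_mesh):
        tracts = ax.make_bundle("straight", 3, start=(0.3, 0.4, 0.5),
                                direction=(1, 0, 0), length=2.0, spread=0.2,
                                seed=0)
        emb = ax.embed_fibers(box_mesh, tracts)
        assert np.all(emb.ref_lengths > 0)


class TestDynamicStrain:
    def _embed_line(self, mesh, direction, start=(0.2, 0.5, 0.5), length=2.0):
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        nodes = np.asarray(start) + np.outer(np.linspace(0, length, 5), d)
        tracts = ax.TractSet()
        tracts.add("T", ax.Fiber(nodes))
        return ax.embed_fibers(mesh, tracts)

    def test_uniaxial_stretch_measures(self, box_mesh):
        emb = self._embed_line(box_mesh, (1, 0, 0))
        disp = affine_history(box_mesh, np.diag([1.2, 1.0, 1.0]))
        for measure, expected in [("green", 0.22), ("engineering", 0.2),
                                  ("logarithmic", np.log(1.2))]:
            hist = ax.axonal_strain_dynamic(emb, box_mesh, disp, measure=measure)
            assert np.allclose(hist.peaks, expected, atol=1e-12)
            assert hist.measure == measure

    def test_diagonal_fiber_stretch(self, box_mesh):
        # fiber along (1,1,0)/sqrt2 under F = diag(1.2,1,1):
        # lambda^2 = (1.44+1)/2 = 1.22
        emb = self._embed_line(box_mesh, (1, 1, 0), start=(0.2, 0.2, 0.5))
        disp = affine_history(box_mesh, np.diag([1.2, 1.0, 1.0]))
        hist = ax.axonal_strain_dynamic(emb, box_mesh, disp, measure="engineering")
        assert np.allclose(hist.peaks, np.sqrt(1.22) - 1.0, atol=1e-12)
        assert np.sqrt(1.22) - 1 == pytest.approx(0.10453610, abs=1e-7)

    def test_rigid_rotation_zero_strain(self, box_mesh, rng):
        emb = self._embed_line(box_mesh, (1, 0.4, 0.2))
        disp = rigid_history(box_mesh, rng)
        hist = ax.axonal_strain_dynamic(emb, box_mesh, disp)
        assert np.max(np.abs(hist.strain)) < 1e-10

    def test_fiber_reversal_invariance(self, box_mesh, rng):
        d = rng.normal(size=3)
        nodes = np.array([1.5, 1.5, 1.5]) + np.outer(
            np.linspace(-1, 1, 5), d / np.linalg.norm(d))
        fw, bw = ax.TractSet(), ax.TractSet()
        fw.add("T", ax.Fiber(nodes))
        bw.add("T", ax.Fiber(nodes[::-1]))
        disp = affine_history(box_mesh, random_affine_matrix(rng))
        h1 = ax.axonal_strain_dynamic(ax.embed_fibers(box_mesh, fw), box_mesh, disp)
        h2 = ax.axonal_strain_dynamic(ax.embed_fibers(box_mesh, bw), box_mesh, disp)
        assert np.allclose(h1.strain, h2.strain[:, ::-1], atol=1e-12)

    def test_peak_monotone_as_history_extends(self, box_mesh, rng):
        emb = self._embed_line(box_mesh, (1, 1, 1), start=(0.2, 0.2, 0.2))
        A = random_affine_matrix(rng)
        times = np.linspace(0, 1, 6)
        disp = affine_history(box_mesh, A, times=times)
        peaks = []
        for k in range(2, 7):
            sub = ax.DisplacementHistory(times[:k], disp.displacements[:k])
            peaks.append(ax.axonal_strain_dynamic(emb, box_mesh, sub).peaks.max())
        assert np.all(np.diff(peaks) >= -1e-15)


class TestStaticStrain:
    def test_projection_examples(self):
        E = np.diag([0.22, 0.0, 0.0])
        assert axonal_strain_static(E, [1, 0, 0]) == pytest.approx(0.22)
        assert axonal_strain_static(np.zeros((3, 3)), [0, 1, 0]) == 0.0
        eng = axonal_strain_static(E, [1, 0, 0], measure="engineering")
        assert eng == pytest.approx(0.2)

    def test_non_unit_axis_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            axonal_strain_static(np.zeros((3, 3)), [1, 1, 0])

    def test_inadmissible_tensor_rejected(self):
        E = np.diag([-0.6, 0.0, 0.0])  # 1 + 2aEa = -0.2
        with pytest.raises(ValueError):
            axonal_strain_static(E, [1, 0, 0], measure="engineering")

    def test_affine_equivalence_dynamic_vs_static(self, rng):
        # homogeneous deformation: both routes give a^T E a per beam
        mesh = ax.make_box_mesh(3, 3, 3, 1.0)
        tracts = ax.make_bundle("straight", 10, start=(0.3, 0.4, 0.5),
                                direction=(1, 0.6, 0.3), length=2.2,
                                spread=0.25, seed=11)
        emb = ax.embed_fibers(mesh, tracts)
        for _ in range(5):
            A = random_affine_matrix(rng)
            disp = affine_history(mesh, A)
            dyn = ax.axonal_strain_dynamic(emb, mesh, disp).strain[-1]
            E = ax.green_lagrange(A)
            vec = (emb.node_ref_coords[emb.beam_nodes[:, 1]]
                   - emb.node_ref_coords[emb.beam_nodes[:, 0]])
            a = vec / np.linalg.norm(vec, axis=1, keepdims=True)
            static = np.einsum("bi,ij,bj->b", a, E, a)
            assert np.max(np.abs(dyn - static)) < 1e-10

    def test_twist_field_dynamic_differs_from_static(self):
        # inhomogeneous field: the difference grows with the twist rate;
        # reported qualitatively, not asserted to zero
        mesh = ax.make_box_mesh(4, 4, 8, 1.0)
        tracts = ax.make_bundle("helix", 6, radius=1.0, pitch=3.0, turns=1.5,
                                center=(2.0, 2.0, 0.5), spread=0.2, seed=5)
        emb = ax.embed_fibers(mesh, tracts)
        diffs = []
        for peak in (0.3, 0.9):
            spec = ax.DeformationSpec(kind="twist", peak=peak, duration=0.01,
                                      length_scale=8.0)
            disp = ax.make_history(mesh, spec, np.linspace(0, 0.005, 3))
            dyn = ax.axonal_strain_dynamic(emb, mesh, disp).strain[-1]
            solid = ax.element_strain_history(mesh, disp).E[-1]
            vec = (emb.node_ref_coords[emb.beam_nodes[:, 1]]
                   - emb.node_ref_coords[emb.beam_nodes[:, 0]])
            a = vec / np.linalg.norm(vec, axis=1, keepdims=True)
            mid_host = emb.node_element[emb.beam_nodes[:, 0]]
            static = np.einsum("bi,bij,bj->b", a, solid[mid_host], a)
            diffs.append(np.max(np.abs(dyn - static)))
        assert diffs[1] > diffs[0] > 0


def test_strain_from_stretch_measures():
    lam = np.array([1.2, 0.9])
    assert np.allclose(strain_from_stretch(lam, "green"), (lam**2 - 1) / 2)
    assert np.allclose(strain_from_stretch(lam, "engineering"), lam - 1)
    assert np.allclose(strain_from_stretch(lam, "logarithmic"), np.log(lam))
    with pytest.raises(ValueError):
        strain_from_stretch(lam, "nope")
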