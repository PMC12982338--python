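"""Streamline I/O, resampling, direction unification, material axes."""

import numpy as np
import pytest

import axonstrain as ax
from axonstrain.tracts import (
    canonicalize_directions,
    export_solid_ortho,
    read_solid_ortho,
    affine_transform_tracts,
)


class TestStreamlineIO:
    def test_tck_round_trip(self, tmp_path, rng):
        sls = [ax.Streamline(np.cumsum(rng.uniform(0.1, 1, (5, 3)), axis=0))
               for _ in range(2)]
        path = tmp_path / "two.tck"
        ax.write_streamlines(path, sls)
        back = ax.read_streamlines(path)
        assert len(back) == 2
        for a, b in zip(sls, back):
            assert a.points.shape == b.points.shape
            assert np.allclose(a.points, b.points, atol=1e-5)

    def test_trk_applies_voxel_affine(self, tmp_path):
        import nibabel as nib

        affine = np.array([
            [2.0, 0, 0, 10.0],
            [0, 2.0, 0, -5.0],
            [0, 0, 2.0, 3.0],
            [0, 0, 0, 1.0],
        ])
        vox_pts = np.array([[0, 0, 0], [1, 0, 0], [2, 1, 0]], dtype=float)
        t = nib.streamlines.Tractogram([vox_pts], affine_to_rasmm=affine)
        path = tmp_path / "one.trk"
        nib.streamlines.save(t, str(path))
        back = ax.read_streamlines(path)
        expected = vox_pts @ affine[:3, :3].T + affine[:3, 3]
        assert np.allclose(back[0].points, expected, atol=1e-4)

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.tck"
        import nibabel as nib
        nib.streamlines.save(
            nib.streamlines.Tractogram([], affine_to_rasmm=np.eye(4)), str(path))
        with pytest.raises(ValueError, match="no streamlines"):
            ax.read_streamlines(path)


class TestResampling:
    def test_straight_10mm(self):
        sl = ax.Streamline(np.array([[0, 0, 0], [10.0, 0, 0]]))
        f = ax.resample_to_beams(sl, step=1.0)
        assert f.nodes.shape[0] == 11
        assert f.n_beams == 10
        assert np.allclose(f.lengths(), 1.0)

    def test_remainder_merged_when_short(self):
        sl = ax.Streamline(np.array([[0, 0, 0], [10.4, 0, 0]]))
        f = ax.resample_to_beams(sl, step=1.0)
        assert f.n_beams == 10  # 0.4 mm remainder merged into last beam
        assert f.lengths()[-1] == pytest.approx(1.4)
        assert np.allclose(f.nodes[-1], [10.4, 0, 0])

    def test_remainder_kept_when_long(self):
        sl = ax.Streamline(np.array([[0, 0, 0], [10.6, 0, 0]]))
        f = ax.resample_to_beams(sl, step=1.0)
        assert f.n_beams == 11
        assert f.lengths()[-1] == pytest.approx(0.6)

    def test_semicircle_arc_length(self):
        r = 10.0
        th = np.linspace(0, np.pi, 400)
        sl = ax.Streamline(np.column_stack(
            [r * np.cos(th), r * np.sin(th), np.zeros_like(th)]))
        f = ax.resample_to_beams(sl, step=1.0)
        assert abs(f.lengths().sum() - np.pi * r) / (np.pi * r) < 0.005

    def test_short_streamline_single_beam(self):
        sl = ax.Streamline(np.array([[0, 0, 0], [0.3, 0, 0]]))
        f = ax.resample_to_beams(sl, step=1.0)
        assert f.n_beams == 1
        assert np.allclose(f.nodes, [[0, 0, 0], [0.3, 0, 0]])

    def test_nonpositive_step_rejected(self):
        sl = ax.Streamline(np.array([[0, 0, 0], [1.0, 0, 0]]))
        with pytest.raises(ValueError):
            ax.resample_to_beams(sl, step=0.0)


class TestCanonicalization:
    @pytest.mark.parametrize("v,expected", [
        ((1, 1, 1), (1, 1, 1)),           # prod > 0: kept
        ((-1, 2, 3), (1, -2, -3)),        # prod = -6 < 0: flipped
        ((1, 0, 0), (1, 0, 0)),           # prod = 0 boundary: unchanged
    ])
    def test_examples(self, v, expected):
        for mode in ("strict", "robust"):
            out = ax.canonicalize_direction(np.array(v, dtype=float), mode=mode)
            assert np.allclose(out, expected)

    def test_robust_resolves_axis_aligned_antipodes(self):
        a = ax.canonicalize_direction(np.array([0.0, -1.0, 0.0]), mode="robust")
        b = ax.canonicalize_direction(np.array([0.0, 1.0, 0.0]), mode="robust")
        assert np.allclose(a, b)
        # strict mode leaves prod=0 vectors alone
        s = ax.canonicalize_direction(np.array([0.0, -1.0, 0.0]), mode="strict")
        assert np.allclose(s, [0.0, -1.0, 0.0])

    def test_idempotent_and_antipodal_collapse(self, rng):
        v = rng.normal(size=(2000, 3))
        prod = v.prod(axis=1)
        v = v[prod != 0]
        once = canonicalize_directions(v)
        twice = canonicalize_directions(once)
        assert np.allclose(once, twice)
        flipped = canonicalize_directions(-v)
        assert np.allclose(once, flipped)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            ax.canonicalize_direction(np.zeros(3))


class TestMaterialAxes:
    def test_single_fiber_along_x(self, box_mesh):
        tracts = ax.TractSet()
        tracts.add("T", ax.Fiber(np.array([[0.1, 0.5, 0.5], [2.9, 0.5, 0.5]])))
        field = ax.assign_material_axes(box_mesh, tracts)
        assert field.present.sum() >= 1
        for e in np.nonzero(field.present)[0]:
            assert np.allclose(np.abs(field.axes[e]), [1, 0, 0], atol=1e-12)

    def test_antipodal_fibers_average_coherently(self, box_mesh):
        d = np.array([1.0, 1.0, 0.0])
        tracts = ax.TractSet()
        c = np.array([1.5, 1.5, 1.5])
        tracts.add("T", ax.Fiber(np.array([c - 0.4 * d / np.sqrt(2),
                                           c + 0.4 * d / np.sqrt(2)])))
        tracts.add("T", ax.Fiber(np.array([c + 0.4 * d / np.sqrt(2) + [0, 0, 0.1],
                                           c - 0.4 * d / np.sqrt(2) + [0, 0, 0.1]])))
        field = ax.assign_material_axes(box_mesh, tracts)
        e = box_mesh.locate_point(c).element_index
        assert field.present[e]
        assert np.allclose(np.abs(field.axes[e] @ (d / np.linalg.norm(d))), 1.0,
                           atol=1e-6)

    def test_untraversed_elements_absent(self, box_mesh):
        tracts = ax.TractSet()
        tracts.add("T", ax.Fiber(np.array([[0.1, 0.5, 0.5], [0.9, 0.5, 0.5]])))
        field = ax.assign_material_axes(box_mesh, tracts)
        assert field.present.sum() == 1
        assert (~field.present).sum() == box_mesh.n_elements - 1

    def test_invariant_to_fiber_reversal(self, box_mesh, rng):
        tracts = ax.TractSet()
        rev = ax.TractSet()
        for _ in range(8):
            p0 = rng.uniform(0.3, 2.7, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            nodes = np.array([p0 - 0.35 * d, p0, p0 + 0.35 * d])
            tracts.add("T", ax.Fiber(nodes))
            rev.add("T", ax.Fiber(nodes[::-1]))
        f1 = ax.assign_material_axes(box_mesh, tracts)
        f2 = ax.assign_material_axes(box_mesh, rev)
        assert np.array_equal(f1.present, f2.present)
        assert np.allclose(f1.axes, f2.axes, atol=1e-12)


class TestTransformAndExport:
    def _bundle(self, rng):
        return ax.make_bundle("straight", 4, start=(0.3, 0.4, 0.5),
                              direction=(1, 0.3, 0.1), length=2.0,
                              spread=0.2, seed=int(rng.integers(1 << 30)))

    def test_identity_transform_bitwise(self, rng):
        tracts = self._bundle(rng)
        out = affine_transform_tracts(tracts, np.eye(4))
        for (t1, _, f1), (t2, _, f2) in zip(tracts.fibers(), out.fibers()):
            assert t1 == t2
            assert np.array_equal(f1.nodes, f2.nodes)

    def test_uniform_scale_doubles_lengths(self, rng):
        tracts = self._bundle(rng)
        M = np.diag([2.0, 2.0, 2.0, 1.0])
        out = affine_transform_tracts(tracts, M)
        for (_, _, f1), (_, _, f2) in zip(tracts.fibers(), out.fibers()):
            assert np.allclose(f2.lengths(), 2.0 * f1.lengths())
        assert out.n_fibers == tracts.n_fibers

    def test_solid_ortho_round_trip(self, tmp_path, box_mesh):
        tracts = ax.TractSet()
        tracts.add("T", ax.Fiber(np.array([[0.1, 0.5, 0.5], [2.9, 1.5, 1.0]])))
        field = ax.assign_material_axes(box_mesh, tracts)
        path = tmp_path / "ortho.k"
        skipped = export_solid_ortho(field, box_mesh, path)
        assert skipped == int((~field.present).sum())
        axes = read_solid_ortho(path)
        assert len(axes) == int(field.present.sum())
        for e, a in axes.items():
            assert np.allclose(a, field.axes[e], atol=1e-6)
            # the exported pair is orthonormal
            txt = path.read_text()
        assert "*ELEMENT_SOLID_ORTHO" in txt
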