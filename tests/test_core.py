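"""Grid conventions, warping primitives and graph-type invariants."""

import numpy as np
import pytest

from ehugs import (
    DisplacementField,
    ImageVolume,
    LabelVolume,
    PopulationGraph,
    apply_warp,
    apply_warp_labels,
    compose,
    load_field,
    load_image,
    load_labels,
    make_identity_warp,
    min_interior_jacobian,
    save_field,
    save_image,
    save_labels,
)
from ehugs.core import warp_array


class TestIdentityWarp:
    @pytest.mark.parametrize("shape", [(4, 4), (8, 8), (6, 5, 7)])
    def test_identity_is_exact_on_intensities(self, shape, rng):
        img = rng.random(shape)
        ident = make_identity_warp(shape)
        assert not ident.displacements.any()
        assert np.array_equal(warp_array(img, ident.displacements, order=1), img)
        assert np.array_equal(warp_array(img, ident.displacements, order=0), img)

    def test_compose_of_identities_is_identity(self):
        ident = make_identity_warp((4, 4))
        assert not compose(ident, ident).displacements.any()

    def test_identity_max_error_zero(self, rng):
        img = ImageVolume(rng.random((8, 8)))
        out = apply_warp(img, make_identity_warp((8, 8)))
        assert np.abs(out.data - img.data).max() == 0.0


class TestComposition:
    def test_identity_is_neutral(self, rng):
        f = DisplacementField(0.3 * rng.standard_normal((12, 12, 2)))
        ident = make_identity_warp((12, 12))
        assert np.allclose(compose(ident, f).displacements, f.displacements)
        assert np.allclose(compose(f, ident).displacements, f.displacements)

    def test_constant_translations_add(self):
        shape = (16, 16)
        a = DisplacementField(np.broadcast_to([0.7, -0.4], (*shape, 2)).copy())
        b = DisplacementField(np.broadcast_to([-0.2, 0.9], (*shape, 2)).copy())
        c = compose(a, b).displacements
        interior = c[3:-3, 3:-3]
        assert np.allclose(interior, [0.5, 0.5], atol=1e-9)

    def test_composite_warp_equals_sequential_warp(self, rng):
        from scipy import ndimage

        from tests.conftest import smooth_velocity
        from ehugs import exp_map

        # smooth test image: the interpolation-error bound scales with the
        # image's second derivatives
        img = ImageVolume(ndimage.gaussian_filter(rng.random((32, 32)), 2.0))
        f = exp_map(smooth_velocity(rng, (32, 32), 1.5))
        g = exp_map(smooth_velocity(rng, (32, 32), 1.5))
        once = apply_warp(img, compose(f, g)).data
        twice = apply_warp(apply_warp(img, f), g).data
        # interpolation error bound, interior only
        assert np.abs(once - twice)[4:-4, 4:-4].max() < 0.15


class TestLabelWarping:
    def test_labels_stay_in_label_set(self, rng):
        lab = LabelVolume(rng.integers(0, 4, (20, 20)))
        disp = DisplacementField(0.8 * rng.standard_normal((20, 20, 2)))
        out = apply_warp_labels(lab, disp)
        assert set(np.unique(out.data)) <= {0, 1, 2, 3}

    def test_out_of_domain_labels_become_background(self):
        lab = LabelVolume(np.full((10, 10), 2))
        disp = DisplacementField(np.full((10, 10, 2), 20.0))  # samples far outside
        out = apply_warp_labels(lab, disp)
        assert (out.data == 0).all()


class TestJacobian:
    def test_identity_has_unit_jacobian(self):
        assert min_interior_jacobian(make_identity_warp((16, 16))) == pytest.approx(1.0)

    def test_smooth_small_warp_is_diffeomorphic(self, rng):
        from tests.conftest import smooth_velocity
        from ehugs import exp_map

        warp = exp_map(smooth_velocity(rng, (32, 32), 2.0))
        assert min_interior_jacobian(warp) > 0.0


class TestPopulationGraphInvariants:
    @staticmethod
    def _star_graph(n):
        E = np.zeros((n, n), dtype=int)
        E[0, 1:] = E[1:, 0] = 1
        return PopulationGraph(E, np.zeros(n, dtype=int), {0: 0}, 0)

    def test_valid_star_passes(self):
        self._star_graph(6).validate()

    def test_edge_count_and_neighbors(self):
        g = self._star_graph(6)
        assert g.n_edges == 5
        assert len(g.edges()) == 5
        assert list(g.neighbors(0)) == [1, 2, 3, 4, 5]

    def test_self_connection_rejected(self):
        g = self._star_graph(4)
        g.connection[2, 2] = 1
        with pytest.raises(AssertionError):
            g.validate()

    def test_disconnected_rejected(self):
        g = self._star_graph(4)
        g.connection[0, 3] = g.connection[3, 0] = 0
        with pytest.raises(AssertionError):
            g.validate()


class TestNiftiRoundtrip:
    def test_image_roundtrip(self, tmp_path, rng):
        img = ImageVolume(rng.random((16, 16)).astype(np.float32), (1.5, 2.0), "x")
        save_image(img, tmp_path / "x.nii.gz")
        back = load_image(tmp_path / "x.nii.gz", id="x")
        assert np.allclose(back.data, img.data, atol=1e-6)
        assert back.spacing == (1.5, 2.0)

    def test_label_roundtrip(self, tmp_path, rng):
        lab = LabelVolume(rng.integers(0, 4, (12, 12)), id="l")
        save_labels(lab, tmp_path / "l.nii.gz")
        assert np.array_equal(load_labels(tmp_path / "l.nii.gz").data, lab.data)

    def test_field_roundtrip(self, tmp_path, rng):
        fld = DisplacementField(rng.standard_normal((10, 10, 2)).astype(np.float32))
        save_field(fld, tmp_path / "f.nii.gz")
        back = load_field(tmp_path / "f.nii.gz")
        assert np.allclose(back.displacements, fld.displacements, atol=1e-6)
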