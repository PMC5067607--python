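"""PIV, vector repair, strain rates and fibre-orientation distributions."""

import numpy as np
import pytest

from activegel.dynamics import ContractionCurve
from activegel.image_analysis import (
    PIVParams,
    VelocityField,
    compute_piv,
    orientation_distribution,
    repair_vectors,
    strain_rate,
)
from activegel.synthetic import (
    FibreTextureSpec,
    SyntheticScene,
    penetrating_contraction_field,
    radial_contraction_field,
    render_bead_movie,
    render_fibre_image,
)


def _texture(shape=(160, 160), seed=0):
    return np.random.default_rng(seed).uniform(0, 255, shape)


def _uniform_field(shape, u, v):
    ny, nx = shape
    return VelocityField(
        x=np.arange(nx, dtype=float), y=np.arange(ny, dtype=float),
        u=np.full(shape, float(u)), v=np.full(shape, float(v)),
        score=np.ones(shape), valid=np.ones(shape, dtype=bool),
    )


class TestPIV:
    params = PIVParams(window=16, search=32, iterations=2, grid_spacing=16)

    def test_integer_shift_recovered_exactly(self):
        img = _texture()
        dx, dy = 5, -3
        shifted = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
        vf = compute_piv(img, shifted, self.params)
        assert vf.valid.sum() > 0.5 * vf.valid.size
        assert np.all(vf.u[vf.valid] == dx)
        assert np.all(vf.v[vf.valid] == dy)
        assert np.all(vf.score[vf.valid] > 0.99)

    def test_translation_equivariance(self):
        """Translating both frames by the same integer vector leaves the
        displacement field unchanged."""
        img = _texture(seed=1)
        moved = np.roll(np.roll(img, 2, axis=0), 1, axis=1)
        base = compute_piv(img, moved, self.params)
        both = compute_piv(np.roll(img, 4, axis=1), np.roll(moved, 4, axis=1),
                           self.params)
        sel = base.valid & both.valid
        assert np.allclose(base.u[sel], both.u[sel])
        assert np.allclose(base.v[sel], both.v[sel])

    def test_featureless_window_invalid_not_fatal(self):
        img = _texture(seed=2)
        img[40:120, 40:120] = 37.0           # large flat patch
        vf = compute_piv(img, img, self.params)
        assert not vf.valid.all()
        assert vf.valid.any()

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            compute_piv(np.zeros((30, 30)), np.zeros((30, 30)), self.params)
        with pytest.raises(ValueError):
            compute_piv(np.zeros((64, 64)), np.zeros((64, 32)), self.params)

    def test_radial_contraction_recovered(self):
        """PIV on a synthetic bead movie advected by the model's radial
        contraction field recovers the field to sub-0.2 px RMS."""
        scene = SyntheticScene(size=(256, 256), seed=3)
        curve = ContractionCurve(L_init=80.0, K=0.23, tau=12.0)
        field = radial_contraction_field((128.0, 128.0), 80.0, curve)
        stack, _ = render_bead_movie(scene, field, [0.0, 3.0])
        vf = compute_piv(stack[0], stack[1])
        X, Y = np.meshgrid(vf.x, vf.y)
        du, dv = field(X, Y, 3.0)
        assert vf.valid.sum() > 0.9 * vf.valid.size
        rms = np.sqrt(np.mean((vf.u[vf.valid] - du[vf.valid]) ** 2
                              + (vf.v[vf.valid] - dv[vf.valid]) ** 2))
        assert rms < 0.2


class TestRepairVectors:
    def test_single_invalid_amid_uniform_field(self):
        vf = _uniform_field((5, 5), 3.0, 0.0)
        vf.valid[2, 2] = False
        vf.u[2, 2] = 99.0
        out = repair_vectors(vf)
        assert out.u[2, 2] == 3.0
        assert out.v[2, 2] == 0.0
        assert out.valid.all()

    def test_median_of_neighbours(self):
        vf = _uniform_field((3, 3), 0.0, 0.0)
        vf.u[:] = np.array([[1, 2, 3], [4, 0, 5], [100, 101, 102]], float)
        vf.valid[1, 1] = False
        out = repair_vectors(vf)
        assert out.u[1, 1] == np.median([1, 2, 3, 4, 5, 100, 101, 102])

    def test_identity_on_valid_field_and_idempotence(self):
        vf = _uniform_field((4, 4), 1.0, -2.0)
        out = repair_vectors(vf)
        assert np.array_equal(out.u, vf.u) and np.array_equal(out.v, vf.v)
        vf.valid[0, 0] = vf.valid[3, 3] = False
        once = repair_vectors(vf)
        twice = repair_vectors(once)
        assert np.array_equal(once.u, twice.u)
        assert np.array_equal(once.valid, twice.valid)

    def test_all_invalid_warns_and_returns_unchanged(self):
        vf = _uniform_field((3, 3), 1.0, 1.0)
        vf.valid[:] = False
        with pytest.warns(UserWarning):
            out = repair_vectors(vf)
        assert not out.valid.any()


class TestStrainRate:
    def test_uniform_translation_is_strain_free(self):
        vf = _uniform_field((6, 6), 4.0, -1.0)
        assert strain_rate(vf, (0, 5, 0, 5), "x") == pytest.approx(0.0)

    def test_linear_field_slope_exact(self):
        vf = _uniform_field((6, 6), 0.0, 0.0)
        X, _ = np.meshgrid(vf.x, vf.y)
        vf.u = 0.25 * X
        assert strain_rate(vf, (0, 5, 0, 5), "x") == pytest.approx(0.25)
        assert strain_rate(vf, (0, 5, 0, 5), "x", dt=2.0) == pytest.approx(0.125)

    def test_degenerate_region_rejected(self):
        vf = _uniform_field((6, 6), 0.0, 0.0)
        with pytest.raises(ValueError):
            strain_rate(vf, (2.1, 2.9, 0, 5), "x")

    def test_boundary_contracts_before_centre(self):
        """With a contraction front penetrating from the interface, the
        early-time strain rate measured by PIV is larger near the boundary
        of the activated disk than at its centre."""
        scene = SyntheticScene(size=(256, 256), seed=4)
        curve = ContractionCurve(L_init=100.0, K=0.23, tau=12.0)
        field = penetrating_contraction_field((128.0, 128.0), 100.0, curve)
        stack, _ = render_bead_movie(scene, field, [3.0, 4.5])
        vf = compute_piv(stack[0], stack[1])
        vf = repair_vectors(vf)
        # boxes on the left interface (x ~ 28..58) and at the centre
        near = abs(strain_rate(vf, (30, 60, 108, 148), "x", dt=1.5))
        centre = abs(strain_rate(vf, (108, 148, 108, 148), "x", dt=1.5))
        assert near > 2 * centre


class TestOrientation:
    def test_isotropic_texture_flat_histogram(self):
        spec = FibreTextureSpec(size=(1024, 1024), n_fibres=20_000, seed=1)
        dist = orientation_distribution(render_fibre_image(spec), 8.0, 128)
        assert len(dist.values) == 23
        assert dist.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(dist.values > 0)
        # flat at ~1/23 per bin; allow the Monte-Carlo fluctuation of a
        # finite fibre sample
        assert np.abs(dist.values - 1 / 23).max() < 0.006

    def test_stripes_peak_in_containing_bin(self):
        y, x = np.mgrid[0:256, 0:256]
        theta = np.radians(30.0)
        stripes = np.cos(2 * np.pi * 0.1 * (-x * np.sin(theta) + y * np.cos(theta)))
        dist = orientation_distribution(stripes, 8.0, 128)
        lo = dist.bin_edges[dist.mode_bin]
        hi = dist.bin_edges[dist.mode_bin + 1]
        assert lo <= 30.0 <= hi
        # energy concentrated around the stripe orientation
        assert dist.values[dist.mode_bin] > 3 / 23

    def test_rotation_equivariance_mod_180(self):
        y, x = np.mgrid[0:256, 0:256]
        theta = np.radians(30.0)
        stripes = np.cos(2 * np.pi * 0.1 * (-x * np.sin(theta) + y * np.cos(theta)))
        base = orientation_distribution(stripes, 8.0, 128)
        rot = orientation_distribution(np.rot90(stripes), 8.0, 128)
        shift = (rot.mode_angle - base.mode_angle) % 180.0
        assert shift == pytest.approx(90.0, abs=8.0)

    def test_intensity_rescaling_invariance(self):
        spec = FibreTextureSpec(size=(256, 256), n_fibres=800, seed=5)
        img = render_fibre_image(spec)
        a = orientation_distribution(img, 8.0, 128)
        b = orientation_distribution(3.5 * img + 17.0, 8.0, 128)
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_oriented_texture_peaks_at_mu(self):
        spec = FibreTextureSpec(size=(512, 512), n_fibres=5000,
                                orientation_law="von_mises", mu_deg=90.0,
                                kappa=8.0, seed=6)
        dist = orientation_distribution(render_fibre_image(spec), 8.0, 128)
        lo = dist.bin_edges[dist.mode_bin]
        hi = dist.bin_edges[dist.mode_bin + 1]
        assert lo <= 90.0 <= hi

    def test_constant_image_uniform_with_warning(self):
        with pytest.warns(UserWarning):
            dist = orientation_distribution(np.full((128, 128), 7.0), 8.0, 128)
        assert np.allclose(dist.values, 1 / 23)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            orientation_distribution(np.zeros((64, 64)), 8.0, 128)
        with pytest.raises(ValueError):
            orientation_distribution(np.zeros((128, 128)), 0.0, 128)
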