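"""PIV displacement accuracy, drift correction, and divergence analysis."""

import dataclasses

import numpy as np
import pytest

import biofilm_mech as bm
from conftest import grid_displacement_field


def crop_pair(big, shape, margin, dx, dy):
    """ref/cur crops of a larger frame related by a feature shift (dx, dy)."""
    h, w = shape
    ref = big[margin:margin + h, margin:margin + w]
    cur = big[margin - dy:margin - dy + h, margin - dx:margin - dx + w]
    return ref, cur


class TestPivDisplacement:
    def test_identical_frames_zero_field(self, static_bead_frame):
        f = bm.piv_displacement(static_bead_frame[:256, :256],
                                static_bead_frame[:256, :256])
        assert f.mask.any()
        assert np.nanmax(np.abs(f.u)) == pytest.approx(0.0, abs=1e-12)
        assert np.nanmax(np.abs(f.v)) == pytest.approx(0.0, abs=1e-12)

    def test_integer_shift_recovered_everywhere(self, static_bead_frame):
        """A rigid (3, −2) px stage translation is recovered to ≤ 0.05 px by
        every unmasked vector."""
        ref, cur = crop_pair(static_bead_frame, (256, 256), 16, 3, -2)
        f = bm.piv_displacement(ref, cur, pixel_size=1.0)
        err = np.hypot(f.u - 3, f.v + 2)
        assert f.mask.mean() > 0.8
        assert np.nanmax(err[f.mask]) <= 0.05

    def test_subpixel_displacement_rms(self):
        """A uniform 0.4 px true displacement is recovered to ≤ 0.1 px RMS on
        rendered (noisy) bead images."""
        beads = bm.BeadScenario(seed=6)
        model = bm.DisplacementModel(
            drift_per_frame=(0.4 * beads.pixel_size, 0.0))
        stack, _ = bm.generate_bead_stack(beads, model, 2)
        f = bm.piv_displacement(stack[0].astype(float), stack[1].astype(float),
                                pixel_size=1.0)  # report in px
        rms = np.sqrt(np.nanmean((f.u[f.mask] - 0.4) ** 2 + f.v[f.mask] ** 2))
        assert rms <= 0.1

    def test_flat_windows_masked(self):
        rng = np.random.default_rng(0)
        ref = np.full((128, 128), 100.0)
        ref[:64] += rng.uniform(0, 1000, (64, 128))
        f = bm.piv_displacement(ref, ref)
        assert not f.mask[-1].any()  # featureless lower half

    def test_translation_equivariance(self, static_bead_frame):
        """Translating both frames identically leaves the field unchanged;
        translating only cur adds that vector."""
        big = static_bead_frame
        ref0, cur0 = crop_pair(big, (224, 224), 20, 2, 1)
        f0 = bm.piv_displacement(ref0, cur0, pixel_size=1.0)
        # shift both crops by (5, -3)
        ref1 = big[23:23 + 224, 15:15 + 224]
        cur1 = big[22:22 + 224, 13:13 + 224]
        f1 = bm.piv_displacement(ref1, cur1, pixel_size=1.0)
        both = f0.mask & f1.mask
        assert np.allclose(f0.u[both], f1.u[both], atol=0.05)
        assert np.allclose(f0.v[both], f1.v[both], atol=0.05)

    @pytest.mark.parametrize("kwargs", [
        {"window_size": 8}, {"overlap": 1.0}, {"overlap": -0.1},
    ])
    def test_bad_parameters_rejected(self, static_bead_frame, kwargs):
        a = static_bead_frame[:64, :64]
        with pytest.raises(ValueError):
            bm.piv_displacement(a, a, **kwargs)

    def test_shape_mismatch_rejected(self, static_bead_frame):
        with pytest.raises(ValueError):
            bm.piv_displacement(static_bead_frame[:64, :64],
                                static_bead_frame[:65, :65])


class TestAccumulateSeries:
    def test_drift_modes(self, drift_bead_stack):
        """Per-frame drift d: accumulated fields ≈ d and 2d; instantaneous
        fields ≈ d and d."""
        stack, _, model = drift_bead_stack
        d = np.asarray(model.drift_per_frame)
        acc = bm.accumulate_series(stack, mode="first_frame")
        ins = bm.accumulate_series(stack, mode="previous_frame")
        tol = 0.05 * stack.pixel_size
        for t, f in enumerate(acc, start=1):
            assert abs(np.nanmean(f.u[f.mask]) - t * d[0]) < tol
            assert abs(np.nanmean(f.v[f.mask]) - t * d[1]) < tol
        for f in ins:
            assert abs(np.nanmean(f.u[f.mask]) - d[0]) < tol
            assert abs(np.nanmean(f.v[f.mask]) - d[1]) < tol

    def test_static_stack_zero_fields(self):
        beads = bm.BeadScenario(seed=1, noise_sd=0.0)
        stack, _ = bm.generate_bead_stack(beads, bm.DisplacementModel(), 3)
        for f in bm.accumulate_series(stack):
            assert np.nanmax(np.abs(f.u[f.mask])) < 1e-9

    def test_two_frame_modes_agree(self):
        beads = bm.BeadScenario(seed=2)
        model = bm.DisplacementModel(drift_per_frame=(0.7, 0.3))
        stack, _ = bm.generate_bead_stack(beads, model, 2)
        a = bm.accumulate_series(stack, mode="first_frame")[0]
        b = bm.accumulate_series(stack, mode="previous_frame")[0]
        assert np.allclose(a.u, b.u, equal_nan=True)
        assert np.allclose(a.v, b.v, equal_nan=True)

    def test_contractile_field_matches_ground_truth(self, contractile_bead_stack):
        """Accumulated PIV recovers the prescribed contractile field to
        ≤ 0.1 px RMS at every frame."""
        stack, truth, _ = contractile_bead_stack
        for f in bm.accumulate_series(stack):
            X, Y = np.meshgrid(f.x, f.y)
            pts = np.column_stack([X.ravel(), Y.ravel()])
            ut = truth.displacement(pts, f.frame).reshape(f.u.shape + (2,))
            m = f.mask
            rms_px = np.sqrt(np.nanmean(
                (f.u[m] - ut[..., 0][m]) ** 2 + (f.v[m] - ut[..., 1][m]) ** 2
            )) / stack.pixel_size
            assert rms_px <= 0.1

    def test_mode_validated(self, drift_bead_stack):
        stack, _, _ = drift_bead_stack
        with pytest.raises(ValueError):
            bm.accumulate_series(stack, mode="nonsense")


class TestDriftCorrect:
    def test_uniform_field_zeroed_and_recorded(self):
        g = np.arange(16.0, 256.0, 16.0)
        ones = np.ones((len(g), len(g)))
        f = bm.DisplacementField(x=g, y=g, u=0.8 * ones, v=-0.3 * ones,
                                 quality=np.full_like(ones, 5.0),
                                 mask=ones.astype(bool))
        out = bm.drift_correct(f, (0, 0, 255, 255))
        assert np.allclose(out.u, 0.0) and np.allclose(out.v, 0.0)
        assert out.metadata["drift_um"] == pytest.approx((0.8, -0.3))

    def test_pure_drift_stack_residual_small(self, drift_bead_stack):
        """Drift-corrected pure-drift stacks leave ≤ 0.05 px RMS residual and
        record the prescribed drift to 0.05 px."""
        stack, _, model = drift_bead_stack
        W = stack.shape[1] * stack.pixel_size
        d = np.asarray(model.drift_per_frame)
        for f in bm.accumulate_series(stack):
            out = bm.drift_correct(f, (0, 0, W, W))
            res = np.sqrt(np.nanmean(out.u[out.mask] ** 2
                                     + out.v[out.mask] ** 2)) / stack.pixel_size
            assert res <= 0.05
            rec = np.asarray(out.metadata["drift_um"])
            assert np.hypot(*(rec - f.frame * d)) / stack.pixel_size <= 0.05

    def test_idempotent(self, drift_bead_stack):
        stack, _, _ = drift_bead_stack
        f = bm.accumulate_series(stack)[0]
        W = stack.shape[1] * stack.pixel_size
        once = bm.drift_correct(f, (0, 0, W, W))
        twice = bm.drift_correct(once, (0, 0, W, W))
        assert np.hypot(*twice.metadata["drift_um"]) < 1e-9

    def test_empty_region_rejected(self, drift_bead_stack):
        stack, _, _ = drift_bead_stack
        f = bm.accumulate_series(stack)[0]
        with pytest.raises(ValueError):
            bm.drift_correct(f, (-100, -100, -50, -50))


class TestDivergence:
    @staticmethod
    def analytic_field(fn, spacing=8.0, extent=256.0):
        g = np.arange(spacing / 2, extent, spacing)
        X, Y = np.meshgrid(g, g)
        u, v = fn(X, Y)
        return bm.DisplacementField(
            x=g, y=g, u=u, v=v, quality=np.full(X.shape, np.inf),
            mask=np.ones(X.shape, dtype=bool))

    def test_linear_expansion_gives_two(self):
        f = self.analytic_field(lambda X, Y: (X, Y))
        d = bm.divergence(f)
        assert np.allclose(d.div, 2.0)
        assert not d.boundary[1:-1, 1:-1].any()
        assert d.boundary[0].all() and d.boundary[:, 0].all()

    def test_rigid_motions_divergence_free(self):
        for fn in [lambda X, Y: (np.full_like(X, 3.0), np.full_like(Y, -1.0)),
                   lambda X, Y: (-0.01 * Y, 0.01 * X)]:
            d = bm.divergence(self.analytic_field(fn))
            assert np.allclose(d.div, 0.0, atol=1e-12)

    def test_radial_gaussian_matches_analytic(self):
        s, A, c = 60.0, 2.0, 128.0

        def fn(X, Y):
            R2 = (X - c) ** 2 + (Y - c) ** 2
            g = A * np.exp(-R2 / (2 * s * s))
            return g * (X - c) / s, g * (Y - c) / s

        spacing = 4.0
        f = self.analytic_field(fn, spacing=spacing)
        d = bm.divergence(f)
        X, Y = np.meshgrid(f.x, f.y)
        R2 = (X - c) ** 2 + (Y - c) ** 2
        g = A * np.exp(-R2 / (2 * s * s))
        true_div = g / s * (2 - R2 / s**2)
        # second-order central differences: error bound h²/6 · max|∂³u|
        h3 = np.max(np.abs(true_div)) * (spacing / s) ** 2
        inner = ~d.boundary
        assert np.max(np.abs(d.div[inner] - true_div[inner])) < h3

    def test_linearity(self):
        f1 = self.analytic_field(lambda X, Y: (0.1 * X, 0.0 * Y))
        f2 = self.analytic_field(lambda X, Y: (np.sin(X / 40), np.cos(Y / 40)))
        fsum = self.analytic_field(
            lambda X, Y: (0.1 * X + 2 * np.sin(X / 40),
                          0.0 * Y + 2 * np.cos(Y / 40)))
        d = bm.divergence(fsum)
        d1, d2 = bm.divergence(f1), bm.divergence(f2)
        assert np.allclose(d.div, d1.div + 2 * d2.div, atol=1e-12)

    def test_masked_vectors_interpolated_and_flagged(self):
        f = self.analytic_field(lambda X, Y: (X, Y))
        f.mask[10, 10] = False
        f.u[10, 10] = f.v[10, 10] = np.nan
        d = bm.divergence(f)
        assert np.isfinite(d.div).all()
        assert d.boundary[10, 10] and d.boundary[9, 10] and d.boundary[10, 9]

    def test_small_grid_rejected(self):
        g = np.arange(2.0)
        z = np.zeros((2, 2))
        f = bm.DisplacementField(x=g, y=g, u=z, v=z, quality=z,
                                 mask=np.ones((2, 2), bool))
        with pytest.raises(ValueError):
            bm.divergence(f)


class TestDivergenceWaveProfile:
    def test_divergence_free_field_flat_profile(self):
        model = bm.DisplacementModel(drift_per_frame=(1.0, 0.5))
        f = grid_displacement_field(model, frame=1)
        d = bm.divergence(f)
        profiles, peaks = bm.divergence_wave_profile(
            [d], [(np.array([256.0, 256.0]), 150.0)])
        assert np.abs(profiles["mean_div"]).max() < 1e-12

    def test_annulus_magnitude_recovered_and_comoving(self):
        """An edge-locked annulus prescribing peak divergence 0.015 is
        recovered within 10% and its peak tracks the edge within one grid
        spacing across frames."""
        radii = (0.0, 150.0, 180.0, 210.0)
        ann = bm.EdgeAnnulus.for_divergence(0.015, 15.0, radii)
        model = bm.DisplacementModel(contractile_center=(256.0, 256.0),
                                     edge_annulus=ann)
        spacing = 5.0
        fields, edges = [], []
        for t in (1, 2, 3):
            f = grid_displacement_field(model, spacing=spacing, frame=t)
            fields.append(bm.divergence(f))
            edges.append((np.array([256.0, 256.0]), radii[t]))
        _, peaks = bm.divergence_wave_profile(fields, edges)
        assert np.allclose(np.abs(peaks["peak_div"]), 0.015, rtol=0.10)
        assert peaks["peak_distance_um"].max() - peaks["peak_distance_um"].min() \
            <= spacing

    def test_static_annulus_moving_edge_geometry(self):
        """With the annulus frozen in the lab frame, the peak's distance from
        the (moving) edge changes exactly with the edge radius."""
        ann = bm.EdgeAnnulus.for_divergence(0.015, 15.0, (150.0,))
        model = bm.DisplacementModel(contractile_center=(256.0, 256.0),
                                     edge_annulus=ann)
        f = grid_displacement_field(model, spacing=5.0, frame=1)
        d = bm.divergence(f)
        edge_radii = [150.0, 180.0, 210.0]
        copies = [dataclasses.replace(d, frame=i) for i in range(3)]
        _, peaks = bm.divergence_wave_profile(
            copies, [(np.array([256.0, 256.0]), R) for R in edge_radii])
        dist = peaks["peak_distance_um"].to_numpy()
        assert np.allclose(np.diff(dist), -30.0, atol=5.0)

    def test_length_mismatch_rejected(self):
        model = bm.DisplacementModel(drift_per_frame=(1.0, 0.0))
        d = bm.divergence(grid_displacement_field(model, frame=1))
        with pytest.raises(ValueError):
            bm.divergence_wave_profile([d], [])
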