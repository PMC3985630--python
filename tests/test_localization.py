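"""Bleaching-analysis localization: renderer, differencing, fitting, backbone."""

import numpy as np
import pytest

from fluorocode.localization import (
    ImageStack,
    RenderParams,
    bleaching_difference,
    localize_spots,
    project_onto_backbone,
    read_tiff,
    render_movie,
    trace_from_stack,
    write_tiff,
    Localization2D,
)
from fluorocode.traces import MoleculeTrace


def single_label_trace(pos_nm=800.0, length_nm=2000.0):
    return MoleculeTrace("m", np.array([pos_nm]), length_nm)


NOISELESS = dict(poisson_noise=False, background=0.0)


class TestRenderMovie:
    def test_no_noise_no_bleaching_gives_identical_frames(self):
        params = RenderParams(n_frames=5, bleach_prob=0.0, **NOISELESS)
        stack, _ = render_movie(single_label_trace(), params, seed=0)
        for frame in stack.frames[1:]:
            np.testing.assert_array_equal(frame, stack.frames[0])
        assert stack.frames[0].max() > 0

    def test_bleach_time_cuts_spot(self):
        params = RenderParams(n_frames=10, bleach_prob=0.0, **NOISELESS)
        stack, truth = render_movie(
            single_label_trace(), params, seed=0, bleach_frames=[4]
        )
        assert truth[0]["bleach_frame"] == 4
        assert all(stack.frames[t].max() > 0 for t in range(4))
        assert all(stack.frames[t].max() == 0 for t in range(4, 10))

    def test_photon_budget_matches_expectation(self):
        params = RenderParams(
            n_frames=200, bleach_prob=0.0, photons_per_frame=500.0, background=1.0
        )
        trace = MoleculeTrace("m", np.array([500.0, 900.0]), 1500.0)
        stack, _ = render_movie(trace, params, seed=1)
        n_px = stack.frames.shape[1] * stack.frames.shape[2]
        expected = 2 * 500.0 + 1.0 * n_px  # photons per frame
        per_frame = stack.frames.sum(axis=(1, 2))
        sem = np.sqrt(expected / len(per_frame))  # Poisson, averaged over frames
        assert abs(per_frame.mean() - expected) <= 3 * sem

    def test_field_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            render_movie(single_label_trace(), RenderParams(), seed=0, field_shape=(5, 5))


class TestBleachingDifference:
    def test_constant_stack_zero_differences(self):
        params = RenderParams(n_frames=4, bleach_prob=0.0, **NOISELESS)
        stack, _ = render_movie(single_label_trace(), params, seed=0)
        assert np.all(bleaching_difference(stack) == 0)

    def test_single_bleach_event_single_blob(self):
        params = RenderParams(n_frames=8, **NOISELESS)
        stack, _ = render_movie(single_label_trace(), params, seed=0, bleach_frames=[3])
        diffs = bleaching_difference(stack)
        above = [d.max() > 1.0 for d in diffs]
        assert above == [t == 2 for t in range(7)]  # frame 2 - frame 3

    def test_sub_diffraction_pair_separable_across_frames(self):
        # 50 nm apart (half a pixel) but bleaching at different frames
        params = RenderParams(
            n_frames=10, photons_per_frame=5000.0, **NOISELESS
        )
        trace = MoleculeTrace("m", np.array([700.0, 750.0]), 1500.0)
        stack, _ = render_movie(trace, params, seed=0, bleach_frames=[3, 7])
        locs = []
        for t, frame in enumerate(bleaching_difference(stack)):
            locs.extend(
                localize_spots(frame, stack.pixel_size_nm, stack.psf_sigma_px, 5.0, t)
            )
        assert len(locs) == 2
        xs = sorted(l.x_nm for l in locs)
        margin = params.margin_px * params.pixel_size_nm
        assert xs[0] == pytest.approx(margin + 700.0, abs=5.0)
        assert xs[1] == pytest.approx(margin + 750.0, abs=5.0)

    def test_requires_two_frames(self):
        stack = ImageStack(np.zeros((1, 5, 5)), 100.0, 1.3)
        with pytest.raises(ValueError):
            bleaching_difference(stack)


class TestLocalizeSpots:
    def test_empty_frame_no_localizations(self):
        assert localize_spots(np.zeros((15, 15)), 100.0, 1.3, 5.0) == []

    def test_bright_spot_recovered_to_subpixel(self, rng):
        # known sub-pixel centre, >= 1e4 photons
        from fluorocode.localization import _gaussian_spot

        frame = rng.poisson(
            _gaussian_spot(21, 21, 10.37, 9.81, 1.3, 20_000.0) + 2.0
        ).astype(float)
        locs = localize_spots(frame, 100.0, 1.3, 50.0)
        assert len(locs) == 1
        assert locs[0].x_nm / 100.0 == pytest.approx(10.37, abs=0.1)
        assert locs[0].y_nm / 100.0 == pytest.approx(9.81, abs=0.1)

    def test_precision_scales_with_photon_count(self, rng):
        from fluorocode.localization import _gaussian_spot

        sigma_px, px = 1.3, 100.0
        for n_photons in (100.0, 1_000.0, 10_000.0):
            errors = []
            for _ in range(40):
                frame = rng.poisson(
                    _gaussian_spot(15, 15, 7.3, 7.6, sigma_px, n_photons)
                ).astype(float)
                locs = localize_spots(frame, px, sigma_px, n_photons / 50.0)
                if locs:
                    # per-axis error: the 1D map uses the along-backbone axis
                    errors.append(locs[0].x_nm / px - 7.3)
            rms_px = np.sqrt(np.mean(np.square(errors)))
            thompson_px = sigma_px / np.sqrt(n_photons)
            assert rms_px <= 2 * thompson_px
            assert rms_px >= thompson_px / 2


class TestBackboneProjection:
    def test_collinear_points_preserve_distances(self):
        ts = np.array([0.0, 120.0, 515.0, 1200.0])
        direction = np.array([0.6, 0.8])
        locs = [
            Localization2D(50 + t * direction[0], -20 + t * direction[1], 0, 1000.0, 5.0)
            for t in ts
        ]
        trace = project_onto_backbone(locs)
        np.testing.assert_allclose(trace.positions_nm, ts, atol=1e-9)

    def test_orthogonal_noise_rms_recovered(self, rng):
        ts = np.sort(rng.uniform(0, 5000, 200))
        sigma = 12.0
        noise = rng.normal(0, sigma, ts.size)
        pts = np.outer(ts, [0.8, 0.6]) + np.outer(noise, [-0.6, 0.8])
        locs = [Localization2D(x, y, 0, 1000.0, 5.0) for x, y in pts]
        trace = project_onto_backbone(locs)
        # residual orthogonal scatter is what the projection discards;
        # pairwise spacings along the axis are preserved to ~sigma
        assert trace.length_nm == pytest.approx(ts[-1] - ts[0], rel=0.01)

    def test_rotation_invariance_up_to_mirror(self, rng):
        pts = rng.uniform(0, 1000, (30, 2)) * np.array([1.0, 0.01])
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        base = project_onto_backbone(
            [Localization2D(x, y, 0, 1.0, 1.0) for x, y in pts]
        )
        turned = project_onto_backbone(
            [Localization2D(x, y, 0, 1.0, 1.0) for x, y in pts @ rot.T]
        )
        same = np.allclose(base.positions_nm, turned.positions_nm, atol=1e-6)
        mirrored = np.allclose(
            base.positions_nm,
            np.sort(turned.length_nm - turned.positions_nm),
            atol=1e-6,
        )
        assert same or mirrored

    def test_coincident_points_rejected(self):
        locs = [Localization2D(5.0, 5.0, 0, 1.0, 1.0)] * 3
        with pytest.raises(ValueError, match="coincide"):
            project_onto_backbone(locs)


class TestEndToEnd:
    def test_movie_to_trace_recovers_positions(self, rng):
        true_pos = np.sort(rng.uniform(0, 4000, 10))
        trace_in = MoleculeTrace("m", true_pos, 4000.0)
        params = RenderParams(n_frames=24, photons_per_frame=4000.0)
        order = rng.permutation(10)
        bleach = np.empty(10, int)
        bleach[order] = 2 + 2 * np.arange(10)  # distinct bleach intervals
        stack, _ = render_movie(trace_in, params, seed=8, bleach_frames=bleach)
        out = trace_from_stack(stack, threshold=40.0)
        assert out.n_labels == 10  # never exceeds, and recovers all here
        rel_true = true_pos - true_pos.min()
        fwd = out.positions_nm - out.positions_nm.min()
        rev = np.sort(out.length_nm - out.positions_nm)
        rev -= rev.min()
        rms = min(
            np.sqrt(np.mean((fwd - rel_true) ** 2)),
            np.sqrt(np.mean((rev - rel_true) ** 2)),
        )
        # Thompson bound for one frame's photons; differencing doubles the
        # shot-noise variance, and the acceptance band is 2x the bound
        thompson_nm = 1.3 * 100.0 / np.sqrt(4000.0)
        assert rms <= 2 * np.sqrt(2) * thompson_nm

    def test_localization_count_bounded_in_noiseless_fixture(self):
        true_pos = np.array([500.0, 1500.0, 2500.0])
        trace_in = MoleculeTrace("m", true_pos, 3000.0)
        params = RenderParams(n_frames=12, **NOISELESS)
        stack, _ = render_movie(trace_in, params, seed=0, bleach_frames=[2, 5, 8])
        diffs = bleaching_difference(stack)
        n = sum(
            len(localize_spots(f, stack.pixel_size_nm, stack.psf_sigma_px, 1.0))
            for f in diffs
        )
        assert n <= 3


def test_tiff_round_trip(tmp_path):
    params = RenderParams(n_frames=6)
    stack, _ = render_movie(single_label_trace(), params, seed=2)
    p = tmp_path / "movie.tif"
    write_tiff(stack, p)
    back = read_tiff(p, stack.pixel_size_nm, stack.psf_sigma_px)
    assert back.frames.shape == stack.frames.shape
    np.testing.assert_allclose(back.frames, np.round(stack.frames), atol=0.5)
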