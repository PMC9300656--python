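"""Track linking, drift/z corrections, dissociation kinetics, force and SNR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from holotrack import (
    DataError,
    StepTrace,
    Track,
    ZCorrection,
    apply_z_correction,
    contour_length_nm,
    detect_dissociation,
    drift_correct,
    fit_bell,
    fit_survival,
    force_from_fluctuations,
    link_tracks,
    step_snr,
)
from holotrack.localize import Position3D
from holotrack.mt import DissociationRecord, KB_PN_NM_PER_K


def _positions(coords, frame):
    return [Position3D(x=x, y=y, z=z, frame_index=frame) for (x, y, z) in coords]


class TestLinkTracks:
    def test_single_bead_links_into_one_complete_track(self):
        frames = [_positions([(100.0 + i, 200.0, 5_000.0)], i) for i in range(10)]
        tracks = link_tracks(np.arange(10.0), frames, gate_radius=50.0)
        assert len(tracks) == 1
        assert tracks[0].present.all()
        np.testing.assert_allclose(tracks[0].x, 100.0 + np.arange(10))

    def test_gap_recorded_when_bead_vanishes(self):
        frames = [
            _positions([(0.0, 0.0, 0.0)], i) if i not in (4, 5) else []
            for i in range(10)
        ]
        tracks = link_tracks(np.arange(10.0), frames, gate_radius=50.0)
        assert len(tracks) == 1
        assert not tracks[0].present[4] and not tracks[0].present[5]
        assert tracks[0].present.sum() == 8

    def test_brownian_ten_beads_link_perfectly(self, rng):
        n_beads, n_frames = 10, 40
        gate = 2_000.0
        sigma = gate / 8  # step scale well under the gate
        centers = rng.uniform(5_000, 95_000, size=(n_beads, 3))
        paths = centers[None] + np.cumsum(
            rng.normal(0, sigma, size=(n_frames, n_beads, 3)), axis=0
        )
        frames = [
            _positions([tuple(paths[f, b]) for b in range(n_beads)], f)
            for f in range(n_frames)
        ]
        tracks = link_tracks(np.arange(float(n_frames)), frames, gate_radius=gate)
        assert len(tracks) == n_beads
        for tr in tracks:
            assert tr.present.all()
            # the track follows exactly one ground-truth bead
            b = int(np.argmin(np.abs(paths[0, :, 0] - tr.x[0])))
            np.testing.assert_allclose(tr.x, paths[:, b, 0])


class TestDriftCorrect:
    def _make_track(self, bead_id, xyz, role="tethered"):
        n = xyz.shape[0]
        return Track(
            bead_id=bead_id, t=np.arange(float(n)), x=xyz[:, 0], y=xyz[:, 1],
            z=xyz[:, 2], present=np.ones(n, dtype=bool), role=role,
        )

    def test_zero_drift_leaves_tracks_unchanged(self):
        ref = self._make_track(0, np.tile([50.0, 60.0, 0.0], (20, 1)), role="reference")
        moving = self._make_track(1, np.column_stack(
            [np.arange(20.0), np.zeros(20), np.zeros(20)]
        ))
        out = drift_correct([ref, moving], reference_ids=[0])
        np.testing.assert_allclose(out[1].x, moving.x)

    def test_linear_drift_removed(self, rng):
        n = 50
        drift = np.column_stack([np.arange(n) * 1.0, np.zeros(n), np.zeros(n)])
        truth = rng.normal(0, 5, size=(n, 3)) + [1_000.0, 2_000.0, 500.0]
        ref = self._make_track(0, np.tile([50.0, 60.0, 0.0], (n, 1)) + drift,
                               role="reference")
        bead = self._make_track(1, truth + drift)
        out = drift_correct([ref, bead], reference_ids=[0])
        rms = np.sqrt(np.mean((out[1].x - truth[:, 0]) ** 2))
        assert rms < 0.1

    def test_idempotent_after_first_pass(self):
        n = 30
        drift = np.column_stack([np.arange(n) * 2.0, np.arange(n) * -1.0, np.zeros(n)])
        ref = self._make_track(0, np.tile([0.0, 0.0, 0.0], (n, 1)) + drift,
                               role="reference")
        bead = self._make_track(1, np.tile([500.0, 0.0, 0.0], (n, 1)) + drift)
        once = drift_correct([ref, bead], reference_ids=[0])
        twice = drift_correct(once, reference_ids=[0])
        np.testing.assert_allclose(twice[1].x, once[1].x, atol=1e-9)


class TestZCorrection:
    def _track(self, z):
        z = np.asarray(z, dtype=float)
        n = z.size
        return Track(bead_id=0, t=np.arange(float(n)), x=np.zeros(n),
                     y=np.zeros(n), z=z, present=np.ones(n, dtype=bool))

    def test_identity_linear(self):
        tr = self._track([1_000.0, 2_000.0])
        out = apply_z_correction(tr, ZCorrection(mode="linear", slope=1.0, intercept=0.0))
        np.testing.assert_array_equal(out.z, tr.z)

    def test_small_angle_index_ratio(self):
        out = apply_z_correction(
            self._track([10_000.0]),
            ZCorrection(mode="smallangle", n_medium=1.33, n_oil=1.515),
        )
        assert out.z[0] == pytest.approx(1.33 / 1.515 * 10_000.0, abs=1e-9)  # 8778.9 nm

    def test_linear_slope(self):
        out = apply_z_correction(
            self._track([9_000.0]), ZCorrection(mode="linear", slope=1.2, intercept=0.0)
        )
        assert out.z[0] == pytest.approx(10_800.0)

    def test_spline_interpolates_knots(self):
        corr = ZCorrection(
            mode="spline",
            knots=((0.0, 0.0), (5_000.0, 6_000.0), (10_000.0, 13_000.0)),
        )
        out = apply_z_correction(self._track([2_500.0, 7_500.0]), corr)
        np.testing.assert_allclose(out.z, [3_000.0, 9_500.0])

    def test_non_monotonic_spline_rejected(self):
        with pytest.raises(DataError, match="monotonic"):
            ZCorrection(mode="spline", knots=((0.0, 0.0), (5.0, -1.0)))


def _mt_track(t, z, present, bead_id=0):
    t = np.asarray(t, dtype=float)
    n = t.size
    return Track(bead_id=bead_id, t=t, x=np.zeros(n), y=np.zeros(n),
                 z=np.asarray(z, dtype=float), present=np.asarray(present, dtype=bool))


class TestDetectDissociation:
    def test_present_throughout_is_censored(self):
        t = np.arange(0.0, 100.0, 0.5)
        z = np.where(t < 5.0, 0.0, 1_100.0)
        rec = detect_dissociation(_mt_track(t, z, np.ones(t.size)), magnet_on=5.0,
                                  force=9.9)
        assert rec.t_dissoc is None
        assert rec.censored_at == pytest.approx(t[-1] - 5.0)
        assert rec.gate_passed

    def test_dissociation_time_measured_from_magnet_on(self):
        t = np.arange(0.0, 60.0, 0.5)
        z = np.where(t < 5.0, 0.0, 1_100.0)
        present = t < 17.0  # vanishes 12 s after magnet-on at t = 5
        rec = detect_dissociation(_mt_track(t, z, present), magnet_on=5.0, force=9.9,
                                  absence_frames=3)
        assert rec.t_dissoc == pytest.approx(12.0)
        assert rec.gate_passed

    def test_short_extension_fails_gate(self):
        # stepwise multivalent-style trace topping out at 600 nm
        t = np.arange(0.0, 60.0, 0.5)
        z = np.where(t < 5.0, 0.0, np.where(t < 20.0, 300.0, 600.0))
        present = t < 40.0
        rec = detect_dissociation(_mt_track(t, z, present), magnet_on=5.0, force=9.9)
        assert not rec.gate_passed
        assert rec.max_extension == pytest.approx(600.0)

    def test_slow_response_fails_gate(self):
        # reaches full extension only 20 s after the force steps on
        t = np.arange(0.0, 60.0, 0.5)
        z = np.where(t < 25.0, 100.0, 1_100.0)
        z[t < 5.0] = 0.0
        rec = detect_dissociation(_mt_track(t, z, np.ones(t.size)), magnet_on=5.0,
                                  force=3.7, response_window_s=10.0)
        assert rec.max_extension >= 1_000.0
        assert not rec.gate_passed

    def test_track_ending_before_magnet_rejected(self):
        t = np.arange(0.0, 4.0, 0.5)
        with pytest.raises(DataError, match="magnet"):
            detect_dissociation(_mt_track(t, np.zeros(t.size), np.ones(t.size)),
                                magnet_on=5.0, force=3.7)


def _records(times, censored=(), force=9.9):
    recs = []
    for i, t in enumerate(times):
        recs.append(DissociationRecord(bead_id=i, force=force, t_dissoc=float(t),
                                       censored_at=None, max_extension=1_100.0,
                                       gate_passed=True))
    for j, t in enumerate(censored):
        recs.append(DissociationRecord(bead_id=1_000 + j, force=force, t_dissoc=None,
                                       censored_at=float(t), max_extension=1_100.0,
                                       gate_passed=True))
    return recs


class TestFitSurvival:
    def test_exact_exponential_grid_recovers_rate(self):
        # times whose empirical step curve lies exactly on exp(-t/tau)
        n, tau = 200, 100.0
        # S(t_i) = 1 - i/n  =>  t_i = -tau ln(1 - i/n); the n-th record is
        # censored so the step curve sits exactly on the exponential
        times = [-tau * np.log(1.0 - i / n) for i in range(1, n)]
        fit = fit_survival(_records(times, censored=(2_000.0,)))
        assert fit.k_off == pytest.approx(1.0 / tau, rel=1e-6)
        assert fit.half_life == pytest.approx(np.log(2) * tau, rel=1e-6)

    def test_monte_carlo_recovery_at_small_n(self, rng):
        tau, n_beads, n_rep = 100.0, 22, 500
        k_hat = []
        for _ in range(n_rep):
            times = rng.exponential(tau, size=n_beads)
            k_hat.append(fit_survival(_records(times)).k_off)
        median = float(np.median(k_hat))
        assert abs(median - 0.01) / 0.01 < 0.25

    def test_offset_mixture_recovered(self, rng):
        # 30% of beads never dissociate within the 1800-s record
        tau, n = 50.0, 200
        times = rng.exponential(tau, size=int(n * 0.7))
        censored = np.full(n - times.size, 1_800.0)
        fit = fit_survival(_records(times, censored), with_offset=True)
        assert fit.offset == pytest.approx(0.3, abs=0.1)

    def test_no_offset_fit_on_offset_data_biases_k_low(self, rng):
        tau, n = 50.0, 300
        times = rng.exponential(tau, size=int(n * 0.7))
        censored = np.full(n - times.size, 1_800.0)
        k_plain = fit_survival(_records(times, censored), with_offset=False).k_off
        k_off = fit_survival(_records(times, censored), with_offset=True).k_off
        assert k_plain < k_off
        assert abs(k_off - 1 / tau) < abs(k_plain - 1 / tau)

    def test_too_few_events_rejected(self):
        with pytest.raises(DataError, match="3 uncensored"):
            fit_survival(_records([10.0, 20.0]))

    def test_identical_times_rejected(self):
        with pytest.raises(DataError, match="degenerate"):
            fit_survival(_records([10.0, 10.0, 10.0]))


class TestFitBell:
    def test_noise_free_round_trip_is_exact(self):
        t0, x_b, T = 149.0, 0.58, 298.0
        kbt = KB_PN_NM_PER_K * T
        forces = [3.7, 7.1, 9.9]
        pts = [(F, t0 * np.exp(-F * x_b / kbt)) for F in forces]
        fit = fit_bell(pts, temperature=T)
        assert fit.t0 == pytest.approx(t0, rel=1e-6)
        assert fit.x_b == pytest.approx(x_b, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_flat_half_lives_give_zero_reaction_coordinate(self):
        fit = fit_bell([(3.0, 80.0), (6.0, 80.0), (9.0, 80.0)])
        assert fit.x_b == pytest.approx(0.0, abs=1e-12)
        assert fit.t0 == pytest.approx(80.0, rel=1e-12)

    def test_noisy_recovery_within_20_percent(self, rng):
        t0, x_b, T = 149.0, 0.58, 298.15
        kbt = KB_PN_NM_PER_K * T
        forces = np.array([2.0, 3.7, 5.5, 7.1, 8.5, 9.9])
        est = []
        for _ in range(200):
            tf = t0 * np.exp(-forces * x_b / kbt) * rng.lognormal(0, 0.1, forces.size)
            fit = fit_bell(list(zip(forces, tf)), temperature=T)
            est.append((fit.t0, fit.x_b))
        t0_med, xb_med = np.median(est, axis=0)
        assert abs(t0_med - t0) / t0 < 0.2
        assert abs(xb_med - x_b) / x_b < 0.2

    def test_non_positive_half_life_rejected(self):
        with pytest.raises(DataError, match="positive"):
            fit_bell([(3.0, 10.0), (6.0, -1.0)])


class TestForceFromFluctuations:
    def test_printed_example(self):
        z = np.full(200, 1_000.0)
        x = np.zeros(200)
        x[::2], x[1::2] = np.sqrt(274.3), -np.sqrt(274.3)  # variance 274.3 nm^2
        est = force_from_fluctuations(z, x, temperature=298.15)
        assert est.force == pytest.approx(15.0, abs=0.05)

    def test_linear_in_extension(self, rng):
        x = rng.normal(0, 20, 500)
        a = force_from_fluctuations(np.full(500, 800.0), x)
        b = force_from_fluctuations(np.full(500, 1_600.0), x)
        assert b.force == pytest.approx(2 * a.force, rel=1e-12)

    def test_langevin_simulation_recovers_applied_force(self, rng):
        """Overdamped bead on an extended tether: lateral stiffness F/<z>
        gives Var(x) = kBT <z> / F; the estimator must invert this."""
        F_true, L = 10.0, 1_000.0  # pN, nm
        kbt = KB_PN_NM_PER_K * 298.15
        k_lat = F_true / L  # pN/nm
        gamma = 1.7e-5  # pN s/nm (~2.8-um bead in water)
        tau = gamma / k_lat  # positional relaxation time, ~1.7 ms
        dt = tau  # sample at the relaxation time: weakly correlated frames
        n = 5_000
        # exact Ornstein-Uhlenbeck update (no discretization bias)
        rho = np.exp(-dt / tau)
        sigma_eq = np.sqrt(kbt / k_lat)
        x = np.empty(n)
        x[0] = 0.0
        noise = rng.normal(0, 1, n - 1) * sigma_eq * np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + noise[i - 1]
        est = force_from_fluctuations(np.full(n, L), x, temperature=298.15)
        assert abs(est.force - F_true) / F_true < 0.15

    def test_zero_variance_is_an_error(self):
        with pytest.raises(DataError, match="variance"):
            force_from_fluctuations(np.full(200, 1_000.0), np.zeros(200))


class TestStepSNR:
    def test_noise_free_staircase_reports_inf(self):
        trace = StepTrace(positions=np.repeat(np.arange(10.0) * 20.0, 10),
                          step_size=20.0, dwell_frames=10)
        assert step_snr(trace) == np.inf

    def test_gaussian_noise_half_step_gives_snr_two(self, rng):
        step, n_dwells, dwell = 10.0, 100, 50
        clean = np.repeat(np.arange(n_dwells) * step, dwell)
        noisy = clean + rng.normal(0, step / 2, clean.size)
        trace = StepTrace(positions=noisy, step_size=step, dwell_frames=dwell)
        assert step_snr(trace) == pytest.approx(2.0, abs=0.1)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(offset=st.floats(-1e6, 1e6))
    def test_invariant_to_constant_offset(self, offset):
        rng = np.random.default_rng(7)
        base = np.repeat(np.arange(5.0) * 8.0, 20) + rng.normal(0, 2.0, 100)
        a = step_snr(StepTrace(positions=base, step_size=8.0, dwell_frames=20))
        b = step_snr(StepTrace(positions=base + offset, step_size=8.0, dwell_frames=20))
        assert a == pytest.approx(b, rel=1e-9)

    def test_single_frame_dwell_rejected(self):
        with pytest.raises(DataError, match="dwell"):
            step_snr(StepTrace(positions=np.arange(10.0), step_size=1.0, dwell_frames=1))


def test_contour_length_arithmetic():
    assert contour_length_nm(3_400) == pytest.approx(1_156.0)
    assert contour_length_nm(48_000) == pytest.approx(16_320.0)


def test_end_to_end_dissociation_from_holograms(optics):
    """Simulated hologram frames of a tethered bead that lifts to full tether
    extension under force and then vanishes: the full pipeline (reconstruct,
    localize, link, classify) reports the dissociation within one frame."""
    from holotrack import NoiseModel, SceneSpec, ZGrid, localize_frame
    from holotrack.synthetic import forward_hologram

    px = optics.pixel_spacing
    cx = cy = 128 * px
    z0, ext = 9_000.0, 1_150.0
    fps = 2.0
    n_pre, n_on, n_gone = 4, 8, 5
    zgrid = ZGrid.from_range(7_500.0, 11_500.0, 100.0)
    frame_positions = []
    times = []
    for fi in range(n_pre + n_on + n_gone):
        times.append(fi / fps)
        if fi < n_pre:
            beads = ((cx, cy, z0),)
        elif fi < n_pre + n_on:
            beads = ((cx, cy, z0 + ext),)
        else:
            beads = ()
        holo, bg, _ = forward_hologram(
            SceneSpec(beads=beads, shape=(256, 256), seed=100 + fi), optics,
            NoiseModel(kind="poisson"),
        )
        frame_positions.append(localize_frame(holo, bg, zgrid, frame_index=fi).positions)

    tracks = link_tracks(np.array(times), frame_positions, gate_radius=2_000.0)
    assert len(tracks) == 1
    magnet_on = n_pre / fps
    rec = detect_dissociation(tracks[0], magnet_on=magnet_on, force=9.9,
                              absence_frames=3)
    assert rec.gate_passed
    t_star = (n_pre + n_on) / fps - magnet_on
    assert rec.t_dissoc == pytest.approx(t_star, abs=1.0 / fps)
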