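"""Covariance, LCMV weights, pseudo-T images, virtual electrodes."""

import numpy as np
import pytest

from opmtheta import localise as loc
from opmtheta.forward import dipole_leadfield
from opmtheta.synth import (
    NoiseSpec,
    Recording,
    SessionTruth,
    TrialSet,
    build_array,
    gen_nback_source,
    gen_sensor_noise,
    simulate_session,
)

FRONTAL = np.array([0.0, 0.055, 0.035])
TANG = np.array([1.0, 0.0, 0.0])


@pytest.fixture(scope="module")
def small_setup(head):
    arr = build_array("opm_triaxial", n_sites=16)
    L = dipole_leadfield(head, arr, FRONTAL)
    return arr, L


def _simulated_covariances(head, arr, L, seed=0, on_gain=3.0):
    """Sensor covariances for a dipole that is stronger in the on half."""
    rng = np.random.default_rng(seed)
    fs, n = 200.0, 8000
    m = 10.0 * rng.standard_normal(n)  # ~10 nA·m RMS
    gain = np.ones(n)
    gain[: n // 2] = on_gain
    sig = np.outer(L @ TANG, m * gain)
    noise = gen_sensor_noise(arr, fs, n / fs, NoiseSpec(floor_fT=5.0, knee_hz=0.0), seed=seed)
    data = sig + noise
    C = loc.regularise(loc.compute_covariance(data), 0.02)
    C_on = loc.compute_covariance(data[:, : n // 2])
    C_off = loc.compute_covariance(data[:, n // 2 :])
    return data, C, C_on, C_off


class TestCovariance:
    def test_constant_data_gives_zero_matrix(self):
        data = np.ones((4, 100)) * np.arange(4)[:, None]
        C = loc.compute_covariance(data)
        assert np.max(np.abs(C.matrix)) == 0.0

    def test_matches_two_pass_textbook_definition(self, rng):
        X = rng.standard_normal((5, 300))
        C = loc.compute_covariance(X).matrix
        ref = np.empty((5, 5))
        mu = [X[i].sum() / 300 for i in range(5)]
        for i in range(5):
            for j in range(5):
                ref[i, j] = sum((X[i] - mu[i]) * (X[j] - mu[j])) / 299
        assert np.allclose(C, ref, rtol=1e-12)

    def test_window_uses_exactly_the_window_samples(self, rng):
        data = rng.standard_normal((3, 4, 40))
        trials = TrialSet(data, ["a"] * 3, 10.0, np.arange(40) / 10.0)
        C = loc.compute_covariance(trials, (0.0, 2.0))
        X = data[:, :, :20].transpose(1, 0, 2).reshape(4, -1)
        ref = np.cov(X)
        assert np.allclose(C.matrix, ref, rtol=1e-12)
        assert C.n_samples == 60

    def test_empty_window_rejected(self, rng):
        trials = TrialSet(rng.standard_normal((3, 2, 10)), ["a"] * 3, 10.0, np.arange(10) / 10.0)
        with pytest.raises(ValueError):
            loc.compute_covariance(trials, (5.0, 6.0))


class TestRegularise:
    def test_identity_and_spectral_shift(self, rng):
        C = loc.Covariance(np.eye(4))
        assert np.allclose(loc.regularise(C).matrix, 1.02 * np.eye(4))
        A = rng.standard_normal((6, 60))
        C2 = loc.Covariance(A @ A.T / 60)
        ev = np.linalg.eigvalsh(C2.matrix)
        ev_reg = np.linalg.eigvalsh(loc.regularise(C2, 0.02).matrix)
        assert np.allclose(ev_reg, ev + 0.02 * ev[-1], rtol=1e-10)
        cond = ev[-1] / ev[0]
        cond_reg = ev_reg[-1] / ev_reg[0]
        assert cond_reg < cond


class TestLCMVWeights:
    def test_unit_gain(self, head, small_setup):
        arr, L = small_setup
        _data, C, *_ = _simulated_covariances(head, arr, L)
        w, eta = loc.lcmv_weights(C, L)
        assert w @ (L @ eta) == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(eta) == pytest.approx(1.0, abs=1e-12)

    def test_orientation_matches_brute_force_scan(self, head, small_setup, rng):
        arr, L = small_setup
        _data, C, *_ = _simulated_covariances(head, arr, L)
        w, eta = loc.lcmv_weights(C, L)
        Ci = np.linalg.inv(C.matrix)
        M = L.T @ Ci @ L
        # scan 10,000 unit orientations in the sensed (externally visible)
        # plane for the max unit-gain power 1/(uᵀMu); the radial direction is
        # silent in a spherical conductor and carries no gain constraint
        _u, _s, vt = np.linalg.svd(L, full_matrices=False)
        v1, v2 = vt[0], vt[1]
        theta = np.linspace(0.0, np.pi, 10000, endpoint=False)
        U = np.cos(theta)[:, None] * v1 + np.sin(theta)[:, None] * v2
        quad = np.einsum("ui,ij,uj->u", U, M, U)
        best = U[np.argmin(quad)]
        angle = np.degrees(np.arccos(min(1.0, abs(best @ eta))))
        assert angle < 1.0

    def test_projected_power_peaks_along_true_orientation(self, head, small_setup):
        arr, L = small_setup
        _data, C, *_ = _simulated_covariances(head, arr, L, on_gain=5.0)
        w, eta = loc.lcmv_weights(C, L)
        # power along the recovered orientation vs an orthogonal one
        M = L.T @ np.linalg.inv(C.matrix) @ L
        ortho = np.cross(eta, [0.0, 0.0, 1.0])
        ortho /= np.linalg.norm(ortho)
        assert 1.0 / (eta @ M @ eta) > 1.0 / (ortho @ M @ ortho)
        assert abs(eta @ TANG) > 0.95

    def test_weights_invariant_to_data_scaling(self, head, small_setup):
        """The unit-gain constraint pins the weights' scale, so globally
        rescaling the data leaves w unchanged and the normalised VE fixed."""
        arr, L = small_setup
        data, C, *_ = _simulated_covariances(head, arr, L)
        C4 = loc.regularise(loc.compute_covariance(2.0 * data), 0.02)
        w1, _ = loc.lcmv_weights(C, L)
        w2, _ = loc.lcmv_weights(C4, L)
        assert np.allclose(w2, w1, rtol=1e-8)
        ve1 = loc.virtual_electrode(w1, data, normalise=True)
        ve2 = loc.virtual_electrode(w2, 2.0 * data, normalise=True)
        assert np.allclose(ve1.timecourse, ve2.timecourse, rtol=1e-8)


class TestPseudoT:
    def test_equal_covariances_give_zero(self, rng):
        A = rng.standard_normal((4, 50))
        C = loc.Covariance(A @ A.T)
        w = rng.standard_normal(4)
        assert loc.pseudo_t(w, C, C) == pytest.approx(0.0, abs=1e-12)

    def test_worked_ratio(self):
        # wᵀC_on w = 3, wᵀC_off w = 1 → T = 1
        w = np.array([1.0, 0.0])
        C_on = loc.Covariance(np.diag([3.0, 1.0]))
        C_off = loc.Covariance(np.diag([1.0, 1.0]))
        assert loc.pseudo_t(w, C_on, C_off) == pytest.approx(1.0)

    def test_matches_direct_formula(self, head, small_setup, rng):
        arr, L = small_setup
        _data, C, C_on, C_off = _simulated_covariances(head, arr, L)
        w, _ = loc.lcmv_weights(C, L)
        got = loc.pseudo_t(w, C_on, C_off)
        want = (w @ C_on.matrix @ w - w @ C_off.matrix @ w) / (2 * w @ C_off.matrix @ w)
        assert got == pytest.approx(want, rel=1e-12)
        assert got > 0.5  # on-window power is genuinely higher


class TestImagesAndPeaks:
    @pytest.fixture(scope="class")
    def session_image(self, head, coarse_grid, opm_array):
        src, ev = gen_nback_source(fs=240.0, n_trials=6, on=10.0, off=10.0, seed=21)
        truth = SessionTruth(fs=240.0, sources=[(src, ev)], seed=77)
        rec, _ = simulate_session(truth, head, opm_array)
        from opmtheta import preprocess as pp

        filt = pp.bandpass(rec, pp.FilterSpec(4.0, 8.0))
        P = pp.hfc_projector(opm_array)
        filt = filt.copy_with(P @ filt.data)
        trials = pp.segment_trials(filt, 20.0)
        C = loc.regularise(loc.compute_covariance(trials), 0.02)
        W = loc.compute_weights_grid(coarse_grid, C, projector=P)
        C_on = loc.compute_covariance(trials, (2.5, 10.0))
        C_off = loc.compute_covariance(trials, (12.0, 19.5))
        img = loc.pseudo_t_image(W, C_on, C_off)
        return src, trials, W, img, C, C_on, C_off

    def test_peak_near_true_source(self, head, coarse_grid, session_image):
        src, _trials, _W, img, *_ = session_image
        pk = loc.find_peak(img, loc.region_mask(coarse_grid.voxel_centres, "frontal"))
        err = np.linalg.norm(coarse_grid.voxel_centres[pk] - src.position)
        assert err <= np.sqrt(3) * coarse_grid.spacing  # within one grid step

    def test_null_session_image_is_flat(self, head, coarse_grid, opm_array):
        """Identical on/off statistics → near-zero pseudo-T everywhere."""
        maxes = []
        for seed in range(5):
            src, ev = gen_nback_source(
                fs=240.0, n_trials=8, on=10.0, off=10.0, rel_amplitude_increase=0.0, seed=seed
            )
            truth = SessionTruth(fs=240.0, sources=[(src, ev)], seed=seed + 50)
            rec, _ = simulate_session(truth, head, opm_array)
            from opmtheta import preprocess as pp

            filt = pp.bandpass(rec, pp.FilterSpec(4.0, 8.0))
            trials = pp.segment_trials(filt, 20.0)
            C = loc.regularise(loc.compute_covariance(trials), 0.02)
            W = loc.compute_weights_grid(coarse_grid, C)
            img = loc.pseudo_t_image(
                W,
                loc.compute_covariance(trials, (0.0, 10.0)),
                loc.compute_covariance(trials, (10.0, 20.0)),
            )
            maxes.append(np.abs(img.values).max())
        assert np.quantile(maxes, 0.95) < 0.2

    def test_ve_correlates_with_true_moment(self, head, opm_array, session_image):
        src, trials, _W, _img, C, *_ = session_image
        from opmtheta import preprocess as pp
        from opmtheta.forward import dipole_leadfield

        P = pp.hfc_projector(opm_array)
        L = P @ dipole_leadfield(head, opm_array, src.position)
        w, _ = loc.lcmv_weights(C, L)
        ve = np.einsum("c,tcs->ts", w, trials.data).ravel()
        # compare against the theta-band filtered moment, aligned trialwise
        m = pp._apply_sos(src.moment, pp.FilterSpec(4.0, 8.0), 240.0)
        n_trial = trials.data.shape[2]
        m_trials = np.stack(
            [m[int(s) : int(s) + n_trial] for s in range(0, len(m), n_trial)]
        ).ravel()
        r = np.corrcoef(ve, m_trials)[0, 1]
        assert abs(r) > 0.9

    def test_empty_mask_rejected(self, session_image, coarse_grid):
        *_stuff, img, _C, _Con, _Coff = (*session_image[:4], *session_image[4:])
        img = session_image[3]
        with pytest.raises(ValueError, match="empty"):
            loc.find_peak(img, np.zeros(img.values.size, bool))

    def test_nifti_export_roundtrip(self, session_image, coarse_grid):
        img = session_image[3]
        nii = loc.image_to_nifti(img)
        vol = np.asarray(nii.dataobj)
        assert np.nanmax(vol) == pytest.approx(img.values.max())


class TestEmptyRoomProjection:
    def test_weights_reused_and_zero_input_gives_zero(self, rng):
        arr = build_array("opm_radial", n_sites=6)
        w = rng.standard_normal(arr.n_channels)
        rec = Recording(np.zeros((arr.n_channels, 100)), 100.0, [], arr)
        ve = loc.project_empty_room(w, rec)
        assert np.all(ve.timecourse == 0.0)

    def test_channel_mismatch_rejected(self, rng):
        arr = build_array("opm_radial", n_sites=6)
        rec = Recording(np.zeros((arr.n_channels, 50)), 100.0, [], arr)
        with pytest.raises(ValueError, match="channel"):
            loc.project_empty_room(rng.standard_normal(4), rec)

    def test_projected_empty_room_below_task_asd(self, head, opm_array):
        from opmtheta import preprocess as pp, spectral

        src, ev = gen_nback_source(fs=240.0, n_trials=4, on=10.0, off=10.0, seed=31)
        truth = SessionTruth(fs=240.0, sources=[(src, ev)], seed=99)
        rec, empty = simulate_session(truth, head, opm_array)
        filt = pp.bandpass(rec, pp.FilterSpec(4.0, 8.0))
        L = dipole_leadfield(head, opm_array, src.position)
        C = loc.regularise(loc.compute_covariance(filt.data), 0.02)
        w, _ = loc.lcmv_weights(C, L)
        ve_task = loc.virtual_electrode(w, filt.data)
        empty_f = pp.bandpass(empty, pp.FilterSpec(4.0, 8.0))
        ve_er = loc.project_empty_room(w, empty_f)
        s_task = spectral.welch_asd(ve_task.timecourse, 240.0, segment=10.0, overlap=5.0)
        s_er = spectral.welch_asd(ve_er.timecourse, 240.0, segment=10.0, overlap=5.0)
        assert s_er.band_mean(4, 8) < s_task.band_mean(4, 8)
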