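import numpy as np
import pytest

from nvfuse.containers import InsufficientDataError, ParameterError, ValidationError
from nvfuse.eeg import BANDS, EpochedData
from nvfuse.fnirs import HemodynamicSeries
from nvfuse import fusion as FU


def _epochs(rng, n_ep=10, n_ch=4, fs=256.0, t0=120.0):
    data = rng.standard_normal((n_ep, n_ch, int(2 * fs)))
    data -= data.mean(axis=2, keepdims=True)
    return EpochedData(
        data=data, fs=fs, epoch_len_s=2.0,
        channel_labels=[f"E{i}" for i in range(n_ch)],
        band=BANDS["lower_alpha"], kept_epoch_indices=list(range(n_ep)), t0=t0,
    )


def _hemo(rng, n_ch=14, fs=5.0, dur=200.0, t0=0.0):
    x = rng.standard_normal((n_ch, int(dur * fs)))
    return HemodynamicSeries(hbo=x, hb=-0.3 * x, fs=fs,
                             channel_labels=[f"CH{i + 1}" for i in range(n_ch)], t0=t0)


def _toy_problem(seed, n=40, noise=0.15):
    """2 EEG x 2 fNIRS planted comodulation, amenable to grid search."""
    rng = np.random.default_rng(seed)
    th, ps = np.deg2rad(40.0), np.deg2rad(-20.0)
    a_e = np.array([np.cos(th), np.sin(th)])
    a_f = np.array([np.cos(ps), np.sin(ps)])
    g = 1.0 + 0.5 * np.sin(np.arange(n) / 3.0)
    covs = np.empty((n, 2, 2))
    for e in range(n):
        z = rng.standard_normal((2, 2)) * noise
        covs[e] = g[e] * np.outer(a_e, a_e) + 0.3 * np.eye(2) + 0.1 * z @ z.T
    Y = np.outer(g + rng.standard_normal(n) * 0.1, a_f)
    Y += rng.standard_normal((n, 2)) * 0.1
    return covs, Y


def _grid_search_r(covs, Y, step_deg=0.5):
    """Exhaustive unit-circle filter-angle oracle."""
    angs = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    W = np.stack([np.cos(angs), np.sin(angs)])
    phi = np.einsum("ia,eij,ja->ea", W, covs, W)
    T = Y @ W
    phi_z = (phi - phi.mean(0)) / phi.std(0)
    T_z = (T - T.mean(0)) / T.std(0)
    return float(np.abs(phi_z.T @ T_z / covs.shape[0]).max())


class TestExtractFeatures:
    def test_ten_epochs_yield_aligned_features(self, rng):
        fs = FU.extract_features(_epochs(rng), _hemo(rng), n_epochs=10)
        assert fs.eeg_epoch_covs.shape == (10, 4, 4)
        assert fs.fnirs_samples.shape == (10, 14)
        assert fs.n_epochs == 10

    def test_white_noise_cov_near_identity(self, rng):
        fs = FU.extract_features(_epochs(rng), _hemo(rng), n_epochs=10)
        for cov in fs.eeg_epoch_covs:
            d = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
            off = np.abs(cov / d - np.eye(4))
            assert off[~np.eye(4, dtype=bool)].max() < 0.2

    def test_lag_shifts_fnirs_window(self, rng):
        """With lag k, EEG epoch e pairs with the fNIRS window k epochs later."""
        ep = _epochs(rng, n_ep=5, t0=0.0)
        ramp = np.arange(1000, dtype=float)[None, :].repeat(2, axis=0)
        h = HemodynamicSeries(hbo=ramp, hb=-ramp, fs=5.0,
                              channel_labels=["CH1", "CH2"], t0=0.0)
        f0 = FU.extract_features(ep, h, n_epochs=5, lag_epochs=0)
        f1 = FU.extract_features(ep, h, n_epochs=5, lag_epochs=1)
        np.testing.assert_allclose(f1.fnirs_samples[0], f0.fnirs_samples[1])

    def test_excluded_channels_dropped(self, rng):
        h = _hemo(rng)
        h.excluded_channels["CH3"] = "low SNR"
        fs = FU.extract_features(_epochs(rng), h, n_epochs=10)
        assert fs.fnirs_samples.shape[1] == 13
        assert "CH3" not in fs.fnirs_labels

    def test_short_fnirs_record_rejected(self, rng):
        h = _hemo(rng, dur=100.0)  # EEG epochs start at t0=120 s
        with pytest.raises(InsufficientDataError):
            FU.extract_features(_epochs(rng), h, n_epochs=10)

    def test_count_mismatch_invariant(self, rng):
        with pytest.raises(ValidationError, match="equal"):
            FU.FeatureSet(
                eeg_epoch_covs=np.stack([np.eye(2)] * 4),
                fnirs_samples=np.zeros((5, 3)),
                eeg_labels=["a", "b"], fnirs_labels=["x", "y", "z"],
                epoch_len_s=2.0,
            )


class TestActivationPattern:
    def test_identity_covariance_returns_filter_direction(self):
        w = np.array([0.6, -0.8])
        a = FU.activation_pattern(w, np.eye(2))
        np.testing.assert_allclose(np.abs(a) / np.linalg.norm(a),
                                   np.abs(w) / np.linalg.norm(w), atol=1e-12)

    def test_scale_invariance(self, rng):
        w = rng.standard_normal(4)
        x = rng.standard_normal((4, 50))
        cov = x @ x.T / 50
        a1 = FU.activation_pattern(w, cov)
        a2 = FU.activation_pattern(3.7 * w, cov)
        np.testing.assert_allclose(a1, a2, atol=1e-12)

    def test_sign_convention(self, rng):
        w = rng.standard_normal(5)
        x = rng.standard_normal((5, 60))
        a = FU.activation_pattern(w, x @ x.T / 60)
        assert a[np.argmax(np.abs(a))] > 0

    def test_degenerate_rejected(self):
        with pytest.raises(ParameterError):
            FU.activation_pattern(np.array([1.0, 0.0]), np.zeros((2, 2)))


class TestMSPoC:
    def test_noise_free_comodulation_reaches_one(self):
        """Single EEG source whose power equals the single driving fNIRS
        feature: the exact comodulation limit."""
        rng = np.random.default_rng(0)
        g = 1.0 + 0.8 * np.abs(np.sin(np.arange(30) / 2.5))
        a = np.array([1.0, 0.4, -0.2])
        covs = np.array([gg * np.outer(a, a) + 1e-6 * np.eye(3) for gg in g])
        Y = np.column_stack([g, rng.standard_normal(30) * 1e-8])
        res = FU.mspoc_fit(
            FU.FeatureSet(covs, Y, ["a", "b", "c"], ["f1", "f2"], 2.0),
            n_restarts=3, B_perm=0, seed=0, reg=1e-8,
        )[0]
        assert res.r >= 0.99

    @pytest.mark.parametrize("seed", [3, 7])
    def test_matches_grid_search_oracle(self, seed):
        covs, Y = _toy_problem(seed)
        r_grid = _grid_search_r(covs, Y)
        est = FU.MSPoC(n_restarts=10, B_perm=0, random_state=0, reg=1e-6,
                       tol=1e-10, max_iter=500)
        est.fit(covs, Y)
        assert est.r_ == pytest.approx(r_grid, abs=1e-3)

    def test_permutation_determinism_and_addone_p(self):
        covs, Y = _toy_problem(11)
        kw = dict(n_restarts=2, B_perm=60, tol=1e-8, max_iter=60)
        a = FU.MSPoC(random_state=5, **kw).fit(covs, Y)
        b = FU.MSPoC(random_state=5, **kw).fit(covs, Y)
        np.testing.assert_array_equal(a.components_[0].null_r,
                                      b.components_[0].null_r)
        assert 0 < a.p_value_ <= 1

    def test_planted_coupling_beats_null(self):
        covs, Y = _toy_problem(21)
        est = FU.MSPoC(n_restarts=3, B_perm=99, random_state=1).fit(covs, Y)
        assert est.p_value_ < 0.05

    def test_simulated_coupling_exceeds_own_null(self):
        """On full-length simulated records the planted comodulation exceeds
        the 95th percentile of its own circular-shift null in >= 90% of
        subjects."""
        import warnings as _w

        from nvfuse import eeg as E
        from nvfuse import fnirs as F
        from nvfuse.synth import SimParams, generate_subject

        band = E.BANDS["lower_alpha"]
        sig = 0
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            for seed in range(10):
                p = SimParams(n_eeg=4, n_fnirs=4, duration_s=660.0,
                              noise_mix=0.5, sync_kappa=0.0, n_sync_pairs=0)
                eeg, _, od, _ = generate_subject(p, 90_000 + seed)
                br = E.bandpass_band(eeg, band)
                sel = E.epoch_and_reject(eeg, n_keep=250)
                ep = E.epoch_select(br, sel.kept_epoch_indices, band=band)
                h5 = F.resample_hemo(F.filter_detrend(F.mbll_invert(od)), 5.0)
                fs = FU.extract_features(ep, h5, n_epochs=250, lag_epochs=3)
                res = FU.mspoc_fit(fs, n_restarts=3, B_perm=99, seed=seed,
                                   max_iter=60)[0]
                sig += res.p_value < 0.05
        assert sig >= 9

    def test_normalization_invariant(self):
        covs, Y = _toy_problem(5)
        est = FU.MSPoC(n_restarts=3, B_perm=0, random_state=0).fit(covs, Y)
        w = est.w_eeg_
        assert w @ covs.mean(axis=0) @ w == pytest.approx(1.0, abs=1e-6)

    def test_too_few_epochs_rejected(self):
        covs, Y = _toy_problem(0, n=4)
        with pytest.raises(InsufficientDataError):
            FU.MSPoC().fit(covs, Y)

    def test_sklearn_interface(self):
        from sklearn.base import clone

        est = FU.MSPoC(n_restarts=4, B_perm=10)
        params = est.get_params()
        assert params["n_restarts"] == 4
        est2 = clone(est).set_params(B_perm=0)
        assert est2.B_perm == 0


class TestFuseGroup:
    def test_identical_subjects_zero_sem(self, rng, small_montage):
        covs, Y = _toy_problem(2)
        fs = FU.FeatureSet(
            eeg_epoch_covs=np.stack([np.pad(c, ((0, 2), (0, 2))) + 1e-3 * np.eye(4)
                                     for c in covs]),
            fnirs_samples=np.column_stack([Y, Y]),
            eeg_labels=["E0", "E1", "E2", "E3"],
            fnirs_labels=["CH1", "CH2", "CH3", "CH4"],
            epoch_len_s=2.0,
        )
        out = FU.fuse_group([fs, fs, fs], "whole_pfc", small_montage,
                            seed=0, n_restarts=2, B_perm=0)
        assert out["whole_pfc"]["sem_r"] == pytest.approx(0.0, abs=1e-9)
        assert out["whole_pfc"]["n"] == 3

    def test_small_rois_skipped_with_warning(self, rng, small_montage):
        fs = FU.extract_features(
            _epochs(rng, n_ch=4), _hemo(rng, n_ch=4), n_epochs=10)
        fs = FU.FeatureSet(fs.eeg_epoch_covs, fs.fnirs_samples,
                           ["E0", "E1", "E2", "E3"],
                           ["CH1", "CH2", "CH3", "CH4"], 2.0)
        with pytest.warns(UserWarning, match="skipped"):
            out = FU.fuse_group([fs, fs], "whole_pfc", small_montage,
                                seed=0, n_restarts=2, B_perm=0)
        # each single ROI has only 1 electrode in this montage -> only the pool
        assert list(out.keys()) == ["whole_pfc"]
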