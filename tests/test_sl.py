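import numpy as np
import pytest

from nvfuse.containers import ConnectivityMatrix, ParameterError, ValidationError
from nvfuse import eeg as E
from nvfuse import sl as S
from nvfuse.synth import SimParams, generate_subject


def naive_sl_pair(x, y, p):
    """Independent O(M^2) double-loop reference implementation."""
    m, tau, w1, w2, pref = p.m, p.tau, p.w1, p.w2, p.p_ref
    M = len(x) - (m - 1) * tau
    X = np.array([[x[i + k * tau] for k in range(m)] for i in range(M)])
    Y = np.array([[y[i + k * tau] for k in range(m)] for i in range(M)])
    S_i = np.empty(M)
    for i in range(M):
        js = [j for j in range(M) if w1 < abs(i - j) <= w2]
        dx = np.array([np.sqrt(((X[i] - X[j]) ** 2).sum()) for j in js])
        dy = np.array([np.sqrt(((Y[i] - Y[j]) ** 2).sum()) for j in js])
        nv = len(js)
        q = pref * (nv - 1)
        lo = int(np.floor(q))
        hi = min(lo + 1, nv - 1)
        fr = q - lo
        sx, sy = np.sort(dx), np.sort(dy)
        ex = sx[lo] * (1 - fr) + sx[hi] * fr
        ey = sy[lo] * (1 - fr) + sy[hi] * fr
        S_i[i] = ((dx <= ex) & (dy <= ey)).sum() / (pref * nv)
    return S_i.mean()


# w2 - w1 = 55 makes the interior neighbour count (110) a multiple of 1/p_ref,
# so the quantile grid aligns and the identical-signal ceiling is unbiased
SMALL = S.SLParameters(m=3, tau=2, w1=8, w2=63, p_ref=0.1)


class TestParameterDerivation:
    def test_lower_alpha_at_256(self):
        p = S.derive_sl_params(E.BANDS["lower_alpha"], 256.0)
        assert (p.tau, p.m, p.w1, p.w2) == (9, 5, 72, 272)
        assert p.p_ref == 0.05

    def test_gamma_tau(self):
        p = S.derive_sl_params(E.BANDS["gamma"], 256.0)
        assert p.tau == 2

    def test_invalid_p_ref(self):
        with pytest.raises(ParameterError):
            S.derive_sl_params(E.BANDS["theta"], 256.0, p_ref=0.0)

    def test_invariant_violations(self):
        with pytest.raises(ParameterError):
            S.SLParameters(m=1, tau=2, w1=8, w2=60, p_ref=0.1)
        with pytest.raises(ParameterError):
            S.SLParameters(m=3, tau=2, w1=8, w2=8, p_ref=0.1)
        with pytest.raises(ParameterError):
            S.SLParameters(m=3, tau=2, w1=2, w2=60, p_ref=0.1)  # w1 < 2*tau*(m-1)

    def test_window_length_check(self):
        p = S.derive_sl_params(E.BANDS["lower_alpha"], 256.0)
        with pytest.raises(ParameterError, match="concatenate"):
            p.check_length(512)  # one 2-s epoch is too short for w2=272
        p.check_length(5120)


class TestSLPair:
    def test_identical_signals_reach_one(self, rng):
        x = rng.standard_normal(1200)
        assert S.sl_pair(x, x.copy(), SMALL) == pytest.approx(1.0, abs=0.02)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(1200)
        assert S.sl_pair(x, 2.0 * x + 5.0, SMALL) == pytest.approx(1.0, abs=0.02)

    def test_independent_noise_floor(self):
        vals = [
            S.sl_pair(np.random.default_rng(2 * s).standard_normal(1500),
                      np.random.default_rng(2 * s + 1).standard_normal(1500), SMALL)
            for s in range(8)
        ]
        assert np.mean(vals) == pytest.approx(SMALL.p_ref, abs=0.015)

    def test_exact_symmetry(self, rng):
        x = rng.standard_normal(400)
        y = rng.standard_normal(400)
        assert S.sl_pair(x, y, SMALL) == S.sl_pair(y, x, SMALL)

    def test_constant_series_rejected(self, rng):
        x = rng.standard_normal(400)
        with pytest.raises(ValidationError, match="constant"):
            S.sl_pair(x, np.full(400, 2.0), SMALL)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(200)
        y = 0.6 * x + 0.4 * rng.standard_normal(200)
        assert S.sl_pair(x, y, SMALL) == pytest.approx(naive_sl_pair(x, y, SMALL),
                                                       abs=1e-12)


class TestSLMatrix:
    def _epochs(self, data, fs=256.0):
        data = np.asarray(data)
        n_ch, n = data.shape
        return E.EpochedData(
            data=data[None, :, :] - data.mean(axis=1)[None, :, None],
            fs=fs, epoch_len_s=n / fs,
            channel_labels=[f"c{i}" for i in range(n_ch)],
            kept_epoch_indices=[0],
        )

    def test_duplicate_channel_orders_above_independent(self, rng):
        x = rng.standard_normal(1200)
        z = rng.standard_normal(1200)
        cm = S.sl_matrix(self._epochs(np.stack([x, x + 1e-9 * z, z])), SMALL)
        assert cm.values[0, 1] >= 0.95
        assert cm.values[0, 1] > cm.values[0, 2]
        assert np.allclose(np.diag(cm.values), 1.0)
        np.testing.assert_allclose(cm.values, cm.values.T, atol=1e-15)

    def test_single_epoch_modes_coincide(self, rng):
        ep = self._epochs(rng.standard_normal((3, 900)))
        a = S.sl_matrix(ep, SMALL, mode="per_epoch_mean")
        b = S.sl_matrix(ep, SMALL, mode="concatenate")
        np.testing.assert_allclose(a.values, b.values, atol=1e-15)

    def test_kappa_monotonicity(self):
        """SL between a planted pair rises monotonically with the mixing
        weight kappa in the synthetic generator."""
        from scipy.stats import spearmanr

        kappas = [0.0, 0.25, 0.5, 0.75, 0.95]
        means = []
        for k in kappas:
            vals = []
            for seed in range(4):
                p = SimParams(n_eeg=2, n_fnirs=2, duration_s=150.0, sync_kappa=k,
                              sync_pairs=[(0, 1)], noise_mix=0.3,
                              coupled_mix_scale=0.0)
                eeg, *_ = generate_subject(p, 900 + seed)
                br = E.bandpass_band(eeg, E.BANDS["lower_alpha"])
                sel = E.epoch_and_reject(br, n_keep=4)
                ep = E.epoch_select(br, sel.kept_epoch_indices)
                cm = S.sl_matrix(ep, SMALL, mode="concatenate")
                vals.append(cm.values[0, 1])
            means.append(np.mean(vals))
        rho = spearmanr(kappas, means).statistic
        assert rho > 0.9
        assert means[-1] > means[0] + 0.05

    def test_too_short_epochs_error_names_remedy(self, rng):
        p = S.derive_sl_params(E.BANDS["lower_alpha"], 256.0)
        ep = E.EpochedData(
            data=rng.standard_normal((2, 3, 512)), fs=256.0, epoch_len_s=2.0,
            channel_labels=["a", "b", "c"], kept_epoch_indices=[0, 1],
        )
        ep.data -= ep.data.mean(axis=2, keepdims=True)
        with pytest.raises(ParameterError, match="concatenate"):
            S.sl_matrix(ep, p, mode="per_epoch_mean")


class TestMeanSL:
    def _cm(self, values):
        n = values.shape[0]
        return ConnectivityMatrix(values=values, metric="sl",
                                  labels=[f"c{i}" for i in range(n)])

    def test_two_by_two(self):
        v = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert S.mean_sl(self._cm(v)) == pytest.approx(0.3)

    def test_constant_offdiagonal(self):
        v = np.full((5, 5), 0.42)
        np.fill_diagonal(v, 1.0)
        assert S.mean_sl(self._cm(v)) == pytest.approx(0.42)

    def test_matches_brute_force_on_64(self, rng):
        v = rng.uniform(0, 1, (64, 64))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        brute = sum(v[i, j] for i in range(64) for j in range(i + 1, 64)) / 2016
        assert S.mean_sl(self._cm(v)) == pytest.approx(brute, abs=1e-12)

    def test_wrong_metric_rejected(self):
        v = np.eye(2)
        cm = ConnectivityMatrix(values=v, metric="pearson_r", labels=["a", "b"])
        with pytest.raises(ParameterError):
            S.mean_sl(cm)


class TestEstimator:
    def test_sklearn_interface(self, rng):
        from sklearn.base import clone

        est = S.SynchronizationLikelihood(band="theta", p_ref=0.1)
        est2 = clone(est)
        assert est2.get_params()["p_ref"] == 0.1
        ep = E.EpochedData(
            data=rng.standard_normal((1, 2, 1200)), fs=256.0, epoch_len_s=1200 / 256,
            channel_labels=["a", "b"], kept_epoch_indices=[0],
        )
        ep.data -= ep.data.mean(axis=2, keepdims=True)
        cm = S.SynchronizationLikelihood(params=SMALL).fit(ep).transform(ep)
        assert cm.metric == "sl" and cm.n == 2
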