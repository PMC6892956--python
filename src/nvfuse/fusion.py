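"""Multimodal source power comodulation (mSPoC).

The estimator finds a spatial-filter pair (w_eeg over electrodes, w_fnirs
over optode channels) such that the per-epoch band power of the filtered EEG,
phi(e) = w_eeg' C_e w_eeg, maximally correlates with the filtered
hemodynamic feature time course t(e) = w_fnirs' y(e).  The solver alternates
three closed-form updates:

  (i)   given w_eeg, compute phi(e) and z-score it;
  (ii)  w_fnirs from ridge-regularized regression of phi on the fNIRS
        features, w_fnirs ~ (Cov_y + lambda I)^-1 Cov(y, phi);
  (iii) given the z-scored target t(e), w_eeg as the leading generalized
        eigenvector of (sum_e t(e) C_e, mean C_e).

Iteration stops when the comodulation correlation changes by less than
``tol``; the best of ``n_restarts`` initializations is kept (deterministic
principal-component seeds first, then random).  Statistical significance
comes from refitting under circular shifts of the epoch pairing — shifts
preserve the autocorrelation both feature streams share, which a full
shuffle would destroy and thereby wildly overstate significance.  The
achievable p floor is therefore ~1/n_epochs.  Activation patterns
a = C w (at unit source power) — not the filters — are the physiologically
interpretable output.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator

from .containers import (
    EpochedData,
    HemodynamicSeries,
    InsufficientDataError,
    Montage,
    ParameterError,
    ValidationError,
)


@dataclass
class FeatureSet:
    """Aligned per-epoch EEG covariances and fNIRS feature samples."""

    eeg_epoch_covs: np.ndarray          # n_epochs x C x C
    fnirs_samples: np.ndarray           # n_epochs x F
    eeg_labels: list[str]
    fnirs_labels: list[str]
    epoch_len_s: float
    lag_epochs: int = 0

    def __post_init__(self):
        self.eeg_epoch_covs = np.asarray(self.eeg_epoch_covs, dtype=float)
        self.fnirs_samples = np.asarray(self.fnirs_samples, dtype=float)
        if self.eeg_epoch_covs.shape[0] != self.fnirs_samples.shape[0]:
            raise ValidationError(
                "EEG epoch count must equal the fNIRS sample count "
                f"({self.eeg_epoch_covs.shape[0]} vs {self.fnirs_samples.shape[0]})"
            )
        C = self.eeg_epoch_covs.shape[1]
        if self.eeg_epoch_covs.shape[1:] != (C, C):
            raise ValidationError("epoch covariances must be square")
        for e, cov in enumerate(self.eeg_epoch_covs):
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValidationError(f"epoch covariance {e} is not symmetric")
        if len(self.eeg_labels) != C or len(self.fnirs_labels) != self.fnirs_samples.shape[1]:
            raise ValidationError("label counts do not match feature dimensions")

    @property
    def n_epochs(self) -> int:
        return self.eeg_epoch_covs.shape[0]

    @property
    def mean_cov(self) -> np.ndarray:
        return self.eeg_epoch_covs.mean(axis=0)

    def subset(self, eeg_labels: list[str], fnirs_labels: list[str]) -> "FeatureSet":
        ei = [self.eeg_labels.index(l) for l in eeg_labels]
        fi = [self.fnirs_labels.index(l) for l in fnirs_labels]
        return FeatureSet(
            eeg_epoch_covs=self.eeg_epoch_covs[np.ix_(range(self.n_epochs), ei, ei)],
            fnirs_samples=self.fnirs_samples[:, fi],
            eeg_labels=list(eeg_labels),
            fnirs_labels=list(fnirs_labels),
            epoch_len_s=self.epoch_len_s,
            lag_epochs=self.lag_epochs,
        )


@dataclass
class FusionResult:
    w_eeg: np.ndarray
    w_fnirs: np.ndarray
    a_eeg: np.ndarray
    a_fnirs: np.ndarray
    r: float
    null_r: np.ndarray = field(default_factory=lambda: np.array([]))
    p_value: float | None = None
    n_restarts_used: int = 0
    converged: bool = False
    component_index: int = 0


def extract_features(
    ep: EpochedData,
    h: HemodynamicSeries,
    n_epochs: int = 10,
    window_s: float = 2.0,
    lag_epochs: int = 0,
) -> FeatureSet:
    """Pair each EEG epoch covariance with a time-aligned fNIRS window mean.

    EEG epoch e (kept index k) is paired with the fNIRS window k+lag_epochs
    on the same 2-s grid, so a positive lag lets the hemodynamics trail the
    electrophysiology.  The fNIRS feature is the per-channel mean of dHbO
    over the window; excluded channels are dropped.
    """
    if abs(ep.epoch_len_s - window_s) > 1e-9:
        raise ParameterError("window_s must match the EEG epoch length")
    if ep.n_epochs < n_epochs:
        raise InsufficientDataError(
            f"need {n_epochs} EEG epochs, have {ep.n_epochs}"
        )
    keep = list(ep.kept_epoch_indices[:n_epochs])
    X = ep.data[:n_epochs]
    T = X.shape[2]
    covs = np.einsum("ect,edt->ecd", X, X) / (T - 1)

    inc = [c for c, lab in enumerate(h.channel_labels) if lab not in h.excluded_channels]
    labels_f = [h.channel_labels[c] for c in inc]
    hbo = h.hbo[inc]
    wlen = int(round(window_s * h.fs))
    if wlen < 1:
        raise ParameterError("fNIRS window shorter than one sample")
    rows = []
    for k in keep:
        start_t = ep.t0 + (k + lag_epochs) * ep.epoch_len_s - h.t0
        s = int(round(start_t * h.fs))
        if s < 0 or s + wlen > hbo.shape[1]:
            raise InsufficientDataError(
                f"fNIRS record too short for epoch index {k} at lag {lag_epochs}"
            )
        rows.append(hbo[:, s:s + wlen].mean(axis=1))
    return FeatureSet(
        eeg_epoch_covs=covs,
        fnirs_samples=np.array(rows),
        eeg_labels=list(ep.channel_labels),
        fnirs_labels=labels_f,
        epoch_len_s=ep.epoch_len_s,
        lag_epochs=lag_epochs,
    )


def activation_pattern(w: np.ndarray, covariance: np.ndarray) -> np.ndarray:
    """Pattern a = C w for the filter normalized to unit source power
    (w' C w = 1); invariant to rescaling w, sign-fixed so the largest-|.|
    entry is positive."""
    w = np.asarray(w, dtype=float)
    covariance = np.asarray(covariance, dtype=float)
    denom = float(w @ covariance @ w)
    if denom <= 0 or not np.isfinite(denom):
        raise ParameterError("degenerate normalization: w' C w must be positive")
    a = covariance @ w / np.sqrt(denom)
    if a[np.argmax(np.abs(a))] < 0:
        a = -a
    return a


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ParameterError("zero-variance feature stream")
    return (x - x.mean()) / sd


class MSPoC(BaseEstimator):
    """Scikit-learn style estimator for the mSPoC decomposition.

    ``fit(X, y)`` takes X = per-epoch EEG covariances (n_epochs, C, C) and
    y = fNIRS feature samples (n_epochs, F).  Fitted attributes carry
    trailing underscores; ``components_`` holds one FusionResult per
    extracted component.
    """

    def __init__(
        self,
        n_components: int = 1,
        n_restarts: int = 20,
        tol: float = 1e-6,
        max_iter: int = 200,
        B_perm: int = 1000,
        reg: float = 0.1,
        permute: str = "shift",
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.B_perm = B_perm
        self.reg = reg
        self.permute = permute
        self.random_state = random_state

    # -- core alternating solver -------------------------------------------
    def _smart_inits(self, covs, Y, mc, k: int = 3):
        """Deterministic initializations: target the leading principal
        components of the fNIRS features and take the corresponding
        SPoC-style generalized eigenvectors.  Seeds the alternation near the
        dominant coupled subspace, which random restarts often miss."""
        n = covs.shape[0]
        U = np.linalg.svd(Y, full_matrices=False)[0]
        inits = []
        for pc in range(min(k, U.shape[1])):
            t = _zscore(U[:, pc])
            for sign in (1.0, -1.0):
                Ct = np.einsum("e,eij->ij", sign * t, covs) / n
                _, evecs = linalg.eigh(Ct, mc)
                w = evecs[:, -1]
                w /= np.sqrt(w @ mc @ w)
                phi = np.einsum("eij,i,j->e", covs, w, w)
                r = abs(float(np.corrcoef(phi, t)[0, 1]))
                inits.append((r, pc, tuple(w)))
        inits.sort(reverse=True)
        # best sign per principal component, ordered by initial coupling
        seen, out = set(), []
        for r, pc, w in inits:
            if pc not in seen:
                seen.add(pc)
                out.append(np.array(w))
        return out

    @staticmethod
    def _best_w_for_target(covs, t_z, evecs, mc):
        """Given the z-scored target, choose the spatial filter maximizing the
        power-target correlation.

        The generalized eigenvectors of (sum_e t_e C_e, mean C) maximize
        covariance, not correlation, so each candidate is scored by the
        correlation it actually achieves; the 2-D span of the two best
        candidates (mc-orthonormal, so any combination stays normalized) is
        then searched over a rotation-angle grid.
        """
        n = covs.shape[0]
        phis = np.einsum("eij,ik,jk->ek", covs, evecs, evecs)
        sd = phis.std(axis=0)
        good = sd > 0
        cors = np.zeros(evecs.shape[1])
        pz = (phis[:, good] - phis[:, good].mean(0)) / sd[good]
        cors[good] = pz.T @ t_z / n
        order = np.argsort(np.abs(cors))[::-1]
        k1 = int(order[0])
        w = evecs[:, k1]
        if len(order) > 1:
            k2 = int(order[1])
            u1, u2 = evecs[:, k1], evecs[:, k2]
            p11 = phis[:, k1]
            p22 = phis[:, k2]
            p12 = np.einsum("eij,i,j->e", covs, u1, u2)
            th = np.linspace(0.0, np.pi, 181)[:-1]
            c, s = np.cos(th), np.sin(th)
            mix = (np.outer(p11, c**2) + np.outer(p22, s**2)
                   + 2.0 * np.outer(p12, c * s))
            msd = mix.std(axis=0)
            ok = msd > 0
            mz = (mix[:, ok] - mix[:, ok].mean(0)) / msd[ok]
            rg = np.abs(mz.T @ t_z / n)
            best = int(np.argmax(rg))
            if rg[best] > abs(cors[k1]):
                idx = np.flatnonzero(ok)[best]
                w = c[idx] * u1 + s[idx] * u2
        return w / np.sqrt(w @ mc @ w)

    def _fit_once(self, covs, Y, rng):
        n, C, _ = covs.shape
        F = Y.shape[1]
        mean_cov = covs.mean(axis=0)
        # tiny ridge keeps the generalized eigenproblem well posed
        mc = mean_cov + 1e-10 * np.trace(mean_cov) / C * np.eye(C)
        Cyy = (Y.T @ Y) / n
        Cyy_reg = Cyy + self.reg * (np.trace(Cyy) / max(F, 1)) * np.eye(F)

        best = (-np.inf, None, None, False)
        n_restarts = max(1, self.n_restarts)
        smart = self._smart_inits(covs, Y, mc)
        for restart in range(n_restarts):
            if restart < len(smart):
                w = smart[restart]
            else:
                w = rng.standard_normal(C)
                w /= np.sqrt(w @ mc @ w)
            r_prev, converged = -np.inf, False
            v = None
            for _ in range(self.max_iter):
                phi = np.einsum("eij,i,j->e", covs, w, w)
                phi_z = _zscore(phi)
                cyphi = (Y.T @ phi_z) / n
                v = np.linalg.solve(Cyy_reg, cyphi)
                t = Y @ v
                if t.std() == 0:
                    break
                if np.corrcoef(phi_z, t)[0, 1] < 0:
                    v = -v
                    t = -t
                t_z = _zscore(t)
                Ct = np.einsum("e,eij->ij", t_z, covs) / n
                _, evecs = linalg.eigh(Ct, mc)
                w = self._best_w_for_target(covs, t_z, evecs, mc)
                phi = np.einsum("eij,i,j->e", covs, w, w)
                r = float(np.corrcoef(phi, t_z)[0, 1])
                if abs(r - r_prev) < self.tol:
                    r_prev = r
                    converged = True
                    break
                r_prev = r
            if v is not None and r_prev > best[0]:
                # normalize the fNIRS filter to unit target variance
                tstd = (Y @ v).std()
                best = (r_prev, w.copy(), v / tstd if tstd > 0 else v, converged)
        return best

    def _permuted_rows(self, n, rng):
        if self.permute == "shuffle":
            return rng.permutation(n)
        if self.permute == "shift":
            # guard band: shifts shorter than the slow-envelope correlation
            # time do not break a genuine coupling and would contaminate the
            # null, so they are excluded (symmetrically at both ends)
            guard = max(1, min(n // 4, 5))
            s = rng.integers(guard, n - guard + 1)
            return np.roll(np.arange(n), s)
        raise ParameterError(f"unknown permute scheme {self.permute!r}")

    def fit(self, X, y):
        covs = np.asarray(X, dtype=float)
        Y = np.asarray(y, dtype=float)
        if covs.ndim != 3 or covs.shape[1] != covs.shape[2]:
            raise ValidationError("X must be (n_epochs, C, C) covariances")
        if Y.ndim != 2 or Y.shape[0] != covs.shape[0]:
            raise ValidationError("y must be (n_epochs, F) aligned with X")
        if covs.shape[0] < 5:
            raise InsufficientDataError("mSPoC needs at least 5 epochs")
        rng = np.random.default_rng(self.random_state)
        Yc = Y - Y.mean(axis=0)

        self.components_ = []
        covs_d, Y_d = covs, Yc
        for comp in range(self.n_components):
            r, w, v, converged = self._fit_once(covs_d, Y_d, rng)
            if w is None:
                raise ParameterError("mSPoC solver failed on all restarts")
            if not converged:
                warnings.warn("no restart converged; returning best-effort filters")
            mean_cov = covs_d.mean(axis=0)
            Cyy = (Y_d.T @ Y_d) / Y_d.shape[0]
            a_eeg = activation_pattern(w, mean_cov)
            a_fn = activation_pattern(v, Cyy) if float(v @ Cyy @ v) > 0 else Cyy @ v

            null_r = np.empty(self.B_perm)
            for b in range(self.B_perm):
                perm = self._permuted_rows(Y_d.shape[0], rng)
                rb, *_ = self._fit_once(covs_d, Y_d[perm], rng)
                null_r[b] = rb
            p = float((1 + np.sum(null_r >= r)) / (1 + self.B_perm)) if self.B_perm else None

            self.components_.append(FusionResult(
                w_eeg=w, w_fnirs=v, a_eeg=a_eeg, a_fnirs=a_fn, r=r,
                null_r=null_r, p_value=p, n_restarts_used=max(1, self.n_restarts),
                converged=converged, component_index=comp,
            ))
            if comp + 1 < self.n_components:
                covs_d, Y_d = self._deflate(covs_d, Y_d, a_eeg, a_fn)
        first = self.components_[0]
        self.w_eeg_ = first.w_eeg
        self.w_fnirs_ = first.w_fnirs
        self.r_ = first.r
        self.p_value_ = first.p_value
        return self

    @staticmethod
    def _deflate(covs, Y, a_eeg, a_fn):
        Pe = np.eye(len(a_eeg)) - np.outer(a_eeg, a_eeg) / (a_eeg @ a_eeg)
        Pf = np.eye(len(a_fn)) - np.outer(a_fn, a_fn) / (a_fn @ a_fn)
        covs2 = np.einsum("ij,ejk,lk->eil", Pe, covs, Pe)
        return covs2, Y @ Pf.T


def mspoc_fit(
    fs: FeatureSet,
    n_components: int = 1,
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 200,
    B_perm: int = 1000,
    seed: int | None = None,
    permute: str = "shift",
    reg: float = 0.1,
) -> list[FusionResult]:
    """Functional wrapper over the :class:`MSPoC` estimator."""
    est = MSPoC(
        n_components=n_components, n_restarts=n_restarts, tol=tol,
        max_iter=max_iter, B_perm=B_perm, random_state=seed, permute=permute,
        reg=reg,
    )
    est.fit(fs.eeg_epoch_covs, fs.fnirs_samples)
    return est.components_


def fuse_group(
    subject_features: list[FeatureSet],
    roi: str,
    montage: Montage,
    rois_to_report: tuple = ("L-dlPFC", "L-FP", "R-FP", "R-dlPFC", "whole_pfc"),
    seed: int | None = None,
    **fit_kwargs,
) -> dict:
    """Per-subject mSPoC fits over montage-selected ROI sensors.

    Returns ``{roi: summary}`` for each requested ROI plus the whole-PFC
    pool; the requested ``roi`` key additionally carries per-subject results.
    A ROI with fewer than 2 electrodes or 2 channels is skipped with a
    warning.  Group activation patterns are sign-aligned (dot product with
    the first subject) before averaging; s.e.m. = SD/sqrt(n).
    """
    rng = np.random.default_rng(seed)
    out = {}
    want = list(dict.fromkeys(tuple(rois_to_report) + (roi,)))
    for r_name in want:
        eeg_sel = montage.roi_labels(r_name, "eeg")
        fn_sel = montage.roi_labels(r_name, "fnirs_od")
        fn_sel = [l for l in fn_sel if all(l in f.fnirs_labels for f in subject_features)]
        if len(eeg_sel) < 2 or len(fn_sel) < 2:
            warnings.warn(f"ROI {r_name} has <2 electrodes or <2 channels; skipped")
            continue
        rs, pats_e, pats_f, results = [], [], [], []
        for f in subject_features:
            sub = f.subset(eeg_sel, fn_sel)
            res = mspoc_fit(
                sub, seed=int(rng.integers(2**31 - 1)), **fit_kwargs
            )[0]
            rs.append(res.r)
            pats_e.append(res.a_eeg)
            pats_f.append(res.a_fnirs)
            results.append(res)
        pe = np.array(pats_e)
        pf = np.array(pats_f)
        for arr in (pe, pf):
            for i in range(1, arr.shape[0]):
                if arr[i] @ arr[0] < 0:
                    arr[i] = -arr[i]
        rs = np.array(rs)
        out[r_name] = {
            "n": len(rs),
            "mean_r": float(rs.mean()),
            "sem_r": float(rs.std(ddof=1) / np.sqrt(len(rs))) if len(rs) > 1 else 0.0,
            "rs": rs,
            "a_eeg_mean": pe.mean(axis=0),
            "a_fnirs_mean": pf.mean(axis=0),
            "eeg_labels": eeg_sel,
            "fnirs_labels": fn_sel,
        }
        if r_name == roi:
            out[r_name]["subject_results"] = results
    return out
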