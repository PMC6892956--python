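"""Synchronization likelihood (SL) between electrode pairs.

SL is a nonparametric generalized-synchronization statistic.  Each signal is
delay-embedded into state vectors X_i = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau}).
For every reference time i, a channel-specific critical distance eps_i is set
to the p_ref-quantile of the distances |X_i - X_j| over the comparison window
w1 < |i - j| <= w2 (a Theiler window w1 excludes autocorrelated neighbours,
an outer window w2 bounds slow nonstationarity).  The pairwise statistic

    S_i = #{j : |X_i - X_j| <= eps_{x,i}  and  |Y_i - Y_j| <= eps_{y,i}}
          / (p_ref * n_valid(i))

counts coincident recurrences; SL is the average of S_i over i.  Independent
signals give SL ~= p_ref (the chance rate of coincidence), identical dynamics
give SL ~= 1.  The estimator is invariant under per-channel affine scaling
because the quantile-based eps rescales with the distances.

Embedding parameters are derived per frequency band with a frequency-adaptive
scheme: the lag spans about a third of the shortest period, the dimension
covers about three cycles of the slowest component, and the outer window is
sized so that roughly n_rec recurrences fall below the quantile.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ConnectivityMatrix, EpochedData, ParameterError, ValidationError
from .eeg import BandDefinition


@dataclass(frozen=True)
class SLParameters:
    m: int            # embedding dimension
    tau: int          # embedding lag (samples)
    w1: int           # Theiler window (samples)
    w2: int           # outer comparison window (samples)
    p_ref: float      # reference recurrence probability

    def __post_init__(self):
        if self.m < 2:
            raise ParameterError(f"embedding dimension m={self.m} < 2")
        if self.tau < 1:
            raise ParameterError(f"embedding lag tau={self.tau} < 1")
        if self.w1 < 2 * self.tau * (self.m - 1):
            raise ParameterError(
                f"Theiler window w1={self.w1} < 2*tau*(m-1)={2 * self.tau * (self.m - 1)}"
            )
        if self.w2 <= self.w1:
            raise ParameterError(f"w2={self.w2} must exceed w1={self.w1}")
        if not (0 < self.p_ref < 1):
            raise ParameterError(f"p_ref={self.p_ref} must lie in (0, 1)")

    def n_vectors(self, n_samples: int) -> int:
        return n_samples - (self.m - 1) * self.tau

    def check_length(self, n_samples: int) -> None:
        M = self.n_vectors(n_samples)
        need = 2 * (self.w2 + 1)
        if M < need:
            raise ParameterError(
                f"{n_samples} samples give {M} embedded vectors but the window "
                f"w2={self.w2} needs at least {need}; use longer epochs or "
                "concatenate mode"
            )


def derive_sl_params(
    band: BandDefinition,
    fs: float,
    p_ref: float = 0.05,
    n_rec: int = 10,
) -> SLParameters:
    """Frequency-adaptive embedding parameters for one band at rate fs."""
    if not (0 < p_ref < 1):
        raise ParameterError(f"p_ref={p_ref} must lie in (0, 1)")
    if band.high_hz >= fs / 2:
        raise ParameterError("band invalid at this sampling rate")
    tau = max(1, int(round(fs / (3.0 * band.high_hz))))
    m = max(2, int(round(3.0 * band.high_hz / band.low_hz)) + 1)
    w1 = 2 * tau * (m - 1)
    w2 = w1 + int(round(n_rec / p_ref))
    return SLParameters(m=m, tau=tau, w1=w1, w2=w2, p_ref=p_ref)


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    M = len(x) - (m - 1) * tau
    if M < 1:
        raise ParameterError("series too short for the requested embedding")
    idx = np.arange(M)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def _recurrence_masks(data: np.ndarray, p: SLParameters):
    """Per-channel recurrence masks.

    Returns (masks, valid) where masks[c, i, k] says whether the k-th
    window neighbour of vector i recurs within the channel's critical
    distance, and valid[i, k] marks in-range neighbours.  The critical
    distance is the linearly interpolated empirical p_ref-quantile of the
    Euclidean distances over each reference vector's valid neighbours.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    C, N = data.shape
    p.check_length(N)
    if np.any(data.std(axis=1) == 0):
        flat = [i for i in range(C) if data[i].std() == 0]
        raise ValidationError(f"constant series (zero variance) at rows {flat}")
    M = p.n_vectors(N)
    offs = np.concatenate([np.arange(-p.w2, -p.w1), np.arange(p.w1 + 1, p.w2 + 1)])
    K = len(offs)
    J = np.arange(M)[:, None] + offs[None, :]
    valid = (J >= 0) & (J < M)
    Jc = np.clip(J, 0, M - 1)
    nv = valid.sum(axis=1)
    rows = np.arange(M)
    q = p.p_ref * (nv - 1)
    lo = np.floor(q).astype(int)
    hi = np.minimum(lo + 1, nv - 1)
    frac = q - lo

    masks = np.empty((C, M, K), dtype=bool)
    D = np.empty((M, K))
    for c in range(C):
        X = _embed(data[c], p.m, p.tau)
        for s in range(0, M, 1024):  # block over i to bound memory
            e = min(s + 1024, M)
            diff = X[s:e, None, :] - X[Jc[s:e], :]
            D[s:e] = np.sqrt(np.einsum("ikm,ikm->ik", diff, diff))
        D[~valid] = np.inf
        Ds = np.sort(D, axis=1)
        eps = Ds[rows, lo] * (1.0 - frac) + Ds[rows, hi] * frac
        masks[c] = D <= eps[:, None]
    return masks, valid


def _sl_from_masks(ma: np.ndarray, mb: np.ndarray, valid: np.ndarray, p_ref: float) -> float:
    nv = valid.sum(axis=1)
    joint = (ma & mb).sum(axis=1)
    return float(np.mean(joint / (p_ref * nv)))


def sl_pair(x: np.ndarray, y: np.ndarray, p: SLParameters) -> float:
    """SL between two equal-length series.  Symmetric by construction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D series")
    masks, valid = _recurrence_masks(np.stack([x, y]), p)
    return _sl_from_masks(masks[0], masks[1], valid, p.p_ref)


def sl_matrix(ep: EpochedData, p: SLParameters, mode: str = "per_epoch_mean") -> ConnectivityMatrix:
    """Whole-head SL matrix from band-filtered epochs.

    ``per_epoch_mean`` averages the pairwise SL over epochs (each epoch must
    satisfy the window-length constraint); ``concatenate`` joins epochs into
    one series first, which is the regime for short epochs.
    """
    if mode not in ("per_epoch_mean", "concatenate"):
        raise ParameterError(f"unknown mode {mode!r}")
    C = ep.n_channels
    if mode == "concatenate" or ep.n_epochs == 1:
        series = ep.data.transpose(1, 0, 2).reshape(C, -1)
        stacks = [series]
        weights = [1.0]
    else:
        stacks = [ep.data[e] for e in range(ep.n_epochs)]
        weights = [1.0 / ep.n_epochs] * ep.n_epochs
    vals = np.zeros((C, C))
    iu = np.triu_indices(C, k=1)
    for block, wgt in zip(stacks, weights):
        try:
            masks, valid = _recurrence_masks(block, p)
        except (ParameterError, ValidationError) as err:
            raise type(err)(f"SL failed on an epoch block: {err}") from err
        nv = valid.sum(axis=1)
        for a, b in zip(*iu):
            joint = (masks[a] & masks[b]).sum(axis=1)
            vals[a, b] += wgt * float(np.mean(joint / (p.p_ref * nv)))
    vals = vals + vals.T
    np.fill_diagonal(vals, 1.0)
    return ConnectivityMatrix(values=vals, metric="sl", labels=ep.channel_labels, band=ep.band)


def mean_sl(cm: ConnectivityMatrix) -> float:
    """Global connectivity: mean of the strict upper triangle."""
    if cm.metric != "sl":
        raise ParameterError(f"mean_sl expects an SL matrix, got {cm.metric}")
    if cm.n < 2:
        raise ParameterError("need at least 2 channels")
    return float(cm.offdiag().mean())


class SynchronizationLikelihood(BaseEstimator, TransformerMixin):
    """Transformer computing per-band SL connectivity matrices.

    Parameters follow the frequency-adaptive derivation unless given
    explicitly.  ``fit`` resolves the embedding parameters for the band and
    sampling rate; ``transform`` maps EpochedData to a ConnectivityMatrix.
    """

    def __init__(self, band="lower_alpha", p_ref=0.05, n_rec=10,
                 mode="per_epoch_mean", params=None):
        self.band = band
        self.p_ref = p_ref
        self.n_rec = n_rec
        self.mode = mode
        self.params = params

    def fit(self, X: EpochedData, y=None):
        from .eeg import BANDS

        if self.params is not None:
            self.params_ = self.params
        else:
            band = BANDS[self.band] if isinstance(self.band, str) else self.band
            self.params_ = derive_sl_params(band, X.fs, p_ref=self.p_ref, n_rec=self.n_rec)
        return self

    def transform(self, X: EpochedData) -> ConnectivityMatrix:
        if not hasattr(self, "params_"):
            self.fit(X)
        return sl_matrix(X, self.params_, mode=self.mode)
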