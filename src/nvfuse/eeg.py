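"""EEG preprocessing: ocular regression, band filtering, decimation, epoching.

The stage order used by the orchestrator is fixed: ocular correction at the
native rate, band-pass filtering, decimation, then segmentation into 2-s
epochs with amplitude-based rejection.  Epoch rejection is evaluated on the
broadband signal so that every frequency band shares one set of kept epochs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import (
    EpochedData,
    InsufficientDataError,
    ParameterError,
    TimeSeriesRecording,
    ValidationError,
)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz):
            raise ParameterError(f"invalid band edges {self.low_hz}-{self.high_hz}")


#: Canonical frequency-band registry (Hz).
BANDS: dict[str, BandDefinition] = {
    b.name: b
    for b in (
        BandDefinition("delta", 1.5, 4.0),
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("lower_alpha", 8.0, 10.0),
        BandDefinition("upper_alpha", 10.0, 13.0),
        BandDefinition("beta", 14.0, 30.0),
        BandDefinition("gamma", 30.0, 50.0),
    )
}


def correct_ocular(rec: TimeSeriesRecording, eog: TimeSeriesRecording) -> TimeSeriesRecording:
    """Subtract the least-squares EOG projection from every scalp channel.

    Residuals are orthogonal to each EOG channel.  An all-zero (or otherwise
    rank-deficient) EOG set degrades gracefully through the pseudo-inverse.
    """
    if rec.fs != eog.fs:
        raise ValidationError(f"fs mismatch: scalp {rec.fs} vs EOG {eog.fs}")
    if rec.n_samples != eog.n_samples:
        raise ValidationError("scalp and EOG sample counts differ")
    if eog.n_channels < 1:
        raise ValidationError("at least one EOG channel required")
    E = eog.data - eog.data.mean(axis=1, keepdims=True)  # n_eog x T
    X = rec.data - rec.data.mean(axis=1, keepdims=True)
    # beta = (E E^T)^+ E X^T, per scalp channel; pinv handles rank deficiency
    G = E @ E.T
    if np.linalg.matrix_rank(G) < G.shape[0]:
        import warnings

        warnings.warn("rank-deficient EOG set; using the pseudo-inverse")
    beta = np.linalg.pinv(G) @ E @ X.T  # n_eog x n_scalp
    cleaned = rec.data - (beta.T @ E)
    return rec.copy_with(data=cleaned)


def bandpass_band(rec: TimeSeriesRecording, band: BandDefinition, order: int = 4) -> TimeSeriesRecording:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    nyq = rec.fs / 2.0
    if band.high_hz >= nyq:
        raise ParameterError(
            f"band edge {band.high_hz} Hz >= Nyquist {nyq} Hz at fs={rec.fs}"
        )
    sos = signal.butter(order, [band.low_hz, band.high_hz], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=out)


def resample(rec: TimeSeriesRecording, fs_new: float, allow_rational: bool = False) -> TimeSeriesRecording:
    """Anti-aliased down-sampling (integer decimation by default)."""
    if fs_new > rec.fs:
        raise ParameterError("upsampling is out of scope")
    if fs_new == rec.fs:
        return rec.copy_with()
    ratio = rec.fs / fs_new
    if abs(ratio - round(ratio)) < 1e-9:
        q = int(round(ratio))
        out = rec.data
        # scipy recommends cascaded decimation for large factors
        while q > 1:
            step = min(q, 8)
            while q % step:
                step -= 1
            out = signal.decimate(out, step, axis=1, zero_phase=True)
            q //= step
    elif allow_rational:
        from fractions import Fraction

        fr = Fraction(fs_new / rec.fs).limit_denominator(10000)
        out = signal.resample_poly(rec.data, fr.numerator, fr.denominator, axis=1)
    else:
        raise ParameterError(
            f"{rec.fs}->{fs_new} Hz is not an integer decimation; "
            "pass allow_rational=True for rational resampling"
        )
    n_out = int(np.floor(rec.n_samples * fs_new / rec.fs))
    return rec.copy_with(data=out[:, :n_out], fs=fs_new)


def segment(rec: TimeSeriesRecording, epoch_len_s: float = 2.0, discard_lead_s: float = 120.0) -> tuple[np.ndarray, float]:
    """Drop the settling-in lead and cut contiguous non-overlapping epochs.

    Returns (epochs x channels x samples, t0 of epoch 0).  Epoch k covers
    samples [k*L, (k+1)*L) of the retained signal (half-open, 0-based).
    """
    lead = int(round(discard_lead_s * rec.fs))
    if lead >= rec.n_samples:
        raise InsufficientDataError(
            f"recording shorter ({rec.duration_s:.1f} s) than discard lead "
            f"({discard_lead_s} s)"
        )
    L = int(round(epoch_len_s * rec.fs))
    tail = rec.data[:, lead:]
    n_ep = tail.shape[1] // L
    if n_ep == 0:
        raise InsufficientDataError("no complete epoch after the discard lead")
    cut = tail[:, : n_ep * L]
    epochs = cut.reshape(rec.n_channels, n_ep, L).transpose(1, 0, 2)
    return epochs, rec.t0 + lead / rec.fs


def epoch_and_reject(
    rec: TimeSeriesRecording,
    epoch_len_s: float = 2.0,
    reject_uv: float = 150.0,
    n_keep: int = 10,
    discard_lead_s: float = 120.0,
    band: BandDefinition | None = None,
) -> EpochedData:
    """Segment, reject epochs exceeding the amplitude bound, keep the first
    ``n_keep`` survivors, demean each kept epoch per channel."""
    epochs, t0 = segment(rec, epoch_len_s, discard_lead_s)
    peak = np.abs(epochs).max(axis=(1, 2))
    clean = np.flatnonzero(peak <= reject_uv)
    if len(clean) < n_keep:
        raise InsufficientDataError(
            f"only {len(clean)} artifact-free epochs available, {n_keep} requested"
        )
    keep = clean[:n_keep]
    data = epochs[keep]
    data = data - data.mean(axis=2, keepdims=True)
    return EpochedData(
        data=data,
        fs=rec.fs,
        epoch_len_s=epoch_len_s,
        channel_labels=rec.channel_labels,
        band=band,
        kept_epoch_indices=[int(k) for k in keep],
        t0=t0,
    )


def epoch_select(
    rec: TimeSeriesRecording,
    kept_epoch_indices: list[int],
    epoch_len_s: float = 2.0,
    discard_lead_s: float = 120.0,
    band: BandDefinition | None = None,
) -> EpochedData:
    """Cut a recording at pre-computed epoch indices (shared across bands).

    Used by the orchestrator so that every band-filtered copy of one subject
    carries the epochs selected on the broadband signal.
    """
    epochs, t0 = segment(rec, epoch_len_s, discard_lead_s)
    idx = np.asarray(kept_epoch_indices, dtype=int)
    if idx.size and idx.max() >= epochs.shape[0]:
        raise InsufficientDataError("kept epoch index beyond available epochs")
    data = epochs[idx]
    data = data - data.mean(axis=2, keepdims=True)
    return EpochedData(
        data=data,
        fs=rec.fs,
        epoch_len_s=epoch_len_s,
        channel_labels=rec.channel_labels,
        band=band,
        kept_epoch_indices=[int(k) for k in idx],
        t0=t0,
    )
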