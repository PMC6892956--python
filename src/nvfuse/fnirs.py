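"""fNIRS processing: Beer-Lambert inversion, slow-wave filtering, motion
correction, and SNR screening.

Concentration changes are recovered from dual-wavelength optical density via
the modified Beer-Lambert law: for wavelengths 690 and 830 nm,

    dOD(lambda) = [eps_HbO(lambda) dHbO + eps_Hb(lambda) dHb] * d * DPF(lambda)

with eps in 1/(uM*cm), source-detector distance d in cm and a dimensionless
differential pathlength factor per wavelength.  Inversion solves the 2x2
linear system per channel and time point.

The shipped extinction coefficients are a standard compiled table; the DPF
default is 6.0 at both wavelengths.  Absolute micromolar scales depend on
that convention; every downstream statistic (correlation-based) is invariant
to it.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import make_smoothing_spline

from .containers import (
    ConfigurationError,
    FormatError,
    HemodynamicSeries,
    ParameterError,
    TimeSeriesRecording,
)

#: Molar extinction coefficients, 1/(uM*cm), rows = wavelength (690, 830 nm),
#: columns = chromophore (HbO, Hb).  Standard compiled values.
DEFAULT_EXTINCTION = np.array(
    [
        [2.7640e-4, 2.0520e-3],   # 690 nm
        [9.7400e-4, 6.9300e-4],   # 830 nm
    ]
)

WAVELENGTHS = (690, 830)


@dataclass
class MBLLCoefficients:
    extinction: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())
    dpf: tuple[float, float] = (6.0, 6.0)
    distance_cm: float = 3.0

    def __post_init__(self):
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.extinction.shape != (2, 2):
            raise ConfigurationError("extinction must be a 2x2 matrix")
        if np.linalg.cond(self.extinction) >= 100:
            raise ConfigurationError("extinction matrix is ill-conditioned")
        if self.distance_cm <= 0:
            raise ConfigurationError("source-detector distance must be positive")
        if any(d <= 0 for d in self.dpf):
            raise ConfigurationError("DPF must be positive")

    def forward_matrix(self) -> np.ndarray:
        """2x2 map from (dHbO, dHb) in uM to dOD at (690, 830) nm."""
        scale = self.distance_cm * np.asarray(self.dpf)
        return self.extinction * scale[:, None]


def _split_od(od: TimeSeriesRecording):
    """Group channel-major @wavelength rows into (labels, od690, od830)."""
    labels, idx = [], {}
    for r, lab in enumerate(od.channel_labels):
        if "@" not in lab:
            raise FormatError(f"OD row {lab!r} lacks an @wavelength suffix")
        chan, wl = lab.rsplit("@", 1)
        try:
            wl = int(wl)
        except ValueError as err:
            raise FormatError(f"bad wavelength suffix in {lab!r}") from err
        if wl not in WAVELENGTHS:
            raise ConfigurationError(
                f"wavelength {wl} nm in {lab!r}; this pipeline expects {WAVELENGTHS}"
            )
        idx.setdefault(chan, {})[wl] = r
        if chan not in labels:
            labels.append(chan)
    for chan, m in idx.items():
        missing = set(WAVELENGTHS) - set(m)
        if missing:
            raise FormatError(f"channel {chan} missing wavelength(s) {sorted(missing)}")
    od690 = od.data[[idx[c][690] for c in labels]]
    od830 = od.data[[idx[c][830] for c in labels]]
    return labels, od690, od830


def mbll_invert(od: TimeSeriesRecording, coeffs: MBLLCoefficients | None = None) -> HemodynamicSeries:
    """Optical density -> concentration changes (uM) per channel and sample."""
    coeffs = coeffs or MBLLCoefficients()
    labels, od690, od830 = _split_od(od)
    A = coeffs.forward_matrix()
    Ainv = np.linalg.inv(A)
    stacked = np.stack([od690, od830])          # 2 x C x T
    conc = np.einsum("ij,jct->ict", Ainv, stacked)
    return HemodynamicSeries(
        hbo=conc[0], hb=conc[1], fs=od.fs, channel_labels=labels, t0=od.t0
    )


def forward_mbll(h: HemodynamicSeries, coeffs: MBLLCoefficients | None = None) -> TimeSeriesRecording:
    """Exact linear forward map; inverse of :func:`mbll_invert`."""
    coeffs = coeffs or MBLLCoefficients()
    A = coeffs.forward_matrix()
    conc = np.stack([h.hbo, h.hb])              # 2 x C x T
    od = np.einsum("ij,jct->ict", A, conc)      # wavelength x C x T
    rows, labels = [], []
    for c, lab in enumerate(h.channel_labels):
        for w, wl in enumerate(WAVELENGTHS):
            rows.append(od[w, c])
            labels.append(f"{lab}@{wl}")
    return TimeSeriesRecording(
        data=np.array(rows), fs=h.fs, channel_labels=labels, modality="fnirs_od", t0=h.t0
    )


def filter_detrend(
    h: HemodynamicSeries,
    low: float = 0.01,
    high: float = 0.1,
    order: int = 3,
    strict_order: bool = False,
) -> HemodynamicSeries:
    """Linear detrend then zero-phase band-pass of the slow hemodynamic band.

    With ``strict_order=True`` the band-pass runs before the detrend (the
    originally listed stage order); the default folds the detrend first,
    which is numerically safer for the 0.01 Hz high-pass edge.
    """
    if high >= h.fs / 2:
        raise ParameterError(f"high edge {high} Hz >= Nyquist at fs={h.fs}")
    eff_low = low
    min_len_s = 3.0 / low
    if h.hbo.shape[1] / h.fs < min_len_s:
        eff_low = 3.0 / (h.hbo.shape[1] / h.fs)
        warnings.warn(
            f"series shorter than 3 time-constants of the {low} Hz edge; "
            f"high-pass edge relaxed to {eff_low:.4g} Hz"
        )
    sos = signal.butter(order, [eff_low, high], btype="bandpass", fs=h.fs, output="sos")

    def run(x):
        if strict_order:
            return signal.detrend(signal.sosfiltfilt(sos, x, axis=1), axis=1)
        return signal.sosfiltfilt(sos, signal.detrend(x, axis=1), axis=1)

    return HemodynamicSeries(
        hbo=run(h.hbo), hb=run(h.hb), fs=h.fs, channel_labels=list(h.channel_labels),
        excluded_channels=dict(h.excluded_channels), t0=h.t0,
    )


def _moving_sd(x: np.ndarray, w: int) -> np.ndarray:
    """Centred moving standard deviation, edge-padded."""
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    c1 = np.convolve(xp, np.ones(w) / w, mode="valid")
    c2 = np.convolve(xp**2, np.ones(w) / w, mode="valid")
    out = np.sqrt(np.maximum(c2 - c1**2, 0.0))
    return out[: len(x)]


def _artifact_segments(flags: np.ndarray, merge_gap: int):
    """Contiguous True runs, with gaps shorter than merge_gap fused."""
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    segs = []
    start = prev = idx[0]
    for i in idx[1:]:
        gap = i - prev - 1  # samples between flagged neighbours
        if gap == 0 or gap < merge_gap:
            prev = i
            continue
        segs.append((start, prev + 1))
        start = prev = i
    segs.append((start, prev + 1))
    return segs


def spline_motion_correct(
    h: HemodynamicSeries,
    window_s: float = 2.0,
    sigma_mult: float = 3.0,
    smooth: float = 0.99,
    merge_gap_s: float = 0.5,
    max_artifact_frac: float = 0.5,
) -> HemodynamicSeries:
    """Moving-SD motion detection with smoothing-spline subtraction.

    Samples whose moving SD (window ``window_s``) exceeds ``sigma_mult`` times
    the channel's median moving SD mark artifact segments (gaps < 0.5 s
    merged).  A smoothing spline (MATLAB-style parameter ``smooth``; the
    penalty weight is (1-smooth)/smooth on the sample-index grid) is fitted to
    each segment and subtracted, and the corrected segment is re-levelled so
    its mean matches the 1-s neighbourhoods on both sides.  Channels with more
    than half their samples flagged are excluded rather than corrected.
    """
    w = int(round(window_s * h.fs))
    if w < 4:
        raise ParameterError("window too short: need fs*window_s >= 4 samples")
    merge_gap = int(round(merge_gap_s * h.fs))
    flank = int(round(1.0 * h.fs))
    lam = (1.0 - smooth) / smooth
    excluded = dict(h.excluded_channels)

    def correct(arrays):
        outs = []
        for which, X in arrays.items():
            out = X.copy()
            T = X.shape[1]
            for c, lab in enumerate(h.channel_labels):
                x = X[c]
                sd = _moving_sd(x, w)
                # quiet-baseline anchor: the lower quartile of the moving SD is
                # robust to artifacts covering even a majority of the record
                base = np.quantile(sd, 0.25)
                if base == 0:
                    outs_flags = sd > 0
                else:
                    outs_flags = sd > sigma_mult * base
                if not outs_flags.any():
                    continue
                if outs_flags.mean() > max_artifact_frac:
                    excluded.setdefault(
                        lab, f"motion: {outs_flags.mean():.0%} of samples flagged ({which})"
                    )
                    continue
                for s, e in _artifact_segments(outs_flags, merge_gap):
                    t = np.arange(s, e)
                    if e - s >= 4:
                        spl = make_smoothing_spline(t, x[s:e], lam=lam)
                        fitted = spl(t)
                    else:
                        fitted = x[s:e]
                    seg = x[s:e] - fitted
                    left = x[max(0, s - flank): s]
                    right = x[e: min(T, e + flank)]
                    neigh = np.concatenate([left, right])
                    level = neigh.mean() if neigh.size else x.mean()
                    out[c, s:e] = seg - seg.mean() + level
            outs.append(out)
        return outs

    hbo, hb = correct({"HbO": h.hbo, "Hb": h.hb})
    return HemodynamicSeries(
        hbo=hbo, hb=hb, fs=h.fs, channel_labels=list(h.channel_labels),
        excluded_channels=excluded, t0=h.t0,
    )


def resample_hemo(h: HemodynamicSeries, fs_new: float) -> HemodynamicSeries:
    """Anti-aliased integer decimation of both chromophores (e.g. 50 -> 5 Hz)."""
    if fs_new > h.fs:
        raise ParameterError("upsampling is out of scope")
    if fs_new == h.fs:
        return h
    ratio = h.fs / fs_new
    if abs(ratio - round(ratio)) > 1e-9:
        raise ParameterError(f"{h.fs}->{fs_new} Hz is not an integer decimation")
    q = int(round(ratio))
    hbo = signal.decimate(h.hbo, q, axis=1, zero_phase=True)
    hb = signal.decimate(h.hb, q, axis=1, zero_phase=True)
    return HemodynamicSeries(
        hbo=hbo, hb=hb, fs=fs_new, channel_labels=list(h.channel_labels),
        excluded_channels=dict(h.excluded_channels), t0=h.t0,
    )


def flag_low_snr(h: HemodynamicSeries, sd_mult: float = 5.0, min_run_s: float = 1.0) -> HemodynamicSeries:
    """Flag channels whose 1-s moving average stays beyond sd_mult channel SDs
    of the channel mean for at least ``min_run_s`` (either chromophore)."""
    w = max(1, int(round(1.0 * h.fs)))
    run = max(1, int(round(min_run_s * h.fs)))
    excluded = dict(h.excluded_channels)
    for which, X in (("HbO", h.hbo), ("Hb", h.hb)):
        for c, lab in enumerate(h.channel_labels):
            x = X[c]
            sd = x.std()
            if sd == 0:
                continue
            pad = w // 2
            ma = np.convolve(np.pad(x, pad, mode="edge"), np.ones(w) / w, mode="valid")[: len(x)]
            dev = np.abs(ma - x.mean()) > sd_mult * sd
            for s, e in _artifact_segments(dev, 0):
                if e - s >= run:
                    excluded.setdefault(
                        lab, f"low SNR: {which} moving average beyond {sd_mult} SD "
                        f"for {(e - s) / h.fs:.2f} s"
                    )
                    break
    return HemodynamicSeries(
        hbo=h.hbo.copy(), hb=h.hb.copy(), fs=h.fs,
        channel_labels=list(h.channel_labels), excluded_channels=excluded, t0=h.t0,
    )
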