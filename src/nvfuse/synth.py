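"""Synthetic bimodal cohorts with known ground truth.

The generator emulates the resting-state recording regime both pipelines
expect: band-limited oscillatory EEG with controllable inter-electrode
synchrony, and slow hemodynamics whose dHbO is the HRF-convolved power envelope of
a designated EEG source, emitted as dual-wavelength optical density through
the same forward Beer-Lambert operator the fNIRS pipeline inverts.

Planted structure, all recoverable downstream:
  * synchronized electrode pairs share a common source with weight kappa
    (SL rises monotonically with kappa);
  * a spatially extended "neurovascular" source whose envelope, convolved
    with a double-gamma HRF, drives dHbO with a smooth spatial pattern and
    signed gain beta (mSPoC recovers filter/pattern and comodulation);
  * a patient-like group with kappa and beta scaled down (group statistics
    recover the direction of the effect).

Source envelopes are smoothed positive random walks with a time constant of
a few seconds, so band power fluctuates on the 0.02-0.1 Hz scale where
resting alpha-power dynamics and the hemodynamic passband overlap.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .containers import ParameterError, TimeSeriesRecording
from .eeg import BANDS, BandDefinition
from .fnirs import HemodynamicSeries, MBLLCoefficients, forward_mbll


@dataclass
class GroupEffect:
    """Multiplicative patient-group factors on the planted effects."""

    kappa_factor: float = 0.6
    beta_factor: float = 0.5


@dataclass
class SimParams:
    n_eeg: int = 64
    n_eog: int = 2
    n_fnirs: int = 14
    fs_eeg: float = 256.0
    fs_fnirs: float = 50.0
    duration_s: float = 660.0
    band: str | BandDefinition = "lower_alpha"
    sync_kappa: float = 0.5
    sync_pairs: list | None = None          # None -> long-range default pairs
    n_sync_pairs: int = 8
    coupling_beta: float = 1.0
    coupled_mix_scale: float = 1.0   # 0 removes the coupled source from the EEG
    noise_mix: float = 0.5
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_ratio: float = 1.0 / 6.0
    hb_ratio: float = -0.3
    eeg_rms_uv: float = 20.0
    env_timescale_s: float = 6.0
    env_depth: float = 0.6
    hbo_rms_um: float = 0.3
    blinks: bool = False
    motion_spikes: bool = False
    group_effect: GroupEffect = field(default_factory=GroupEffect)
    seed: int | None = None

    def __post_init__(self):
        if min(self.fs_eeg, self.fs_fnirs, self.duration_s) <= 0:
            raise ParameterError("rates and duration must be positive")
        if not (0 <= self.sync_kappa <= 1):
            raise ParameterError("sync_kappa must lie in [0, 1]")
        if not (0 <= self.noise_mix <= 1):
            raise ParameterError("noise_mix must lie in [0, 1]")
        if self.duration_s < 150:
            raise ParameterError(
                "duration_s must be >= 150 s (120 s discard + 20 s analysis window)"
            )
        if self.n_eeg < 2 or self.n_fnirs < 2:
            raise ParameterError("need at least 2 EEG and 2 fNIRS channels")

    @property
    def band_def(self) -> BandDefinition:
        return BANDS[self.band] if isinstance(self.band, str) else self.band

    def resolved_sync_pairs(self) -> list[tuple[int, int]]:
        if self.sync_pairs is not None:
            return [tuple(p) for p in self.sync_pairs]
        half = self.n_eeg // 2
        return [(i, i + half) for i in range(min(self.n_sync_pairs, half))]


@dataclass
class GroundTruth:
    """Planted quantities, stored exactly for recovery metrics."""

    eeg_mixing: np.ndarray            # effective coupled-source column over electrodes
    fnirs_pattern: np.ndarray         # spatial dHbO pattern over channels
    coupled_envelope: np.ndarray      # source envelope at fs_eeg
    hbo_signal: np.ndarray            # z-scored HRF-convolved envelope at fs_fnirs
    sync_pairs: list                  # [(i, j, kappa)]
    coupling_beta: float
    channel_gains: np.ndarray
    seed: int


def hrf_kernel(p: SimParams) -> np.ndarray:
    """Double-gamma hemodynamic response, unit peak, 32 s at fs_fnirs.

    Gamma bumps with unit scale peak at shape-1, so the shapes are chosen as
    peak_s+1 and undershoot_s+1; the undershoot is subtracted with weight
    ``hrf_ratio``.
    """
    t = np.arange(0.0, 32.0, 1.0 / p.fs_fnirs)
    k1 = p.hrf_peak_s + 1.0
    k2 = p.hrf_undershoot_s + 1.0
    g1 = t ** (k1 - 1) * np.exp(-t)
    g2 = t ** (k2 - 1) * np.exp(-t)
    g1 /= g1.max()
    g2 /= g2.max()
    h = g1 - p.hrf_ratio * g2
    return h / h.max()


def _band_noise(rng, n, fs, band, order=4):
    sos = sps.butter(order, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _envelope(rng, n, fs, timescale_s, depth):
    # built on a coarse 4 Hz grid (the envelope is slow) and interpolated
    fs_env = 4.0
    n_env = max(int(np.ceil(n * fs_env / fs)) + 2, 8)
    z = gaussian_filter1d(rng.standard_normal(n_env), sigma=timescale_s * fs_env,
                          mode="reflect")
    z = (z - z.mean()) / z.std()
    t = np.arange(n) / fs
    env = np.interp(t, np.arange(n_env) / fs_env, 1.0 + depth * z)
    return np.clip(env, 0.05, None)


def _pink_noise(rng, n):
    """1/f (slope -1 in power) background, unit RMS."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    phases = rng.uniform(0, 2 * np.pi, len(freqs))
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _blink_waveform(fs):
    """Biphasic ~300 ms blink transient, unit peak."""
    t = np.arange(int(0.3 * fs)) / fs
    w = np.sin(np.pi * t / 0.3) * np.exp(-t / 0.15)
    return w / np.abs(w).max()


def default_eeg_labels(n: int) -> list[str]:
    if n == 64:
        from .io import BIOSEMI64_LABELS

        return list(BIOSEMI64_LABELS)
    return [f"E{i + 1:02d}" for i in range(n)]


def generate_subject(p: SimParams, subject_seed: int):
    """One subject's simultaneous recordings plus the planted ground truth.

    Returns ``(eeg, eog, fnirs_od, truth)`` where the EEG is in microvolts at
    fs_eeg, the EOG carries ocular signals (plus blinks when enabled), and
    the fNIRS record is channel-major dual-wavelength optical density from
    the forward Beer-Lambert operator.
    """
    rng = np.random.default_rng(subject_seed)
    band = p.band_def
    n = int(round(p.duration_s * p.fs_eeg))
    nf = int(round(p.duration_s * p.fs_fnirs))
    C = p.n_eeg

    # private per-electrode sources
    sig = np.empty((C, n))
    for c in range(C):
        sig[c] = _band_noise(rng, n, p.fs_eeg, band) * _envelope(
            rng, n, p.fs_eeg, p.env_timescale_s, p.env_depth
        )

    # channels joined by sync pairs form components sharing one common source,
    # so overlapping pairs (stars, chains) synchronize consistently
    pairs = []
    comp: dict[int, int] = {}
    for (a, b) in p.resolved_sync_pairs():
        if not (0 <= a < C and 0 <= b < C and a != b):
            raise ParameterError(f"invalid sync pair ({a}, {b}) for {C} electrodes")
        ra, rb = comp.get(a), comp.get(b)
        if ra is None and rb is None:
            cid = len(set(comp.values()))
            comp[a] = comp[b] = cid
        elif ra is None:
            comp[a] = rb
        elif rb is None:
            comp[b] = ra
        elif ra != rb:
            for ch, cid in comp.items():
                if cid == rb:
                    comp[ch] = ra
        pairs.append((a, b, p.sync_kappa))
    k = p.sync_kappa
    for cid in set(comp.values()):
        shared = _band_noise(rng, n, p.fs_eeg, band) * _envelope(
            rng, n, p.fs_eeg, p.env_timescale_s, p.env_depth
        )
        for ch, c_ in comp.items():
            if c_ == cid:
                sig[ch] = (1 - k) * sig[ch] + k * shared

    # spatially extended neurovascular source
    env_c = _envelope(rng, n, p.fs_eeg, p.env_timescale_s, p.env_depth)
    s_c = _band_noise(rng, n, p.fs_eeg, band) * env_c
    centre = C // 4
    width = max(C / 6.0, 1.5)
    mix = p.coupled_mix_scale * np.exp(-0.5 * ((np.arange(C) - centre) / width) ** 2)
    sig = sig + np.outer(mix, s_c)

    noise = np.empty((C, n))
    for c in range(C):
        noise[c] = 0.9 * _pink_noise(rng, n) + 0.45 * rng.standard_normal(n)

    x = (1 - p.noise_mix) * sig + p.noise_mix * noise
    if p.blinks:
        w = _blink_waveform(p.fs_eeg)
        n_blinks = rng.poisson(p.duration_s / 5.0)
        starts = rng.integers(0, n - len(w), size=n_blinks)
        frontal = np.exp(-np.arange(C) / 6.0)  # decays away from the front rows
        for s in starts:
            x[:, s:s + len(w)] += 100.0 * np.outer(frontal, w)
    gains = p.eeg_rms_uv / x.std(axis=1)
    x = x * gains[:, None]
    eeg = TimeSeriesRecording(
        data=x, fs=p.fs_eeg, channel_labels=default_eeg_labels(C), modality="eeg"
    )

    # EOG: slow ocular drift plus blinks
    eog_data = np.empty((p.n_eog, n))
    for c in range(p.n_eog):
        drift = gaussian_filter1d(rng.standard_normal(n), sigma=0.2 * p.fs_eeg, mode="reflect")
        eog_data[c] = 20.0 * drift / drift.std()
    if p.blinks:
        w = _blink_waveform(p.fs_eeg)
        for s in starts:
            eog_data[:, s:s + len(w)] += 400.0 * w
    eog = TimeSeriesRecording(
        data=eog_data, fs=p.fs_eeg,
        channel_labels=[f"{'HV'[c % 2]}EOG" for c in range(p.n_eog)],
        modality="eog",
    )

    # hemodynamics: HRF-convolved envelope of the coupled source
    t_f = np.arange(nf) / p.fs_fnirs
    t_e = np.arange(n) / p.fs_eeg
    pow_f = np.interp(t_f, t_e, env_c**2)  # neural activity ~ power envelope
    hrf = hrf_kernel(p)
    drive = sps.fftconvolve(pow_f - pow_f.mean(), hrf)[:nf]
    drive = (drive - drive.mean()) / drive.std()

    pattern = 0.2 + 0.8 * np.exp(
        -0.5 * ((np.arange(p.n_fnirs) - p.n_fnirs / 3.0) / (p.n_fnirs / 4.0)) ** 2
    )
    pink_f = np.array([_pink_noise(rng, nf) for _ in range(p.n_fnirs)])
    hbo = p.hbo_rms_um * (
        (1 - p.noise_mix) * p.coupling_beta * np.outer(pattern, drive)
        + p.noise_mix * pink_f
    )
    hb = p.hb_ratio * hbo + 0.05 * p.hbo_rms_um * np.array(
        [_pink_noise(rng, nf) for _ in range(p.n_fnirs)]
    )
    hemo = HemodynamicSeries(
        hbo=hbo, hb=hb, fs=p.fs_fnirs,
        channel_labels=[f"CH{i + 1}" for i in range(p.n_fnirs)],
    )
    od = forward_mbll(hemo, MBLLCoefficients())
    if p.motion_spikes:
        n_spk = rng.poisson(3)
        od_data = od.data.copy()
        for _ in range(n_spk):
            ch = rng.integers(0, od_data.shape[0])
            s = rng.integers(0, od_data.shape[1] - int(p.fs_fnirs))
            dur = rng.integers(int(0.2 * p.fs_fnirs), int(p.fs_fnirs))
            od_data[ch, s:s + dur] += 10.0 * od_data[ch].std() * np.hanning(dur)
        od = od.copy_with(data=od_data)

    truth = GroundTruth(
        eeg_mixing=(1 - p.noise_mix) * mix * gains,
        fnirs_pattern=pattern,
        coupled_envelope=env_c,
        hbo_signal=drive,
        sync_pairs=pairs,
        coupling_beta=p.coupling_beta,
        channel_gains=gains,
        seed=subject_seed,
    )
    return eeg, eog, od, truth


def apply_group_effect(p: SimParams) -> SimParams:
    """Patient-like parameter set: kappa and beta scaled by the group effect."""
    import dataclasses

    return dataclasses.replace(
        p,
        sync_kappa=p.sync_kappa * p.group_effect.kappa_factor,
        coupling_beta=p.coupling_beta * p.group_effect.beta_factor,
    )


def generate_cohort(p: SimParams, nA: int = 11, nB: int = 8, seed: int | None = None):
    """Two-group cohort: group A at nominal parameters, group B patient-like.

    Returns a list of ``(group_label, eeg, eog, od, truth)`` tuples; per
    subject seeds derive deterministically from the cohort seed.
    """
    if nA < 2 or nB < 2:
        raise ParameterError("need at least 2 subjects per group")
    ss = np.random.SeedSequence(seed if seed is not None else p.seed)
    children = ss.spawn(nA + nB)
    pB = apply_group_effect(p)
    out = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        params = p if i < nA else pB
        label = "A" if i < nA else "B"
        eeg, eog, od, truth = generate_subject(params, sub_seed)
        out.append((label, eeg, eog, od, truth))
    return out
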