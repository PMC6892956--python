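"""Core in-memory containers shared by both recording modalities.

Units are fixed package-wide: EEG in microvolts, hemoglobin concentration
changes in micromolar, coordinates in millimetres (MNI space), time in
seconds.  Unit mismatches are treated as errors, never silently converted.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PFC_ROIS = ("L-dlPFC", "L-FP", "R-FP", "R-dlPFC")
ROI_TOKENS = PFC_ROIS + ("other",)
MODALITIES = ("eeg", "eog", "fnirs_od")


class NVFuseError(Exception):
    """Base class for all package errors."""


class FormatError(NVFuseError):
    """Malformed or unsupported on-disk input."""


class ValidationError(NVFuseError):
    """A container invariant is violated."""


class ParameterError(NVFuseError):
    """Invalid analysis parameters."""


class ConfigurationError(NVFuseError):
    """Invalid run or instrument configuration."""


class InsufficientDataError(NVFuseError):
    """Not enough clean data to satisfy the requested analysis."""


@dataclass
class TimeSeriesRecording:
    """Multichannel uniformly sampled signal (one modality).

    ``data`` is channels x samples; ``t0`` is the time offset in seconds of
    the first retained sample relative to the start of the recording.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    modality: str
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 1:
            raise ValidationError("data must be a channels x samples matrix")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("channel labels must be unique")
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data=None, fs=None, labels=None, t0=None) -> "TimeSeriesRecording":
        return TimeSeriesRecording(
            data=self.data.copy() if data is None else data,
            fs=self.fs if fs is None else fs,
            channel_labels=self.channel_labels if labels is None else labels,
            modality=self.modality,
            t0=self.t0 if t0 is None else t0,
        )


@dataclass
class MontageEntry:
    label: str
    modality: str
    x: float
    y: float
    z: float
    roi: str


@dataclass
class Montage:
    """Sensor layout: labels, modalities, MNI coordinates (mm) and PFC ROI tags."""

    entries: list[MontageEntry]

    def __post_init__(self):
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate montage labels: {dup}")
        for e in self.entries:
            if e.modality not in MODALITIES:
                raise ValidationError(f"unknown modality {e.modality!r} for {e.label}")
            if e.roi not in ROI_TOKENS:
                raise ValidationError(f"unknown roi token {e.roi!r} for {e.label}")
            if e.modality == "fnirs_od" and e.roi == "other":
                raise ValidationError(f"fNIRS channel {e.label} carries no PFC ROI")
        for roi in PFC_ROIS:
            if not any(e.roi == roi and e.modality == "fnirs_od" for e in self.entries):
                raise ValidationError(f"ROI {roi} has no fNIRS channel")
            if not any(e.roi == roi and e.modality == "eeg" for e in self.entries):
                raise ValidationError(f"ROI {roi} has no EEG electrode")

    def labels(self, modality: str | None = None) -> list[str]:
        return [e.label for e in self.entries if modality is None or e.modality == modality]

    def roi_labels(self, roi: str, modality: str) -> list[str]:
        """Labels in one PFC ROI, or in all four ROIs for roi='whole_pfc'."""
        if roi == "whole_pfc":
            want = set(PFC_ROIS)
        elif roi in ROI_TOKENS:
            want = {roi}
        else:
            raise ParameterError(f"unknown ROI {roi!r}")
        return [e.label for e in self.entries if e.modality == modality and e.roi in want]

    def coords(self, labels: list[str]) -> np.ndarray:
        by_label = {e.label: (e.x, e.y, e.z) for e in self.entries}
        return np.array([by_label[l] for l in labels])


@dataclass
class EpochedData:
    """Epochs x channels x samples, after segmentation/rejection/demeaning."""

    data: np.ndarray
    fs: float
    epoch_len_s: float
    channel_labels: list[str]
    band: object = None  # BandDefinition or None for broadband
    kept_epoch_indices: list[int] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("epoched data must be epochs x channels x samples")
        expect = int(round(self.fs * self.epoch_len_s))
        if self.data.shape[2] != expect:
            raise ValidationError(
                f"epoch has {self.data.shape[2]} samples, expected {expect}"
            )
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValidationError("label count does not match channel dimension")
        if len(self.kept_epoch_indices) != self.data.shape[0]:
            raise ValidationError("kept_epoch_indices length does not match epochs")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class HemodynamicSeries:
    """Per-channel hemoglobin concentration changes (micromolar)."""

    hbo: np.ndarray
    hb: np.ndarray
    fs: float
    channel_labels: list[str]
    excluded_channels: dict[str, str] = field(default_factory=dict)
    t0: float = 0.0

    def __post_init__(self):
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hb = np.asarray(self.hb, dtype=float)
        if self.hbo.shape != self.hb.shape or self.hbo.ndim != 2:
            raise ValidationError("hbo and hb must share a channels x samples shape")
        if len(self.channel_labels) != self.hbo.shape[0]:
            raise ValidationError("label count does not match rows")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hb))):
            raise ValidationError("non-finite concentration values")
        unknown = set(self.excluded_channels) - set(self.channel_labels)
        if unknown:
            raise ValidationError(f"excluded channels not in labels: {sorted(unknown)}")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    def included_labels(self) -> list[str]:
        return [l for l in self.channel_labels if l not in self.excluded_channels]

    def chromophore(self, which: str = "hbo") -> np.ndarray:
        if which not in ("hbo", "hb"):
            raise ParameterError(f"chromophore must be 'hbo' or 'hb', got {which!r}")
        return self.hbo if which == "hbo" else self.hb


@dataclass
class ConnectivityMatrix:
    """Symmetric pairwise connectivity (SL, Pearson r, or Fisher z)."""

    values: np.ndarray
    metric: str
    labels: list[str]
    band: object = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} for {n} labels")
        if self.metric not in ("sl", "pearson_r", "fisher_z"):
            raise ValidationError(f"unknown metric {self.metric!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("matrix is not symmetric")
        if self.metric in ("sl", "pearson_r"):
            if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
                raise ValidationError(f"{self.metric} diagonal must be 1")
        if self.metric == "sl" and np.any(self.values < -1e-12):
            raise ValidationError("SL entries must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def offdiag(self) -> np.ndarray:
        """Strict upper-triangle values, row-major."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class NetworkGraph:
    """Thresholded connectivity graph with per-node degree strengths."""

    labels: list[str]
    edges: list[tuple[int, int, float]]
    threshold_value: float
    threshold_rule: str
    degree_strength: np.ndarray

    def __post_init__(self):
        n = len(self.labels)
        self.degree_strength = np.asarray(self.degree_strength, dtype=float)
        if self.degree_strength.shape != (n,):
            raise ValidationError("degree_strength length must equal label count")
        for i, j, w in self.edges:
            if i == j:
                raise ValidationError("self-loops are not allowed")
            if not (0 <= i < j < n):
                raise ValidationError("edges must satisfy 0 <= i < j < n")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.labels)
        for i, j, w in self.edges:
            g.add_edge(self.labels[i], self.labels[j], weight=w)
        return g


@dataclass
class ResultBundle:
    """Everything one pipeline run produces, plus provenance."""

    matrices: dict = field(default_factory=dict)     # name -> ConnectivityMatrix
    graphs: dict = field(default_factory=dict)       # name -> NetworkGraph
    scalars: dict = field(default_factory=dict)      # name -> float
    tables: dict = field(default_factory=dict)       # name -> pandas.DataFrame
    provenance: dict = field(default_factory=dict)
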