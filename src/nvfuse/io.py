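"""Readers and writers for every external artifact the pipeline touches.

EEG interchange is EDF/EDF+ (read through MNE; written by a minimal
single-rate EDF writer, since EDF is a fixed-layout ASCII-header + int16
format).  fNIRS optical density travels as a wide delimited table with
``<chan>@<wavelength>`` columns; montages and matrices as labelled TSV.
Readers never reorder channels relative to the source file.
"""
from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ConnectivityMatrix,
    FormatError,
    Montage,
    MontageEntry,
    NetworkGraph,
    ResultBundle,
    TimeSeriesRecording,
    ValidationError,
)

#: Biosemi 64-electrode cap in 10-10 nomenclature, vendor channel order.
BIOSEMI64_LABELS = (
    "Fp1 AF7 AF3 F1 F3 F5 F7 FT7 FC5 FC3 FC1 C1 C3 C5 T7 TP7 CP5 CP3 CP1 "
    "P1 P3 P5 P7 P9 PO7 PO3 O1 Iz Oz POz Pz CPz Fpz Fp2 AF8 AF4 AFz Fz F2 "
    "F4 F6 F8 FT8 FC6 FC4 FC2 FCz Cz C2 C4 C6 T8 TP8 CP6 CP4 CP2 P2 P4 P6 "
    "P8 P10 PO8 PO4 O2"
).split()

DEFAULT_EOG_PATTERN = r"^(H|V)EOG$"

_FS_PLAUSIBLE = (1.0, 10_000.0)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def write_edf(rec_or_list, path) -> None:
    """Write recordings (shared fs) as a plain EDF file, one record per second.

    Physical units are microvolts; values are quantized to the 16-bit digital
    range of each channel's span, the resolution the format defines.
    """
    recs = rec_or_list if isinstance(rec_or_list, (list, tuple)) else [rec_or_list]
    fs = recs[0].fs
    if any(r.fs != fs for r in recs):
        raise ValidationError("all recordings in one EDF must share fs")
    if fs != int(fs):
        raise ValidationError("EDF writer requires an integer sampling rate")
    data = np.vstack([r.data for r in recs])
    labels = [l for r in recs for l in r.channel_labels]
    n_ch, n_samp = data.shape
    spr = int(fs)
    n_rec = n_samp // spr
    if n_rec * spr != n_samp:
        data = data[:, : n_rec * spr]
    if n_rec == 0:
        raise ValidationError("recording shorter than one EDF data record (1 s)")

    pmax = np.maximum(np.abs(data).max(axis=1), 1.0) * 1.02
    pmin = -pmax
    dmax, dmin = 32767, -32768

    def f8(v):
        return f"{v:.6g}".encode().ljust(8)[:8]

    with open(path, "wb") as f:
        hdr = b"0".ljust(8)
        hdr += b"X X X X".ljust(80)
        hdr += b"Startdate 01-JAN-2000 X X X".ljust(80)
        hdr += b"01.01.00" + b"00.00.00"
        hdr += str(256 * (n_ch + 1)).encode().ljust(8)
        hdr += b"".ljust(44)
        hdr += str(n_rec).encode().ljust(8)
        hdr += b"1".ljust(8)
        hdr += str(n_ch).encode().ljust(4)
        f.write(hdr)
        f.write(b"".join(l.encode().ljust(16)[:16] for l in labels))
        f.write(b"".join(b"AgAgCl".ljust(80) for _ in labels))
        f.write(b"".join(b"uV".ljust(8) for _ in labels))
        f.write(b"".join(f8(v) for v in pmin))
        f.write(b"".join(f8(v) for v in pmax))
        f.write(b"".join(str(dmin).encode().ljust(8) for _ in labels))
        f.write(b"".join(str(dmax).encode().ljust(8) for _ in labels))
        f.write(b"".join(b"".ljust(80) for _ in labels))
        f.write(b"".join(str(spr).encode().ljust(8) for _ in labels))
        f.write(b"".join(b"".ljust(32) for _ in labels))
        gain = (pmax - pmin) / (dmax - dmin)
        dig = np.round((data - pmin[:, None]) / gain[:, None]).astype(np.int64) + dmin
        dig = np.clip(dig, dmin, dmax).astype("<i2")
        for r in range(n_rec):
            f.write(dig[:, r * spr:(r + 1) * spr].tobytes())


def _check_edf_header(path) -> None:
    """Light structural validation before handing the file to the reader."""
    with open(path, "rb") as f:
        hdr = f.read(256)
        if len(hdr) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            n_ch = int(hdr[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as err:
            raise FormatError(f"{path}: malformed EDF header") from err
        if n_ch <= 0:
            raise FormatError(f"{path}: EDF header declares {n_ch} channels")
        sig_hdr = f.read(256 * n_ch)
        if len(sig_hdr) < 256 * n_ch:
            raise FormatError(f"{path}: truncated EDF signal header")
        off = n_ch * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
        spr_field = sig_hdr[off: off + 8 * n_ch]
        try:
            spr = [int(spr_field[i * 8:(i + 1) * 8].decode().strip()) for i in range(n_ch)]
        except (UnicodeDecodeError, ValueError) as err:
            raise FormatError(f"{path}: malformed samples-per-record field") from err
        if len(set(spr)) > 1:
            raise FormatError(
                f"{path}: mixed per-channel sampling rates {sorted(set(spr))} "
                "are an unsupported layout"
            )


def read_eeg_edf(path, eog_pattern: str = DEFAULT_EOG_PATTERN):
    """Read an EDF recording, splitting EOG channels off by label pattern.

    Returns ``(eeg, eog)`` where ``eog`` is None when no label matches.
    Scalp channels must share one sampling rate; units are enforced as
    microvolts through the header scaling.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    _check_edf_header(path)
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except FormatError:
        raise
    except Exception as err:  # mne raises assorted types on malformed headers
        raise FormatError(f"cannot parse EDF {path}: {err}") from err
    data_uv = raw.get_data() * 1e6  # mne loads Volts
    pat = re.compile(eog_pattern)
    is_eog = np.array([bool(pat.search(ch)) for ch in raw.ch_names])
    eeg = TimeSeriesRecording(
        data=data_uv[~is_eog],
        fs=float(raw.info["sfreq"]),
        channel_labels=[c for c, e in zip(raw.ch_names, is_eog) if not e],
        modality="eeg",
    )
    eog = None
    if is_eog.any():
        eog = TimeSeriesRecording(
            data=data_uv[is_eog],
            fs=float(raw.info["sfreq"]),
            channel_labels=[c for c, e in zip(raw.ch_names, is_eog) if e],
            modality="eog",
        )
    return eeg, eog


# ---------------------------------------------------------------------------
# fNIRS optical density tables
# ---------------------------------------------------------------------------

def write_fnirs_table(rec: TimeSeriesRecording, path, sep: str = "\t") -> None:
    t = rec.t0 + np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time": t})
    for lab, row in zip(rec.channel_labels, rec.data):
        df[lab] = row
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_fnirs_table(path, sep: str | None = None) -> TimeSeriesRecording:
    """Read a wide delimited OD table with a time column and
    ``<chan>@<wavelength>`` columns, channel-major row ordering."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=sep if sep is not None else None, engine="python")
    if "time" not in df.columns:
        raise FormatError("fNIRS table needs a 'time' column")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError("fNIRS table needs at least two samples")
    steps = np.diff(t)
    if np.ptp(steps) > 1e-6:
        raise FormatError("non-uniform time step in fNIRS table")
    fs = 1.0 / steps.mean()
    if not (_FS_PLAUSIBLE[0] <= fs <= _FS_PLAUSIBLE[1]):
        raise FormatError(
            f"inferred rate {fs:.4g} Hz outside plausible bounds "
            f"{_FS_PLAUSIBLE}; is the time column in seconds?"
        )
    cols = [c for c in df.columns if c != "time"]
    chans: dict[str, dict[int, str]] = {}
    for c in cols:
        if "@" not in c:
            raise FormatError(f"column {c!r} lacks the @wavelength suffix")
        chan, wl = c.rsplit("@", 1)
        chans.setdefault(chan, {})[int(wl)] = c
    ordered_cols, labels = [], []
    for chan in dict.fromkeys(c.rsplit("@", 1)[0] for c in cols):
        have = chans[chan]
        for wl in (690, 830):
            if wl not in have:
                raise FormatError(f"channel {chan} missing its @{wl} partner column")
            ordered_cols.append(have[wl])
            labels.append(f"{chan}@{wl}")
    data = df[ordered_cols].to_numpy(dtype=float).T
    return TimeSeriesRecording(
        data=data, fs=float(np.round(fs, 9)), channel_labels=labels,
        modality="fnirs_od", t0=float(t[0]),
    )


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

def read_montage(path) -> Montage:
    df = pd.read_csv(path, sep="\t")
    need = {"label", "modality", "x", "y", "z", "roi"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"montage missing columns {sorted(missing)}")
    entries = [
        MontageEntry(
            label=str(r.label), modality=str(r.modality),
            x=float(r.x), y=float(r.y), z=float(r.z), roi=str(r.roi),
        )
        for r in df.itertuples()
    ]
    return Montage(entries=entries)


def write_montage(m: Montage, path) -> None:
    pd.DataFrame(
        [
            {"label": e.label, "modality": e.modality, "x": e.x, "y": e.y,
             "z": e.z, "roi": e.roi}
            for e in m.entries
        ]
    ).to_csv(path, sep="\t", index=False)


def default_montage() -> Montage:
    """The montage shipped with the package: 64 EEG + 2 EOG + 14 fNIRS."""
    from importlib.resources import files

    with (files("nvfuse") / "data" / "default_montage.tsv").open("rb") as fh:
        df = pd.read_csv(fh, sep="\t")
    entries = [
        MontageEntry(str(r.label), str(r.modality), float(r.x), float(r.y),
                     float(r.z), str(r.roi))
        for r in df.itertuples()
    ]
    return Montage(entries=entries)


# ---------------------------------------------------------------------------
# Result bundles
# ---------------------------------------------------------------------------

def write_matrix_tsv(cm: ConnectivityMatrix, path) -> None:
    pd.DataFrame(cm.values, index=cm.labels, columns=cm.labels).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_matrix_tsv(path, metric: str) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(
        values=df.to_numpy(dtype=float), metric=metric, labels=[str(c) for c in df.columns]
    )


def write_graph_tsv(g: NetworkGraph, path) -> None:
    rows = [
        {"node_a": g.labels[i], "node_b": g.labels[j], "weight": w}
        for i, j, w in g.edges
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def write_results(bundle: ResultBundle, directory, overwrite: bool = False) -> dict:
    """Serialize a ResultBundle: matrices and graphs as TSV, scalars and
    provenance as a structured-text summary.  Returns the path manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} already exists; pass overwrite=True to replace the run"
        )
    manifest = {"matrices": {}, "graphs": {}, "tables": {}, "summary": None}
    for name, cm in bundle.matrices.items():
        p = directory / f"matrix_{name}.tsv"
        write_matrix_tsv(cm, p)
        manifest["matrices"][name] = str(p)
    for name, g in bundle.graphs.items():
        p = directory / f"graph_{name}.tsv"
        write_graph_tsv(g, p)
        manifest["graphs"][name] = str(p)
    for name, df in bundle.tables.items():
        p = directory / f"table_{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.17g")
        manifest["tables"][name] = str(p)
    summary = directory / "summary.txt"
    with open(summary, "w") as f:
        f.write("# nvfuse run summary\n\n[provenance]\n")
        for k, v in bundle.provenance.items():
            f.write(f"{k} = {v}\n")
        f.write("\n[scalars]\n")
        for k, v in bundle.scalars.items():
            f.write(f"{k} = {v!r}\n")
    manifest["summary"] = str(summary)
    with open(manifest_path, "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
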