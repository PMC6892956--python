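"""End-to-end orchestration of the bimodal resting-state analysis.

The run mirrors the two-arm workflow: the EEG arm (ocular correction, band
filtering, decimation, epoch selection, SL connectivity, group permutation
statistics with cluster correction) and the fNIRS arm (Beer-Lambert
inversion, slow-band filtering, motion/SNR screening, Pearson/Fisher-z
connectivity, thresholded graphs and degree strength), followed by feature
selection and mSPoC fusion of the selected band with dHbO.

Feature selection for the fusion stage reads only the group-statistics
outputs, never fusion results, so no information leaks backwards through
the DAG.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import eeg as eegmod
from . import fnirs as fnirsmod
from . import fusion as fusionmod
from . import io as iomod
from . import sl as slmod
from . import stats as statsmod
from .containers import (
    ConfigurationError,
    ConnectivityMatrix,
    Montage,
    ParameterError,
    ResultBundle,
    TimeSeriesRecording,
)

log = logging.getLogger(__name__)

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_DEFAULTS = {
    "seed": 0,
    "out_dir": None,
    "montage": None,                  # path; None -> shipped default
    "subjects": None,                 # list of {id, group, eeg, fnirs} paths
    "simulate": None,                 # dict of SimParams overrides + nA/nB
    "eeg": {
        "fs_analysis": 256.0,
        "epoch_len_s": 2.0,
        "reject_uv": 150.0,
        "n_keep": 10,
        "discard_lead_s": 120.0,
        "bands": ["delta", "theta", "lower_alpha", "upper_alpha", "beta", "gamma"],
        "eog_pattern": iomod.DEFAULT_EOG_PATTERN,
    },
    "sl": {"p_ref": 0.05, "n_rec": 10, "mode": "auto"},
    "fnirs": {
        "low_hz": 0.01, "high_hz": 0.1, "dpf": [6.0, 6.0], "distance_cm": 3.0,
        "motion_window_s": 2.0, "motion_sigma_mult": 3.0, "motion_smooth": 0.99,
        "snr_sd_mult": 5.0, "snr_min_run_s": 1.0, "fs_feature": 5.0,
    },
    "stats": {"B": 1000, "forming_alpha": 0.05},
    "connectivity": {"fraction": 0.05, "chromophore": "hbo"},
    "fusion": {
        "n_epochs": 10, "lag_epochs": 0, "n_restarts": 20, "B_perm": 1000,
        "tol": 1e-6, "max_iter": 200, "roi": "whole_pfc", "band": None,
    },
    "report": {"sl_display_threshold": 0.8},
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for k, v in defaults.items():
        if isinstance(v, dict) and k in user and user[k] is not None:
            out[k] = _merge(v, user[k], f"{path}{k}.")
        elif k in user:
            out[k] = user[k]
        else:
            out[k] = json.loads(json.dumps(v)) if isinstance(v, (dict, list)) else v
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(f'{path}{k}' for k in unknown)}")
    return out


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self):
        self.raw = _merge(_DEFAULTS, self.raw or {})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as f:
            return cls(raw=yaml.safe_load(f) or {})

    def __getitem__(self, key):
        return self.raw[key]

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Per-subject processing
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    subject_id: str
    group: str
    eeg: TimeSeriesRecording
    eog: TimeSeriesRecording | None
    od: TimeSeriesRecording


@dataclass
class SubjectDerived:
    subject_id: str
    group: str
    sl_matrices: dict            # band -> ConnectivityMatrix
    mean_sl: dict                # band -> float
    band_epochs: dict            # band -> EpochedData
    hemo: object                 # cleaned HemodynamicSeries
    pearson: ConnectivityMatrix
    fisher: ConnectivityMatrix


def process_subject(sub: SubjectData, cfg: RunConfig) -> SubjectDerived:
    e = cfg["eeg"]
    rec = sub.eeg
    if sub.eog is not None:
        rec = eegmod.correct_ocular(rec, sub.eog)
    bands = {name: eegmod.BANDS[name] for name in e["bands"]}
    band_recs = {
        name: eegmod.resample(eegmod.bandpass_band(rec, b), e["fs_analysis"])
        for name, b in bands.items()
    }
    broadband = eegmod.resample(rec, e["fs_analysis"])
    selected = eegmod.epoch_and_reject(
        broadband, epoch_len_s=e["epoch_len_s"], reject_uv=e["reject_uv"],
        n_keep=e["n_keep"], discard_lead_s=e["discard_lead_s"],
    )
    band_epochs = {
        name: eegmod.epoch_select(
            br, selected.kept_epoch_indices, epoch_len_s=e["epoch_len_s"],
            discard_lead_s=e["discard_lead_s"], band=bands[name],
        )
        for name, br in band_recs.items()
    }

    s = cfg["sl"]
    sl_matrices, mean_sl = {}, {}
    for name, ep in band_epochs.items():
        params = slmod.derive_sl_params(
            bands[name], ep.fs, p_ref=s["p_ref"], n_rec=s["n_rec"]
        )
        mode = s["mode"]
        if mode == "auto":
            try:
                params.check_length(ep.data.shape[2])
                mode = "per_epoch_mean"
            except ParameterError:
                mode = "concatenate"
        cm = slmod.sl_matrix(ep, params, mode=mode)
        sl_matrices[name] = cm
        mean_sl[name] = slmod.mean_sl(cm)

    f = cfg["fnirs"]
    coeffs = fnirsmod.MBLLCoefficients(dpf=tuple(f["dpf"]), distance_cm=f["distance_cm"])
    hemo = fnirsmod.mbll_invert(sub.od, coeffs)
    hemo = fnirsmod.filter_detrend(hemo, low=f["low_hz"], high=f["high_hz"])
    hemo = fnirsmod.spline_motion_correct(
        hemo, window_s=f["motion_window_s"], sigma_mult=f["motion_sigma_mult"],
        smooth=f["motion_smooth"],
    )
    hemo = fnirsmod.flag_low_snr(hemo, sd_mult=f["snr_sd_mult"], min_run_s=f["snr_min_run_s"])
    pear = conn.pearson_matrix(hemo, chromophore=cfg["connectivity"]["chromophore"])
    fish = conn.fisher_z(pear)
    return SubjectDerived(
        subject_id=sub.subject_id, group=sub.group, sl_matrices=sl_matrices,
        mean_sl=mean_sl, band_epochs=band_epochs, hemo=hemo,
        pearson=pear, fisher=fish,
    )


# ---------------------------------------------------------------------------
# Group level
# ---------------------------------------------------------------------------

def _common_label_subset(mats: list[ConnectivityMatrix]) -> list[ConnectivityMatrix]:
    common = set(mats[0].labels)
    for m in mats[1:]:
        common &= set(m.labels)
    order = [l for l in mats[0].labels if l in common]
    out = []
    for m in mats:
        idx = [m.labels.index(l) for l in order]
        out.append(ConnectivityMatrix(
            values=m.values[np.ix_(idx, idx)], metric=m.metric, labels=order, band=m.band
        ))
    return out


def feature_select(band_stats: dict, default_band: str = "lower_alpha"):
    """Choose the band for fusion: the one whose CBPT yields the most
    significant cluster (ties: lower cluster_p, then lower band edge).

    ``band_stats`` maps band name -> dict with key 'cbpt' (ClusterResult).
    Returns (band, chromophore, reason); falls back to the configured
    default when no band shows a significant cluster.
    """
    candidates = []
    for name, st in band_stats.items():
        cr = st["cbpt"]
        if cr.cluster_p:
            candidates.append((min(cr.cluster_p), eegmod.BANDS[name].low_hz, name))
    candidates.sort()
    if candidates and candidates[0][0] < 0.05:
        best = candidates[0]
        return best[2], "hbo", f"CBPT cluster_p={best[0]:.4g}"
    log.warning("no band with a significant cluster; falling back to %s", default_band)
    return default_band, "hbo", "fallback: no significant band"


def analyze_cohort(
    subjects: list[SubjectData],
    cfg: RunConfig,
    montage: Montage | None = None,
    covariates: np.ndarray | None = None,
) -> ResultBundle:
    """The full two-arm group analysis on an in-memory cohort."""
    t_start = time.time()
    montage = montage or iomod.default_montage()
    seed = int(cfg["seed"])
    B = int(cfg["stats"]["B"])
    rng = np.random.default_rng(seed)

    derived = []
    for sub in subjects:
        t0 = time.time()
        try:
            derived.append(process_subject(sub, cfg))
        except Exception as err:
            raise type(err)(
                f"subject {sub.subject_id}: per-subject processing failed: {err}"
            ) from err
        log.info("subject %s processed in %.1f s", sub.subject_id, time.time() - t0)

    groups = sorted({d.group for d in derived})
    if len(groups) != 2:
        raise ConfigurationError(f"expected exactly 2 groups, got {groups}")
    gA, gB = groups
    byg = {g: [d for d in derived if d.group == g] for g in groups}

    bundle = ResultBundle()
    bundle.provenance = {
        "config_hash": cfg.hash(), "seed": seed, "software": f"nvfuse {__version__}",
        "n_subjects": {g: len(byg[g]) for g in groups},
    }

    # ---- EEG arm: per-band group statistics --------------------------------
    band_stats = {}
    for name in cfg["eeg"]["bands"]:
        msA = np.array([d.mean_sl[name] for d in byg[gA]])
        msB = np.array([d.mean_sl[name] for d in byg[gB]])
        if covariates is not None:
            resid = statsmod.residualize_covariates(
                np.concatenate([msA, msB]), covariates
            )
            msA, msB = resid[: len(msA)], resid[len(msA):]
        perm = statsmod.permutation_mean_diff(
            msA, msB, B=B, seed=int(rng.integers(2**31 - 1))
        )
        matsA = [d.sl_matrices[name] for d in byg[gA]]
        matsB = [d.sl_matrices[name] for d in byg[gB]]
        cres = statsmod.cbpt(
            matsA, matsB, forming_alpha=cfg["stats"]["forming_alpha"],
            B=B, seed=int(rng.integers(2**31 - 1)),
        )
        band_stats[name] = {"perm": perm, "cbpt": cres,
                            "mean_sl": {gA: float(np.mean(msA)), gB: float(np.mean(msB))}}
        meanA = np.mean([m.values for m in matsA], axis=0)
        meanB = np.mean([m.values for m in matsB], axis=0)
        np.fill_diagonal(meanA, 1.0); np.fill_diagonal(meanB, 1.0)
        labels = matsA[0].labels
        bundle.matrices[f"sl_{name}_mean_{gA}"] = ConnectivityMatrix(
            values=(meanA + meanA.T) / 2, metric="sl", labels=labels)
        bundle.matrices[f"sl_{name}_mean_{gB}"] = ConnectivityMatrix(
            values=(meanB + meanB.T) / 2, metric="sl", labels=labels)
        bundle.scalars[f"mean_sl_{name}_{gA}"] = float(
            np.mean([d.mean_sl[name] for d in byg[gA]]))
        bundle.scalars[f"mean_sl_{name}_{gB}"] = float(
            np.mean([d.mean_sl[name] for d in byg[gB]]))
        bundle.scalars[f"mean_sl_perm_p_{name}"] = perm.p_value
        bundle.scalars[f"cbpt_min_cluster_p_{name}"] = (
            min(cres.cluster_p) if cres.cluster_p else None)
    # pooled low-band summary alongside the per-band results
    low = [b for b in ("delta", "theta", "lower_alpha") if b in band_stats]
    if low:
        pooledA = np.array([np.mean([d.mean_sl[b] for b in low]) for d in byg[gA]])
        pooledB = np.array([np.mean([d.mean_sl[b] for b in low]) for d in byg[gB]])
        pperm = statsmod.permutation_mean_diff(
            pooledA, pooledB, B=B, seed=int(rng.integers(2**31 - 1)))
        bundle.scalars["mean_sl_perm_p_low_bands_pooled"] = pperm.p_value

    # ---- fNIRS arm ---------------------------------------------------------
    fishers = _common_label_subset([d.fisher for d in derived])
    pearsons = _common_label_subset([d.pearson for d in derived])
    fA = [m for m, d in zip(fishers, derived) if d.group == gA]
    fB = [m for m, d in zip(fishers, derived) if d.group == gB]
    pA = [m for m, d in zip(pearsons, derived) if d.group == gA]
    pB = [m for m, d in zip(pearsons, derived) if d.group == gB]
    labels = fishers[0].labels

    def group_mean_r(fs_z):
        z = np.mean([m.values for m in fs_z], axis=0)
        r = np.tanh(z)
        np.fill_diagonal(r, 1.0)
        return ConnectivityMatrix(values=(r + r.T) / 2, metric="pearson_r", labels=labels)

    meanA_r = group_mean_r(fA)
    meanB_r = group_mean_r(fB)
    bundle.matrices[f"hbo_pearson_mean_{gA}"] = meanA_r
    bundle.matrices[f"hbo_pearson_mean_{gB}"] = meanB_r

    frac = cfg["connectivity"]["fraction"]
    graphA = conn.threshold_top_fraction(meanA_r, frac)          # reference group
    graphB = conn.threshold_top_fraction(meanB_r, frac, reference=meanA_r)
    bundle.graphs[f"hbo_network_{gA}"] = graphA
    bundle.graphs[f"hbo_network_{gB}"] = graphB
    bundle.scalars["hbo_r_threshold"] = graphA.threshold_value
    bundle.scalars[f"hbo_n_edges_{gA}"] = len(graphA.edges)
    bundle.scalars[f"hbo_n_edges_{gB}"] = len(graphB.edges)

    sigA = np.array([conn.degree_strength(m) for m in pA])
    sigB = np.array([conn.degree_strength(m) for m in pB])
    bundle.tables["degree_strength"] = pd.DataFrame({
        "channel": labels,
        f"sigma_{gA}": sigA.mean(axis=0),
        f"sem_{gA}": sigA.std(axis=0, ddof=1) / np.sqrt(len(sigA)),
        f"sigma_{gB}": sigB.mean(axis=0),
        f"sem_{gB}": sigB.std(axis=0, ddof=1) / np.sqrt(len(sigB)),
    })
    dperm = statsmod.permutation_mean_diff(
        sigA.mean(axis=1), sigB.mean(axis=1), B=B, seed=int(rng.integers(2**31 - 1)))
    bundle.scalars[f"degree_strength_mean_{gA}"] = float(sigA.mean())
    bundle.scalars[f"degree_strength_mean_{gB}"] = float(sigB.mean())
    bundle.scalars["degree_strength_perm_p"] = dperm.p_value
    et, ep_ = statsmod.edgewise_t(fA, fB)
    bundle.scalars["hbo_edges_p_lt_05_fraction"] = float(
        np.mean(ep_[np.triu_indices(len(labels), k=1)] < 0.05))

    # ---- Fusion ------------------------------------------------------------
    fu = cfg["fusion"]
    band_for_fusion = fu["band"]
    if band_for_fusion is None:
        band_for_fusion, chromo, reason = feature_select(band_stats)
    else:
        chromo, reason = "hbo", "manual override"
    bundle.scalars["fusion_band"] = band_for_fusion
    bundle.scalars["fusion_band_reason"] = reason

    feats = {g: [] for g in groups}
    for d in derived:
        hemo5 = fnirsmod.resample_hemo(d.hemo, cfg["fnirs"]["fs_feature"])
        fs = fusionmod.extract_features(
            d.band_epochs[band_for_fusion], hemo5,
            n_epochs=fu["n_epochs"], window_s=cfg["eeg"]["epoch_len_s"],
            lag_epochs=fu["lag_epochs"],
        )
        feats[d.group].append(fs)

    fusion_rows = []
    for g in groups:
        summary = fusionmod.fuse_group(
            feats[g], fu["roi"], montage,
            seed=int(rng.integers(2**31 - 1)),
            n_restarts=fu["n_restarts"], B_perm=fu["B_perm"],
            tol=fu["tol"], max_iter=fu["max_iter"],
        )
        for roi_name, s in summary.items():
            fusion_rows.append({
                "group": g, "roi": roi_name, "n": s["n"],
                "mean_r": s["mean_r"], "sem_r": s["sem_r"],
            })
        whole = summary.get(fu["roi"])
        if whole is not None:
            bundle.scalars[f"mspoc_r_mean_{g}"] = whole["mean_r"]
            bundle.scalars[f"mspoc_r_sem_{g}"] = whole["sem_r"]
            bundle.tables[f"mspoc_pattern_eeg_{g}"] = pd.DataFrame({
                "label": whole["eeg_labels"], "a_eeg": whole["a_eeg_mean"]})
            bundle.tables[f"mspoc_pattern_fnirs_{g}"] = pd.DataFrame({
                "label": whole["fnirs_labels"], "a_fnirs": whole["a_fnirs_mean"]})
    bundle.tables["mspoc_by_roi"] = pd.DataFrame(fusion_rows)
    bundle.provenance["runtime_s"] = round(time.time() - t_start, 2)
    return bundle


# ---------------------------------------------------------------------------
# Entry points
# ---------------------------------------------------------------------------

def load_subjects_from_config(cfg: RunConfig) -> tuple[list[SubjectData], Montage]:
    montage = (
        iomod.read_montage(cfg["montage"]) if cfg["montage"] else iomod.default_montage()
    )
    if cfg["simulate"] is not None:
        from . import synth

        sim = dict(cfg["simulate"])
        nA = int(sim.pop("nA", 11))
        nB = int(sim.pop("nB", 8))
        preset = sim.pop("preset", None)
        if preset == "test-small":
            sim.setdefault("duration_s", 180.0)
            sim.setdefault("n_eeg", 16)
        params = synth.SimParams(**sim)
        cohort = synth.generate_cohort(params, nA=nA, nB=nB, seed=int(cfg["seed"]))
        subjects = [
            SubjectData(subject_id=f"S{i:02d}", group=g, eeg=eeg, eog=eog, od=od)
            for i, (g, eeg, eog, od, _) in enumerate(cohort)
        ]
        if params.n_eeg != 64:
            montage = _synthetic_montage(subjects[0])
        return subjects, montage
    if not cfg["subjects"]:
        raise ConfigurationError("config needs either 'subjects' or 'simulate'")
    subjects = []
    for row in cfg["subjects"]:
        eeg, eog = iomod.read_eeg_edf(row["eeg"], eog_pattern=cfg["eeg"]["eog_pattern"])
        od = iomod.read_fnirs_table(row["fnirs"])
        subjects.append(SubjectData(
            subject_id=str(row["id"]), group=str(row["group"]), eeg=eeg, eog=eog, od=od,
        ))
    return subjects, montage


def _synthetic_montage(sub: SubjectData) -> Montage:
    """A montage covering a reduced synthetic electrode set: electrodes are
    spread over the four PFC ROIs in round-robin order."""
    from .containers import MontageEntry, PFC_ROIS

    entries = []
    for i, lab in enumerate(sub.eeg.channel_labels):
        roi = PFC_ROIS[i % 4]
        entries.append(MontageEntry(lab, "eeg", float(i), 60.0, 20.0, roi))
    if sub.eog is not None:
        for j, lab in enumerate(sub.eog.channel_labels):
            entries.append(MontageEntry(lab, "eog", -50.0 + j, 60.0, -20.0, "other"))
    n_f = len({l.rsplit("@", 1)[0] for l in sub.od.channel_labels})
    for i in range(n_f):
        roi = PFC_ROIS[i % 4]
        entries.append(MontageEntry(f"CH{i + 1}", "fnirs_od", float(i), 60.0, 15.0, roi))
    return Montage(entries=entries)


def run_pipeline(cfg: RunConfig) -> ResultBundle:
    """Load (or simulate) the cohort, analyze it, optionally write results."""
    subjects, montage = load_subjects_from_config(cfg)
    bundle = analyze_cohort(subjects, cfg, montage=montage)
    if cfg["out_dir"]:
        iomod.write_results(bundle, cfg["out_dir"], overwrite=True)
    return bundle


def render_report(bundle: ResultBundle, montage: Montage, out_dir) -> list[str]:
    """Best-effort figures: matrix heat maps, degree-strength bars with
    s.e.m. error bars, and 2-D sensor-layout connectivity above the display
    threshold (a visualization choice only; it enters no statistics)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, cm in bundle.matrices.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(cm.values, vmin=0 if cm.metric == "sl" else -1, vmax=1,
                       cmap="viridis")
        ax.set_title(name)
        fig.colorbar(im, ax=ax)
        p = out_dir / f"{name}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(str(p))
    if "degree_strength" in bundle.tables:
        df = bundle.tables["degree_strength"]
        sig_cols = [c for c in df.columns if c.startswith("sigma_")]
        fig, ax = plt.subplots(figsize=(7, 3.5))
        xs = np.arange(len(df))
        wdt = 0.38
        for k, sc in enumerate(sig_cols):
            g = sc.split("_", 1)[1]
            ax.bar(xs + (k - 0.5) * wdt, df[sc], wdt, yerr=df[f"sem_{g}"],
                   capsize=2, label=g)
        ax.set_xticks(xs, df["channel"], rotation=90)
        ax.set_ylabel("degree strength")
        ax.legend()
        fig.tight_layout()
        p = out_dir / "degree_strength.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(str(p))
    # sensor-layout edges above the display threshold
    thr = 0.8
    for name, cm in bundle.matrices.items():
        if cm.metric != "sl":
            continue
        labs = [l for l in cm.labels]
        try:
            xy = montage.coords(labs)[:, :2]
        except KeyError:
            continue
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.scatter(xy[:, 0], xy[:, 1], s=12, c="k", zorder=3)
        n = len(labs)
        for i in range(n):
            for j in range(i + 1, n):
                if cm.values[i, j] > thr:
                    ax.plot(xy[[i, j], 0], xy[[i, j], 1], c="g", lw=0.8, alpha=0.7)
        ax.set_title(f"{name} (edges > {thr})")
        ax.set_aspect("equal")
        p = out_dir / f"{name}_layout.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(str(p))
    return written
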