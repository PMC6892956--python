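"""Hemodynamic connectivity: Pearson matrices, Fisher z, top-fraction
thresholding and degree strength."""
from __future__ import annotations

import logging
import warnings

import numpy as np

from .containers import (
    ConnectivityMatrix,
    HemodynamicSeries,
    NetworkGraph,
    ParameterError,
)

log = logging.getLogger(__name__)


def pearson_matrix(h: HemodynamicSeries, chromophore: str = "hbo") -> ConnectivityMatrix:
    """Pearson correlation between the time courses of all retained channels.

    Channels already excluded (motion/SNR screening) are dropped; a
    zero-variance channel is auto-excluded with a logged reason.
    """
    X = h.chromophore(chromophore)
    keep, labels = [], []
    for c, lab in enumerate(h.channel_labels):
        if lab in h.excluded_channels:
            continue
        if X[c].std() == 0:
            log.warning("channel %s has zero variance; excluded from %s connectivity",
                        lab, chromophore)
            continue
        keep.append(c)
        labels.append(lab)
    if len(keep) < 2:
        raise ParameterError("need at least 2 non-excluded channels")
    if X.shape[1] < 3:
        raise ParameterError("need at least 3 time samples")
    r = np.corrcoef(X[keep])
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return ConnectivityMatrix(values=r, metric="pearson_r", labels=labels)


def fisher_z(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Variance-stabilizing z = atanh(r), off-diagonal; diagonal set to 0.

    The diagonal of a correlation matrix is 1 by convention and carries no
    information; it is stored as 0 here and excluded from statistics.
    """
    if cm.metric != "pearson_r":
        raise ParameterError(f"fisher_z expects pearson_r, got {cm.metric}")
    r = cm.values.copy()
    clip = 1.0 - 1e-7
    off = ~np.eye(cm.n, dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        warnings.warn("off-diagonal |r| >= 1 clipped before atanh")
        r[off] = np.clip(r[off], -clip, clip)
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    return ConnectivityMatrix(values=z, metric="fisher_z", labels=list(cm.labels), band=cm.band)


def degree_strength(cm: ConnectivityMatrix) -> np.ndarray:
    """sigma_i = mean of row i excluding the diagonal (full, unthresholded)."""
    if cm.n < 2:
        raise ParameterError("need at least 2 nodes")
    v = cm.values.copy()
    np.fill_diagonal(v, 0.0)
    return v.sum(axis=1) / (cm.n - 1)


def threshold_top_fraction(
    cm: ConnectivityMatrix,
    fraction: float = 0.05,
    reference: ConnectivityMatrix | None = None,
) -> NetworkGraph:
    """Keep the foremost ``fraction`` of connections.

    The cut value r_T is the k-th largest off-diagonal entry of the
    *reference* matrix (e.g. the control-group mean) with
    k = ceil(fraction * n(n-1)/2); edges of ``cm`` with weight >= r_T are
    retained.  Ties at r_T are all kept.  When a reference is given, the
    thresholded graph of a weaker-connectivity matrix may hold fewer than k
    edges.
    """
    if not (0 < fraction <= 1):
        raise ParameterError(f"fraction must lie in (0, 1], got {fraction}")
    ref = reference if reference is not None else cm
    if ref.labels != cm.labels:
        raise ParameterError("reference labels differ from matrix labels")
    n = cm.n
    n_pairs = n * (n - 1) // 2
    k = int(np.ceil(fraction * n_pairs))
    if k == 0:
        raise ParameterError("fraction yields an empty edge budget")
    ref_off = np.sort(ref.offdiag())[::-1]
    r_t = float(ref_off[k - 1])
    iu = np.triu_indices(n, k=1)
    w = cm.values[iu]
    sel = w >= r_t
    edges = [(int(i), int(j), float(v)) for i, j, v in
             zip(iu[0][sel], iu[1][sel], w[sel])]
    if len(edges) > k and reference is None:
        log.info("ties at r_T=%.4g: %d edges retained for budget %d", r_t, len(edges), k)
    return NetworkGraph(
        labels=list(cm.labels),
        edges=edges,
        threshold_value=r_t,
        threshold_rule=f"top {fraction:.0%} of reference off-diagonals (k={k})",
        degree_strength=degree_strength(cm),
    )
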