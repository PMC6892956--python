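"""Permutation inference for group comparisons.

All group tests are label-permutation tests with an add-one p estimator
p = (1 + #{null >= observed}) / (1 + B), which can never return zero.  The
edge-level statistic is the Welch (unequal-variance) two-sample t, chosen for
the unequal group sizes this design targets.  Cluster-based correction over
sensor-pair networks uses cluster mass (sum of |t|) with edges adjacent iff
they share an electrode endpoint.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats as sps

from .containers import ParameterError, ValidationError


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    B: int
    seed: int | None
    tails: str

    def __post_init__(self):
        self.null_stats = np.asarray(self.null_stats, dtype=float)
        if len(self.null_stats) != self.B:
            raise ValidationError("null_stats length must equal B")
        if not (0 < self.p_value <= 1):
            raise ValidationError("p_value must lie in (0, 1]")


@dataclass
class ClusterResult:
    clusters: list = field(default_factory=list)       # list of edge-(i,j) lists
    cluster_mass: list = field(default_factory=list)
    cluster_p: list = field(default_factory=list)
    edge_t: np.ndarray | None = None
    edge_p: np.ndarray | None = None
    adjacency_rule: str = "edges adjacent iff they share an electrode endpoint"

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def significant_edges(self, alpha: float = 0.05) -> set:
        out = set()
        for edges, p in zip(self.clusters, self.cluster_p):
            if p < alpha:
                out.update(edges)
        return out


def _perm_p(observed: float, null: np.ndarray, tails: str) -> float:
    if tails == "two":
        hits = np.sum(np.abs(null) >= abs(observed))
    elif tails == "greater":
        hits = np.sum(null >= observed)
    elif tails == "less":
        hits = np.sum(null <= observed)
    else:
        raise ParameterError(f"unknown tails {tails!r}")
    return float((1 + hits) / (1 + len(null)))


def residualize_covariates(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Remove the least-squares projection of per-subject values onto
    [intercept, covariates].  Accepts (n,) or (n, d) values."""
    values = np.asarray(values, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != values.shape[0]:
        cov = cov.T
    n = values.shape[0]
    if cov.shape[0] != n:
        raise ParameterError("covariate rows must match the number of subjects")
    if n <= cov.shape[1] + 1:
        raise ParameterError("need n_subjects > n_covariates + 1")
    X = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("collinear covariates; using the pseudo-inverse")
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def _welch_t(A: np.ndarray, B: np.ndarray):
    """Vectorized Welch t and two-tailed parametric p along axis 0."""
    nA, nB = A.shape[0], B.shape[0]
    mA, mB = A.mean(axis=0), B.mean(axis=0)
    vA = A.var(axis=0, ddof=1)
    vB = B.var(axis=0, ddof=1)
    se2 = vA / nA + vB / nB
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mA - mB) / np.sqrt(se2)
        df = se2**2 / (vA**2 / (nA**2 * (nA - 1)) + vB**2 / (nB**2 * (nB - 1)))
        p = 2.0 * special.stdtr(df, -np.abs(t))
    return t, p, df


def permutation_mean_diff(
    groupA: np.ndarray,
    groupB: np.ndarray,
    B: int = 1000,
    seed: int | None = None,
    tails: str = "two",
) -> PermutationResult:
    """Group-difference permutation test on a per-subject scalar.

    The observed statistic is the Welch t; the null is built by reshuffling
    group labels while preserving group sizes.
    """
    a = np.asarray(groupA, dtype=float)
    b = np.asarray(groupB, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if pooled.var() == 0:
        raise ParameterError("zero pooled variance")
    t_obs = float(sps.ttest_ind(a, b, equal_var=False).statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    nA = a.size
    for i in range(B):
        perm = rng.permutation(pooled)
        pa, pb = perm[:nA], perm[nA:]
        va, vb = pa.var(ddof=1), pb.var(ddof=1)
        null[i] = (pa.mean() - pb.mean()) / np.sqrt(va / nA + vb / pb.size)
    return PermutationResult(
        observed_stat=t_obs, null_stats=null, p_value=_perm_p(t_obs, null, tails),
        B=B, seed=seed, tails=tails,
    )


def _stack_offdiag(mats, labels_n=None):
    """(n_subj, n, n) stack -> (n_subj, n_edges) over the strict upper triangle."""
    arr = np.asarray([m.values if hasattr(m, "values") else m for m in mats], dtype=float)
    n = arr.shape[1]
    iu = np.triu_indices(n, k=1)
    return arr[:, iu[0], iu[1]], iu, n


def edgewise_t(matricesA, matricesB):
    """Per-edge Welch t across subjects with two-tailed parametric p.

    Returns symmetric (t, p) matrices with zero diagonal; edges with zero
    variance in both groups are masked as NaN.
    """
    A, iu, n = _stack_offdiag(matricesA)
    Bm, _, n2 = _stack_offdiag(matricesB)
    if n != n2:
        raise ParameterError("groups have different matrix sizes")
    if A.shape[0] < 2 or Bm.shape[0] < 2:
        raise ParameterError("need at least 2 subjects per group")
    t, p, _ = _welch_t(A, Bm)
    dead = (A.var(axis=0) == 0) & (Bm.var(axis=0) == 0)
    if dead.any():
        warnings.warn(f"{int(dead.sum())} edge(s) with zero variance in both groups masked")
        t[dead] = np.nan
        p[dead] = np.nan
    tm = np.zeros((n, n))
    pm = np.zeros((n, n))
    tm[iu] = t
    pm[iu] = p
    tm = tm + tm.T
    pm = pm + pm.T
    return tm, pm


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _clusters_and_masses(t: np.ndarray, p: np.ndarray, iu, n, alpha: float):
    """Supra-threshold edges grouped by shared-endpoint adjacency."""
    with np.errstate(invalid="ignore"):
        supra = p < alpha
    if not supra.any():
        return [], []
    uf = _UnionFind(n)
    ii, jj = iu[0][supra], iu[1][supra]
    for i, j in zip(ii, jj):
        uf.union(int(i), int(j))
    groups = {}
    for e, (i, j) in enumerate(zip(ii, jj)):
        groups.setdefault(uf.find(int(i)), []).append(e)
    tv = np.abs(t[supra])
    clusters, masses = [], []
    for members in groups.values():
        clusters.append([(int(ii[e]), int(jj[e])) for e in members])
        masses.append(float(tv[members].sum()))
    order = np.argsort(masses)[::-1]
    return [clusters[o] for o in order], [masses[o] for o in order]


def cbpt(
    matricesA,
    matricesB,
    electrode_labels: list[str] | None = None,
    forming_alpha: float = 0.05,
    B: int = 1000,
    seed: int | None = None,
) -> ClusterResult:
    """Cluster-based permutation test over a sensor-pair network.

    Uncorrected edge p-values below ``forming_alpha`` define supra-threshold
    edges; connected groups of edges sharing an electrode form clusters whose
    mass is the summed |t|.  The null is the maximum cluster mass over B
    whole-subject label permutations; cluster p uses the add-one rule.
    """
    A, iu, n = _stack_offdiag(matricesA)
    Bm, _, _ = _stack_offdiag(matricesB)
    nA = A.shape[0]
    pooled = np.concatenate([A, Bm], axis=0)
    t_obs, p_obs, _ = _welch_t(A, Bm)
    clusters, masses = _clusters_and_masses(t_obs, p_obs, iu, n, forming_alpha)

    tm = np.zeros((n, n)); pm = np.zeros((n, n))
    tm[iu] = t_obs; pm[iu] = p_obs
    result = ClusterResult(
        clusters=clusters, cluster_mass=masses, cluster_p=[],
        edge_t=tm + tm.T, edge_p=pm + pm.T,
    )
    if not clusters:
        return result

    rng = np.random.default_rng(seed)
    null_max = np.zeros(B)
    nsub = pooled.shape[0]
    for b in range(B):
        perm = rng.permutation(nsub)
        pa = pooled[perm[:nA]]
        pb = pooled[perm[nA:]]
        t_b, p_b, _ = _welch_t(pa, pb)
        _, m_b = _clusters_and_masses(t_b, p_b, iu, n, forming_alpha)
        null_max[b] = m_b[0] if m_b else 0.0
    result.cluster_p = [
        float((1 + np.sum(null_max >= m)) / (1 + B)) for m in masses
    ]
    return result


def demographics_table(df, group_col: str, value_cols: list[str]):
    """Two-sample t tests on demographic columns with Bonferroni correction.

    Returns a DataFrame with group means/SDs, raw and corrected p-values.
    """
    import pandas as pd

    groups = sorted(df[group_col].unique())
    if len(groups) != 2:
        raise ParameterError("demographics_table expects exactly two groups")
    g0 = df[df[group_col] == groups[0]]
    g1 = df[df[group_col] == groups[1]]
    rows = []
    for col in value_cols:
        t = sps.ttest_ind(g0[col], g1[col], equal_var=False)
        rows.append({
            "variable": col,
            f"mean_{groups[0]}": g0[col].mean(), f"sd_{groups[0]}": g0[col].std(),
            f"mean_{groups[1]}": g1[col].mean(), f"sd_{groups[1]}": g1[col].std(),
            "t": t.statistic, "p": t.pvalue,
            "p_bonferroni": min(1.0, t.pvalue * len(value_cols)),
        })
    return pd.DataFrame(rows)
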