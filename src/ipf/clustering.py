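"""Patient clustering: 1 - correlation dissimilarity on smoothed profiles,
partitioning around medoids (PAM), and gap-statistic selection of the
cluster count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .fusion import SmoothedProfiles

logger = logging.getLogger("ipf")


# ======================================================================
# dissimilarities
# ======================================================================
def correlation_dissimilarity(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between the rows of X; entries in [0, 2].

    Rows with zero variance have undefined correlation; their off-diagonal
    dissimilarities are set to the neutral value 1 with a warning.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant profile(s); dissimilarity set to 1")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R = np.nan_to_num(R, nan=0.0)
    D = 1.0 - R
    D[const, :] = 1.0
    D[:, const] = 1.0
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2.0, 0.0, 2.0)


def patient_dissimilarity(profiles: SmoothedProfiles | pd.DataFrame) -> pd.DataFrame:
    """Pairwise patient dissimilarity D_jj' = 1 - cor(c_j, c_j')."""
    values = profiles.values if isinstance(profiles, SmoothedProfiles) else profiles
    D = correlation_dissimilarity(values.to_numpy())
    return pd.DataFrame(D, index=values.index, columns=values.index)


# ======================================================================
# PAM (k-medoids, BUILD + SWAP)
# ======================================================================
def _pam_build(D: np.ndarray, k: int, first: int | None = None) -> list[int]:
    n = D.shape[0]
    if first is None:
        first = int(np.argmin(D.sum(axis=1)))
    medoids = [first]
    dnear = D[:, first].copy()
    while len(medoids) < k:
        cand = np.setdiff1d(np.arange(n), medoids)
        gains = np.maximum(dnear[:, None] - D[:, cand], 0.0).sum(axis=0)
        best = cand[int(np.argmax(gains))]  # argmax takes the lowest index on ties
        medoids.append(int(best))
        dnear = np.minimum(dnear, D[:, best])
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int], max_iter: int = 200) -> list[int]:
    n = D.shape[0]
    medoids = sorted(medoids)
    cost = D[:, medoids].min(axis=1).sum()
    for _ in range(max_iter):
        best_delta, best_swap = -1e-12, None
        for pos, i in enumerate(medoids):
            others = [m for m in medoids if m != i]
            dother = (
                D[:, others].min(axis=1) if others else np.full(n, np.inf)
            )
            cand = np.setdiff1d(np.arange(n), medoids)
            new_costs = np.minimum(dother[:, None], D[:, cand]).sum(axis=0)
            j = int(np.argmin(new_costs))
            delta = cost - new_costs[j]
            if delta > best_delta + 1e-12:
                best_delta, best_swap = delta, (pos, int(cand[j]))
        if best_swap is None:
            break
        pos, h = best_swap
        medoids[pos] = h
        medoids = sorted(medoids)
        cost -= best_delta
    return medoids


def _assign(D: np.ndarray, medoids: list[int]) -> np.ndarray:
    """Cluster labels 1..K; ties go to the lower-numbered cluster."""
    return np.argmin(D[:, medoids], axis=1) + 1


@dataclass
class ClusterSolution:
    """Patient partition from PAM: labels 1..K, medoid samples, the chosen
    K, and (when selected by the gap statistic) the gap curve."""

    labels: pd.Series  # index = sample id, values in 1..K
    medoid_ids: list[str]
    K: int
    cost: float
    source: str = ""
    gap_curve: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        lab = self.labels.to_numpy()
        assert lab.min() >= 1 and lab.max() <= self.K
        assert len(self.medoid_ids) == self.K

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    def write(self, path) -> None:
        self.labels.rename("cluster").to_csv(path, sep="\t", index_label="sample_id")


def pam(
    dissim: pd.DataFrame | np.ndarray,
    k: int,
    seed: int | None = None,
    source: str = "",
    starts: int = 5,
) -> ClusterSolution:
    """Partitioning around medoids on a precomputed dissimilarity matrix.

    BUILD then greedy best-improvement SWAP, restarted from ``starts``
    deterministic anchors (the samples with smallest total dissimilarity
    seed successive BUILDs) with the lowest-cost solution kept — a cheap
    guard against the local optima single-start BUILD+SWAP is known to hit
    on ambiguous geometries.  Ties are broken toward the lowest sample
    index, so results are fully deterministic (``seed`` is accepted for
    interface symmetry but the algorithm has no randomness).
    """
    if isinstance(dissim, pd.DataFrame):
        ids = list(dissim.index)
        D = dissim.to_numpy(dtype=float)
    else:
        D = np.asarray(dissim, dtype=float)
        ids = [str(i) for i in range(D.shape[0])]
    n = D.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    if k == n:
        medoids = list(range(n))
    else:
        anchors = np.argsort(D.sum(axis=1), kind="stable")[: max(1, starts)]
        best_cost, medoids = np.inf, None
        for a in anchors:
            cand = _pam_swap(D, _pam_build(D, k, first=int(a)))
            c = pam_objective(D, cand)
            if c < best_cost - 1e-12:
                best_cost, medoids = c, cand
    labels = _assign(D, medoids)
    cost = float(D[np.arange(n), [medoids[l - 1] for l in labels]].sum())
    return ClusterSolution(
        labels=pd.Series(labels, index=ids),
        medoid_ids=[ids[m] for m in medoids],
        K=k,
        cost=cost,
        source=source,
    )


def pam_objective(D: np.ndarray, medoids: list[int]) -> float:
    """Total dissimilarity of every point to its nearest medoid."""
    return float(np.asarray(D)[:, medoids].min(axis=1).sum())


# ======================================================================
# gap statistic
# ======================================================================
def _within_dispersion(D: np.ndarray, labels: np.ndarray, power: int = 2) -> float:
    """W_k = sum_r (1 / 2 n_r) * sum of within-cluster d^power.

    ``power=2`` matches the original gap-statistic dispersion (pooled
    within-cluster sum of squared pairwise distances).
    """
    Dp = D ** power if power != 1 else D
    W = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) > 1:
            W += Dp[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return W


def gap_select(
    X: pd.DataFrame | np.ndarray,
    k_max: int = 6,
    B: int = 20,
    seed: int = 0,
    dissim_fn: Callable[[np.ndarray], np.ndarray] = correlation_dissimilarity,
    rule: str = "increment",
    reference: str = "pca",
    ref_space: np.ndarray | pd.DataFrame | None = None,
    ref_transform: Callable[[np.ndarray], np.ndarray] | None = None,
    source: str = "",
) -> ClusterSolution:
    """Choose the cluster count by the gap statistic and return that PAM fit.

    ``X`` holds one observation per row (smoothed profiles or any feature
    matrix); dissimilarities come from ``dissim_fn`` (default 1 - Pearson).
    Null reference sets are drawn uniformly over the observed range of each
    coordinate, by default in the principal-component rotation of the data
    (``reference="pca"``); the rotation preserves the data's covariance
    footprint, which matters for correlation-based dissimilarities.  When the
    clustered rows are derived quantities (smoothed profiles), pass the
    underlying feature matrix as ``ref_space`` and the profile-producing map
    as ``ref_transform``: null draws are then made at the feature level and
    pushed through the same smoothing, so any structure the pipeline itself
    manufactures is present under the null too.  gap(k) = mean_b log W*_kb -
    log W_k with W the pooled within-cluster sum of squared dissimilarities.

    Decision rules (``rule``):

    - ``"increment"`` (default): K = 1 if no k improves on gap(1) by more
      than one reference standard error; otherwise the k at which the gap
      curve makes its largest upward jump gap(k) - gap(k-1).  Correlation
      dissimilarities on smoothed profiles keep shrinking as genuine
      clusters are split, so the gap can drift upward past the true K; the
      largest increment marks where the real structure is resolved.
    - ``"1se"``: Tibshirani's rule, smallest k with
      gap(k) >= gap(k+1) - s_{k+1}.
    - ``"globalse"``: smallest k with gap(k) >= max_k' gap(k') - s_{k'*}.
    - ``"maxgap"``: argmax gap(k).

    The scan starts at k = 1 so an unclustered cohort is representable.
    """
    if rule not in ("increment", "1se", "maxgap", "globalse"):
        raise ValueError("rule must be 'increment', '1se', 'globalse' or 'maxgap'")
    if reference not in ("pca", "uniform"):
        raise ValueError("reference must be 'pca' or 'uniform'")
    if isinstance(X, pd.DataFrame):
        ids = list(X.index)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        ids = [str(i) for i in range(arr.shape[0])]
    rng = np.random.default_rng(seed)
    ks = np.arange(1, k_max + 1)

    D = dissim_fn(arr)
    sols = {k: pam(D, k) for k in ks}
    logW = np.array(
        [_safe_log(_within_dispersion(D, sols[k].labels.to_numpy())) for k in ks]
    )

    if ref_space is None:
        space = arr
    elif isinstance(ref_space, pd.DataFrame):
        space = ref_space.to_numpy(dtype=float)
    else:
        space = np.asarray(ref_space, dtype=float)
    if np.isnan(space).any():  # box construction only; observed fit unaffected
        col_mean = np.nanmean(space, axis=0)
        space = np.where(np.isnan(space), col_mean, space)
    if reference == "pca":
        mean = space.mean(axis=0)
        _, _, Vt = np.linalg.svd(space - mean, full_matrices=False)
        scores = (space - mean) @ Vt.T
        lo, hi = scores.min(axis=0), scores.max(axis=0)
    else:
        mean, Vt = None, None
        lo, hi = space.min(axis=0), space.max(axis=0)
    logWstar = np.empty((B, len(ks)))
    for b in range(B):
        if reference == "pca":
            ref = rng.uniform(lo, hi, size=(space.shape[0], len(lo))) @ Vt + mean
        else:
            ref = rng.uniform(lo, hi, size=space.shape)
        if ref_transform is not None:
            ref = ref_transform(ref)
        Dref = dissim_fn(ref)
        for j, k in enumerate(ks):
            lab = pam(Dref, k).labels.to_numpy()
            logWstar[b, j] = _safe_log(_within_dispersion(Dref, lab))

    gap = logWstar.mean(axis=0) - logW
    sd = logWstar.std(axis=0, ddof=0)
    s = sd * np.sqrt(1.0 + 1.0 / B)

    if rule == "maxgap":
        chosen = int(ks[int(np.argmax(gap))])
    elif rule == "globalse":
        jstar = int(np.argmax(gap))
        thr = gap[jstar] - s[jstar]
        chosen = int(ks[int(np.argmax(gap >= thr))])
    elif rule == "increment":
        jstar = int(np.argmax(gap))
        if gap[jstar] - s[jstar] <= gap[0]:
            chosen = int(ks[0])  # nothing beats the unclustered null
        else:
            chosen = int(ks[1 + int(np.argmax(np.diff(gap)))])
    else:  # Tibshirani's one-standard-error rule
        chosen = int(ks[-1])
        for j in range(len(ks) - 1):
            if gap[j] >= gap[j + 1] - s[j + 1]:
                chosen = int(ks[j])
                break

    curve = pd.DataFrame({"k": ks, "gap": gap, "se": s, "logW": logW})
    best = sols[chosen]  # fitted on positional ids "0".."n-1"
    return ClusterSolution(
        labels=pd.Series(best.labels.to_numpy(), index=ids),
        medoid_ids=[ids[int(m)] for m in best.medoid_ids],
        K=chosen,
        cost=best.cost,
        source=source,
        gap_curve=curve,
    )


def _safe_log(w: float) -> float:
    if w <= 0:
        warnings.warn("zero within-cluster dispersion; log guarded")
        return float(np.log(np.finfo(float).tiny))
    return float(np.log(w))


# ======================================================================
# cluster-averaged profiles
# ======================================================================
def cluster_average_ftp(
    profiles: SmoothedProfiles, solution: ClusterSolution
) -> SmoothedProfiles:
    """Element-wise mean profile per cluster (the representative FTPs)."""
    missing = [s for s in profiles.sample_ids if s not in solution.labels.index]
    if missing:
        raise ValueError(f"samples without cluster labels: {missing[:5]}")
    rows, idx = [], []
    for c in range(1, solution.K + 1):
        members = [s for s in solution.members(c) if s in profiles.values.index]
        if not members:
            raise ValueError(f"cluster {c} has no profiled members")
        rows.append(profiles.values.loc[members].mean(axis=0))
        idx.append(f"cluster_{c}")
    return SmoothedProfiles(
        pd.DataFrame(rows, index=idx), profiles.grid_n, profiles.source
    )
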