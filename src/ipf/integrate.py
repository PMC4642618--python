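"""Integrative strategy across omics sources.

Each source yields its own patient clustering; pairs of sources are
cross-tabulated (with optimal cluster matching) to decide whether they tell
a homogeneous story.  Homogeneous pairs are merged — their features pooled
and the patients re-smoothed and re-clustered on the shared embedding — and
the process repeats agglomeratively until only heterogeneous pairs remain,
which are reported side by side.  A frozen embedding also supports the
discovery -> prediction -> validation scheme on a held-out cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import comb

from .clustering import (
    ClusterSolution,
    cluster_average_ftp,
    gap_select,
    pam,
    patient_dissimilarity,
)
from .config import RunConfig
from .datasets import OmicsDataset, align_samples
from .fusion import (
    FeatureEmbedding,
    SmoothedProfiles,
    concatenate,
    correlation_matrix,
    dissimilarity,
    embed,
    smooth_patients,
)
from .preprocess import filter_features, standardize

logger = logging.getLogger("ipf")


# ======================================================================
# adjusted Rand index
# ======================================================================
def ari(labels1, labels2) -> float:
    """Adjusted Rand index between two partitions of the same samples.

    Computed from the contingency table under the permutation model:
    ARI = (sum_ij C(n_ij,2) - E) / (max - E) with
    E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2).
    """
    l1 = np.asarray(labels1)
    l2 = np.asarray(labels2)
    if l1.shape != l2.shape:
        raise ValueError("label vectors must have equal length")
    n = len(l1)
    table = pd.crosstab(pd.Series(l1), pd.Series(l2)).to_numpy()
    sum_ij = comb(table, 2).sum()
    a = comb(table.sum(axis=1), 2).sum()
    b = comb(table.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = a * b / total if total > 0 else 0.0
    max_index = 0.5 * (a + b)
    if max_index == expected:  # degenerate marginals (all-one-cluster etc.)
        return 0.0
    return float((sum_ij - expected) / (max_index - expected))


# ======================================================================
# cross-tabulation and homogeneity
# ======================================================================
@dataclass
class ComparisonReport:
    """Cross-tabulation of two cluster solutions with an optimal diagonal.

    The cluster correspondence is chosen by maximum-weight bipartite
    matching on the contingency table, so the off-diagonal count is
    invariant to how either solution numbers its clusters.
    """

    source1: str
    source2: str
    table: pd.DataFrame
    matching: list[tuple[int, int]]  # (row cluster, column cluster) pairs
    offdiag_count: int
    offdiag_fraction: float
    ari: float
    verdict: str = ""

    @property
    def n_samples(self) -> int:
        return int(self.table.to_numpy().sum())


def crosstab(
    sol1: ClusterSolution, sol2: ClusterSolution, threshold: float | None = None
) -> ComparisonReport:
    """Compare two patient clusterings of the same cohort."""
    if set(sol1.labels.index) != set(sol2.labels.index):
        raise ValueError("cluster solutions cover different samples")
    l2 = sol2.labels.reindex(sol1.labels.index)
    table = pd.crosstab(sol1.labels, l2)
    table = table.reindex(
        index=range(1, sol1.K + 1), columns=range(1, sol2.K + 1), fill_value=0
    )
    table.index.name = sol1.source or "clusters_1"
    table.columns.name = sol2.source or "clusters_2"
    arr = table.to_numpy()
    rows, cols = linear_sum_assignment(-arr)
    matched = int(arr[rows, cols].sum())
    total = int(arr.sum())
    offdiag = total - matched
    report = ComparisonReport(
        source1=sol1.source,
        source2=sol2.source,
        table=table,
        matching=[(int(r) + 1, int(c) + 1) for r, c in zip(rows, cols)],
        offdiag_count=offdiag,
        offdiag_fraction=offdiag / total,
        ari=ari(sol1.labels.to_numpy(), l2.to_numpy()),
    )
    if threshold is not None:
        report.verdict = decide_homogeneity(report, threshold)
    return report


def decide_homogeneity(report: ComparisonReport, threshold: float = 0.20) -> str:
    """Call a pair of sources homogeneous when at most ``threshold`` of the
    cohort falls off the optimally matched diagonal (boundary counts as
    homogeneous)."""
    verdict = "homogeneous" if report.offdiag_fraction <= threshold else "heterogeneous"
    report.verdict = verdict
    return verdict


# ======================================================================
# fitted per-source (or per-group) clustering, reusable for prediction
# ======================================================================
@dataclass
class TrainedClustering:
    """Everything needed to reproduce or transfer one source's clustering:
    the frozen feature embedding, the standardized training values of the
    source's features, the smoothed profiles and the PAM solution."""

    source: str
    embedding: FeatureEmbedding
    train_values: pd.DataFrame  # samples x features (standardized)
    profiles: SmoothedProfiles
    solution: ClusterSolution
    grid_n: int

    @property
    def feature_ids(self) -> list[str]:
        return list(self.train_values.columns)


def fit_source(
    embedding: FeatureEmbedding,
    values: pd.DataFrame,
    config: RunConfig,
    source: str,
) -> TrainedClustering:
    """Smooth one source's (possibly pooled) features on the shared embedding
    and cluster the patients, selecting K by the gap statistic.

    The gap-statistic null is drawn at the feature level (uniform box in the
    PCA rotation of the standardized feature matrix) and pushed through the
    same thin-plate smoothing, so smoothing artefacts do not masquerade as
    cluster structure.
    """
    from .fusion import ThinPlateSmoother, unit_grid

    profiles = smooth_patients(embedding, values, grid_n=config.grid_n, source=source)
    coords = embedding.coords.loc[values.columns].to_numpy()
    smoother = ThinPlateSmoother(coords)
    grid = unit_grid(config.grid_n)

    def _smooth_reference(F: np.ndarray) -> np.ndarray:
        return smoother.fit(F.T).predict(grid).T

    solution = gap_select(
        profiles.values,
        k_max=config.k_max,
        B=config.gap_B,
        seed=config.seed,
        ref_space=values,
        ref_transform=_smooth_reference,
        source=source,
    )
    return TrainedClustering(source, embedding, values, profiles, solution, config.grid_n)


# ======================================================================
# merge workflow
# ======================================================================
@dataclass
class MergePlan:
    events: list[tuple[str, str, str]] = field(default_factory=list)  # (a, b, merged)
    final_groups: list[list[str]] = field(default_factory=list)


@dataclass
class WorkflowResult:
    embedding: FeatureEmbedding
    merge_plan: MergePlan
    trained: dict[str, TrainedClustering]  # final group name -> fit
    reports: list[ComparisonReport]  # final (heterogeneous) pairwise panels
    history: list[ComparisonReport] = field(default_factory=list)

    def solution(self, source: str) -> ClusterSolution:
        return self.trained[source].solution


def prepare_datasets(
    datasets: list[OmicsDataset], config: RunConfig
) -> list[OmicsDataset]:
    """Filter, align and standardize every source.

    Quantile filters apply to expression-style (all-continuous) sources;
    mixed-type clinical tables only lose constant features.
    """
    filtered = []
    for ds in datasets:
        all_cont = (ds.var_types == "continuous").all()
        mq = config.filter_mean_quantile if all_cont else 0.0
        sq = config.filter_sd_quantile if all_cont else 0.0
        fds, report = filter_features(ds, mean_q=mq, sd_q=sq)
        logger.info(
            "%s: kept %d / %d features", ds.name, len(report.kept_ids), ds.n_features
        )
        filtered.append(fds)
    if len(filtered) > 1:
        filtered = align_samples(filtered)
    return [standardize(ds) for ds in filtered]


def build_embedding(
    datasets: list[OmicsDataset], config: RunConfig
) -> tuple[FeatureEmbedding, dict[str, pd.DataFrame]]:
    """One shared non-metric MDS embedding of all concatenated features.

    Coordinates live in a common unit square, which is what makes per-source
    clusterings comparable and merged-source smoothing well defined.
    """
    concat = concatenate(datasets)
    R = correlation_matrix(concat)
    D = dissimilarity(R)
    embedding = embed(D, seed=config.seed)
    values = {ds.name: ds.values[ds.feature_ids] for ds in datasets}
    return embedding, values


def merge_and_recluster(
    embedding: FeatureEmbedding,
    group_values: list[pd.DataFrame],
    config: RunConfig,
    source: str,
) -> TrainedClustering:
    """Pool the features of a homogeneous group and recluster the patients
    with a single smooth per patient over the shared embedding."""
    if len(group_values) == 1:
        return fit_source(embedding, group_values[0], config, source)
    pooled = pd.concat(group_values, axis=1)
    return fit_source(embedding, pooled, config, source)


def run_workflow(
    datasets: list[OmicsDataset],
    config: RunConfig | None = None,
    preprocessed: bool = False,
) -> WorkflowResult:
    """Full agglomerative integration of two or more omics sources.

    Every source is clustered on the shared embedding; all pairs are
    cross-tabulated; the most homogeneous pair under the off-diagonal
    threshold is merged and reclustered; this repeats until no pair is
    mergeable (at most M - 1 merges).  The surviving pairwise comparisons
    are returned as the heterogeneity panel.
    """
    config = config or RunConfig()
    if len(datasets) < 2:
        raise ValueError("the workflow needs at least 2 omics sources")
    if not preprocessed:
        datasets = prepare_datasets(datasets, config)
    embedding, values = build_embedding(datasets, config)

    trained = {
        name: fit_source(embedding, vals, config, name) for name, vals in values.items()
    }
    groups: dict[str, list[pd.DataFrame]] = {name: [v] for name, v in values.items()}
    plan = MergePlan()
    history: list[ComparisonReport] = []

    while len(trained) > 1:
        names = sorted(trained)
        reports = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rep = crosstab(
                    trained[names[i]].solution,
                    trained[names[j]].solution,
                    threshold=config.homogeneity_max_offdiag,
                )
                reports.append(rep)
        history.extend(reports)
        mergeable = [r for r in reports if r.verdict == "homogeneous"]
        if not mergeable:
            final_reports = reports
            break
        best = min(mergeable, key=lambda r: r.offdiag_fraction)
        a, b = best.source1, best.source2
        merged_name = f"{a}+{b}"
        logger.info(
            "merging %s and %s (offdiag %.3f)", a, b, best.offdiag_fraction
        )
        group_vals = groups.pop(a) + groups.pop(b)
        groups[merged_name] = group_vals
        del trained[a], trained[b]
        trained[merged_name] = merge_and_recluster(
            embedding, group_vals, config, merged_name
        )
        plan.events.append((a, b, merged_name))
        final_reports = []
    else:
        final_reports = []

    plan.final_groups = [name.split("+") for name in sorted(trained)]
    return WorkflowResult(embedding, plan, trained, final_reports, history)


# ======================================================================
# discovery -> prediction -> validation
# ======================================================================
def predict_clusters(
    trained: TrainedClustering, new_values: pd.DataFrame
) -> pd.Series:
    """Assign new patients to the training clusters.

    The training embedding is frozen; features absent from the new cohort
    are dropped from both cohorts, both are re-smoothed on the common
    feature set, and each new patient joins the cluster of its nearest
    training medoid under 1 - Pearson correlation of the profiles.
    """
    common = [f for f in trained.feature_ids if f in new_values.columns]
    overlap = len(common) / len(trained.feature_ids)
    if overlap < 0.5:
        raise ValueError(
            f"only {overlap:.0%} of training features present in the new cohort"
        )
    if len(common) == len(trained.feature_ids):
        train_profiles = trained.profiles
    else:
        train_profiles = smooth_patients(
            trained.embedding,
            trained.train_values[common],
            grid_n=trained.grid_n,
            source=trained.source,
        )
    new_profiles = smooth_patients(
        trained.embedding, new_values[common], grid_n=trained.grid_n,
        source=trained.source,
    )
    medoid_mat = train_profiles.values.loc[trained.solution.medoid_ids].to_numpy()
    new_mat = new_profiles.values.to_numpy()

    # 1 - cor between every new profile and every medoid profile
    def _center_norm(M: np.ndarray) -> np.ndarray:
        M = M - M.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(M, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return M / norm

    C = _center_norm(new_mat) @ _center_norm(medoid_mat).T
    labels = np.argmin(1.0 - C, axis=1) + 1  # ties -> lower-numbered cluster
    return pd.Series(labels, index=new_profiles.values.index, name="cluster")


def validation_concordance(
    trained: TrainedClustering,
    new_values: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[pd.Series, ClusterSolution, float]:
    """Prediction vs independent re-clustering of a held-out cohort.

    Returns the predicted labels, the within-cohort PAM solution (K fixed to
    the training K) and the ARI between the two — the concordance statistic
    of the validation phase.
    """
    config = config or RunConfig()
    predicted = predict_clusters(trained, new_values)
    common = [f for f in trained.feature_ids if f in new_values.columns]
    profiles = smooth_patients(
        trained.embedding, new_values[common], grid_n=trained.grid_n,
        source=trained.source,
    )
    D = patient_dissimilarity(profiles)
    revalidated = pam(D, trained.solution.K, source=trained.source)
    concordance = ari(predicted.to_numpy(), revalidated.labels.to_numpy())
    return predicted, revalidated, concordance
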