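"""Post-clustering biomarker detection and characterisation.

Once patient clusters are fixed, each molecular feature is tested for a
cluster effect with a one-way ANOVA under Bonferroni control; the
significant features are grouped into co-expression modules by PAM on a
1 - Pearson feature distance (with an optional sign flip for inhibitory
species such as miRNAs), and clinical variables are summarised per cluster
with Kruskal-Wallis tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import correlation_dissimilarity, gap_select
from .datasets import OmicsDataset


# ======================================================================
# one-way ANOVA feature selection
# ======================================================================
@dataclass
class BiomarkerResult:
    feature_id: str
    omics: str
    f_stat: float
    p_value: float
    p_adjusted: float
    significant: bool


def _oneway_f(X: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way F statistic and p per column of X (NaN-aware)."""
    levels = np.unique(groups)
    k = len(levels)
    n_feat = X.shape[1]
    obs = ~np.isnan(X)
    grand_sum = np.nansum(X, axis=0)
    grand_n = obs.sum(axis=0)
    grand_mean = grand_sum / grand_n
    ss_between = np.zeros(n_feat)
    ss_within = np.zeros(n_feat)
    n_groups = np.zeros(n_feat)
    for g in levels:
        sel = groups == g
        Xg = X[sel]
        ng = (~np.isnan(Xg)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            mg = np.nansum(Xg, axis=0) / ng
            ss_between += np.where(ng > 0, ng * (mg - grand_mean) ** 2, 0.0)
            ss_within += np.nansum((Xg - mg) ** 2, axis=0)
        n_groups += ng > 0
    df_between = n_groups - 1
    df_within = grand_n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_between = ss_between / df_between
        ms_within = ss_within / df_within
        F = ms_between / ms_within
    # degenerate features: no between- and no within-variation -> F = 0, p = 1
    zero_both = (ss_between <= 1e-300) & (ss_within <= 1e-300)
    F = np.where(zero_both, 0.0, F)
    F = np.where(np.isfinite(F), F, np.inf)
    p = stats.f.sf(F, df_between, df_within)
    p = np.where(zero_both, 1.0, p)
    return F, p


def anova_select(
    datasets: list[OmicsDataset],
    labels: pd.Series,
    alpha: float = 1e-10,
    clusters: list[int] | None = None,
) -> pd.DataFrame:
    """Per-feature one-way ANOVA across the selected clusters, Bonferroni
    adjusted over every tested feature from every source.

    ``labels`` gives the cluster of each sample; ``clusters`` restricts the
    test to a subset of unambiguous clusters (all clusters by default).
    Returns a frame sortable by adjusted p with a ``significant`` flag at
    ``alpha``.
    """
    if clusters is not None:
        labels = labels[labels.isin(clusters)]
    counts = labels.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 clusters with >= 2 members each")
    rows = []
    n_tests = sum(ds.n_features for ds in datasets)
    for ds in datasets:
        sub = ds.values.loc[labels.index]
        F, p = _oneway_f(sub.to_numpy(dtype=float), labels.to_numpy())
        for fid, f_val, p_val in zip(ds.feature_ids, F, p):
            p_adj = min(1.0, p_val * n_tests)
            rows.append(
                BiomarkerResult(fid, ds.name, float(f_val), float(p_val),
                                float(p_adj), bool(p_adj < alpha))
            )
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.sort_values("p_adjusted", kind="stable").reset_index(drop=True)


# ======================================================================
# co-expression module discovery
# ======================================================================
@dataclass
class ModuleResult:
    assignments: pd.DataFrame  # feature_id, omics, module, sign_flipped
    G: int
    gap_curve: pd.DataFrame
    flipped_values: pd.DataFrame  # features x samples, after the sign flip


def module_discovery(
    values: pd.DataFrame,
    flip_set: list[str] | None = None,
    g_max: int = 8,
    B: int = 20,
    seed: int = 0,
    omics: pd.Series | None = None,
) -> ModuleResult:
    """Cluster significant features into co-expression modules.

    ``values`` is features x samples (standardized intensities of the
    significant features).  Features named in ``flip_set`` are negated
    first — the device that lets inhibitory miRNAs join the module of the
    mRNAs they suppress.  PAM on 1 - Pearson feature correlation; the
    module count G is chosen by the gap statistic over 1..g_max.
    """
    if values.shape[0] < 2:
        raise ValueError("need at least 2 significant features to form modules")
    flip_set = flip_set or []
    unknown = [f for f in flip_set if f not in values.index]
    if unknown:
        raise ValueError(f"flip_set features not present: {unknown[:5]}")
    flipped = values.copy()
    flipped.loc[flip_set] = -flipped.loc[flip_set]

    sol = gap_select(
        flipped, k_max=g_max, B=B, seed=seed,
        dissim_fn=correlation_dissimilarity, source="modules",
    )
    assignments = pd.DataFrame(
        {
            "feature_id": flipped.index,
            "omics": omics.reindex(flipped.index).to_numpy() if omics is not None else "",
            "module": sol.labels.to_numpy(),
            "sign_flipped": flipped.index.isin(flip_set),
        }
    )
    return ModuleResult(assignments, sol.K, sol.gap_curve, flipped)


# ======================================================================
# cluster-wise clinical summaries
# ======================================================================
def group_summary(clinical: OmicsDataset, labels: pd.Series) -> pd.DataFrame:
    """Per-cluster means (percent in level 1 for binary variables) with
    Kruskal-Wallis p across all clusters and pairwise rank tests.

    Pairwise p-values are reported unadjusted, as is conventional for
    descriptive cohort tables.
    """
    labels = labels.reindex(clinical.sample_ids).dropna()
    clusters = sorted(labels.unique())
    rows = []
    for fid in clinical.feature_ids:
        col = clinical.values[fid].reindex(labels.index)
        is_binary = clinical.var_types[fid] == "binary"
        row: dict[str, object] = {"variable": fid}
        groups = []
        for c in clusters:
            vals = col[labels == c].dropna()
            groups.append(vals.to_numpy())
            if is_binary and len(vals):
                top = np.nanmax(clinical.values[fid].to_numpy())
                row[f"cluster_{c}"] = float((vals == top).mean() * 100.0)
            else:
                row[f"cluster_{c}"] = float(vals.mean()) if len(vals) else np.nan
        nonempty = [g for g in groups if len(g) > 0]
        if len(nonempty) < 2:
            row["kw_p"] = np.nan
        elif np.ptp(np.concatenate(nonempty)) == 0:
            row["kw_p"] = 1.0
        else:
            row["kw_p"] = float(stats.kruskal(*nonempty).pvalue)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                key = f"p_{clusters[a]}_vs_{clusters[b]}"
                ga, gb = groups[a], groups[b]
                if len(ga) == 0 or len(gb) == 0:
                    row[key] = np.nan
                elif np.ptp(np.concatenate([ga, gb])) == 0:
                    row[key] = 1.0
                else:
                    row[key] = float(stats.kruskal(ga, gb).pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


# ======================================================================
# heatmap export
# ======================================================================
def heatmap_export(
    modules: ModuleResult,
    labels: pd.Series,
    path_img=None,
    path_tsv=None,
):
    """Module-by-cluster blocked heatmap of the significant features.

    Rows are ordered by module (sign-flipped rows annotated), columns by
    patient cluster; the reordered numeric matrix (post-flip) is exported
    alongside the image.
    """
    assign = modules.assignments.sort_values(["module", "feature_id"], kind="stable")
    order_samples = labels.sort_values(kind="stable").index
    mat = modules.flipped_values.loc[assign["feature_id"], order_samples]
    if path_tsv is not None:
        mat.to_csv(path_tsv, sep="\t", index_label="feature_id")
    fig = None
    if path_img is not None:
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 6))
        v = np.nanmax(np.abs(mat.to_numpy())) or 1.0
        ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-v, vmax=v)
        # block boundaries
        for m in assign["module"].unique()[:-1]:
            y = (assign["module"] <= m).sum() - 0.5
            ax.axhline(y, color="black", lw=0.8)
        cl = labels.loc[order_samples].to_numpy()
        for b in np.flatnonzero(cl[:-1] != cl[1:]):
            ax.axvline(b + 0.5, color="black", lw=0.8)
        flip_rows = np.flatnonzero(assign["sign_flipped"].to_numpy())
        ax.set_yticks(flip_rows)
        ax.set_yticklabels(["*"] * len(flip_rows), fontsize=6)
        ax.set_xlabel("samples (by cluster)")
        ax.set_ylabel("features (by module; * = sign-flipped)")
        fig.savefig(path_img, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return mat
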