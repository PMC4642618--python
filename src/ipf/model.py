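"""Model-style front end: configure once, ``fit()``, inspect results.

``IntegrativePhenotyping`` bundles the whole pipeline — preprocessing,
feature fusion, per-source clustering and agglomerative integration —
behind a fit/results pair, with prediction on new cohorts and biomarker
selection hanging off the results object.
"""

from __future__ import annotations

from io import StringIO
from pathlib import Path

import pandas as pd

from . import biomarkers as bm
from .clustering import cluster_average_ftp
from .config import RunConfig
from .datasets import OmicsDataset, read_omics
from .integrate import (
    WorkflowResult,
    predict_clusters,
    run_workflow,
    validation_concordance,
)
from .preprocess import standardize


class IntegrativePhenotyping:
    """Integrative patient-subtype model over multiple omics sources.

    Parameters
    ----------
    datasets : list of OmicsDataset
        Raw (pre-normalised) omics sources sharing sample ids.
    config : RunConfig, optional
        Pipeline settings; defaults are sensible for expression-scale data.
    """

    def __init__(self, datasets: list[OmicsDataset], config: RunConfig | None = None):
        if len(datasets) < 2:
            raise ValueError("provide at least two omics sources")
        self.datasets = datasets
        self.config = config or RunConfig()

    @classmethod
    def from_files(
        cls,
        paths: list[str | Path],
        types_paths: list[str | Path | None] | None = None,
        names: list[str] | None = None,
        config: RunConfig | None = None,
    ) -> "IntegrativePhenotyping":
        types_paths = types_paths or [None] * len(paths)
        names = names or [None] * len(paths)
        datasets = [
            read_omics(p, tp, n) for p, tp, n in zip(paths, types_paths, names)
        ]
        return cls(datasets, config)

    def fit(self) -> "IPFResults":
        """Run the full workflow and return the results object."""
        wf = run_workflow(self.datasets, self.config)
        return IPFResults(self, wf)


class IPFResults:
    """Fitted integrative clustering: per-group solutions, merge plan and
    pairwise comparison panels, plus prediction on held-out cohorts."""

    def __init__(self, model: IntegrativePhenotyping, workflow: WorkflowResult):
        self.model = model
        self.workflow = workflow

    # ------------------------------------------------------------------
    @property
    def groups(self) -> list[str]:
        return sorted(self.workflow.trained)

    def labels(self, group: str | None = None) -> pd.Series:
        group = group or self.groups[0]
        return self.workflow.trained[group].solution.labels

    def gap_curve(self, group: str | None = None) -> pd.DataFrame:
        group = group or self.groups[0]
        return self.workflow.trained[group].solution.gap_curve

    def cluster_profiles(self, group: str | None = None):
        """Cluster-averaged feature topology profiles for one group."""
        group = group or self.groups[0]
        t = self.workflow.trained[group]
        return cluster_average_ftp(t.profiles, t.solution)

    # ------------------------------------------------------------------
    def predict(self, new_dataset: OmicsDataset, group: str | None = None) -> pd.Series:
        """Nearest-medoid cluster labels for a new cohort on the frozen
        training embedding (the prediction phase)."""
        group = group or self.groups[0]
        trained = self.workflow.trained[group]
        values = self._prepare_new(new_dataset, trained.feature_ids)
        return predict_clusters(trained, values)

    def validate(self, new_dataset: OmicsDataset, group: str | None = None):
        """Prediction vs independent re-clustering of the new cohort;
        returns (predicted labels, revalidated solution, ARI)."""
        group = group or self.groups[0]
        trained = self.workflow.trained[group]
        values = self._prepare_new(new_dataset, trained.feature_ids)
        return validation_concordance(trained, values, self.model.config)

    @staticmethod
    def _prepare_new(ds: OmicsDataset, feature_ids: list[str]) -> pd.DataFrame:
        common = [f for f in feature_ids if f in ds.feature_ids]
        if not common:
            raise ValueError("new cohort shares no features with the training fit")
        return standardize(ds.subset_features(common)).values

    # ------------------------------------------------------------------
    def select_biomarkers(
        self,
        alpha: float | None = None,
        clusters: list[int] | None = None,
        group: str | None = None,
        sources: list[str] | None = None,
    ) -> pd.DataFrame:
        """One-way ANOVA of every molecular feature against the fitted
        cluster labels, Bonferroni-controlled."""
        labels = self.labels(group)
        datasets = self.model.datasets
        if sources is not None:
            datasets = [d for d in datasets if d.name in sources]
        datasets = [
            replace_values(d, labels.index) for d in datasets
        ]
        return bm.anova_select(
            datasets,
            labels,
            alpha=alpha if alpha is not None else self.model.config.anova_alpha,
            clusters=clusters,
        )

    # ------------------------------------------------------------------
    def summary(self) -> str:
        buf = StringIO()
        w = self.workflow
        print("Integrative phenotyping results", file=buf)
        print("=" * 60, file=buf)
        n = len(next(iter(w.trained.values())).solution.labels)
        print(f"samples: {n}   embedding stress: {w.embedding.stress:.4f}", file=buf)
        print(f"sources after merging: {', '.join(sorted(w.trained))}", file=buf)
        if w.merge_plan.events:
            for a, b, m in w.merge_plan.events:
                print(f"  merged: {a} + {b} -> {m}", file=buf)
        else:
            print("  no merges (all pairs heterogeneous)", file=buf)
        print("-" * 60, file=buf)
        for name in sorted(w.trained):
            sol = w.trained[name].solution
            sizes = sol.labels.value_counts().sort_index()
            size_str = ", ".join(f"{c}: {v}" for c, v in sizes.items())
            print(f"{name}: K = {sol.K}  cluster sizes  {size_str}", file=buf)
        for rep in w.reports:
            print("-" * 60, file=buf)
            print(
                f"{rep.source1} vs {rep.source2}: off-diagonal "
                f"{rep.offdiag_count}/{rep.n_samples} "
                f"({rep.offdiag_fraction:.1%}), ARI {rep.ari:.3f} "
                f"-> {rep.verdict}",
                file=buf,
            )
            print(rep.table.to_string(), file=buf)
        return buf.getvalue()

    # ------------------------------------------------------------------
    def plot_panel(self, report_index: int = 0, path=None):
        """Comparison panel for one remaining heterogeneous pair: marginal
        cluster-averaged FTPs along the axes of the cross-tabulation."""
        import matplotlib.pyplot as plt

        from .fusion import ftp_render

        rep = self.workflow.reports[report_index]
        t1 = self.workflow.trained[rep.source1]
        t2 = self.workflow.trained[rep.source2]
        avg1 = cluster_average_ftp(t1.profiles, t1.solution)
        avg2 = cluster_average_ftp(t2.profiles, t2.solution)
        k1, k2 = t1.solution.K, t2.solution.K
        fig, axes = plt.subplots(
            k1 + 1, k2 + 1, figsize=(2.2 * (k2 + 1), 2.2 * (k1 + 1))
        )
        axes = pd.DataFrame(axes)
        lo = min(avg1.values.min().min(), avg2.values.min().min())
        hi = max(avg1.values.max().max(), avg2.values.max().max())
        axes.iloc[0, 0].axis("off")
        for j in range(k2):
            ftp_render(avg2.profile(f"cluster_{j + 1}"), avg2.grid_n,
                       ax=axes.iloc[0, j + 1], vmin=lo, vmax=hi,
                       title=f"{rep.source2} c{j + 1}")
        for i in range(k1):
            ftp_render(avg1.profile(f"cluster_{i + 1}"), avg1.grid_n,
                       ax=axes.iloc[i + 1, 0], vmin=lo, vmax=hi,
                       title=f"{rep.source1} c{i + 1}")
            for j in range(k2):
                ax = axes.iloc[i + 1, j + 1]
                ax.axis("off")
                ax.text(0.5, 0.5, str(rep.table.iloc[i, j]),
                        ha="center", va="center", fontsize=14)
        fig.suptitle(f"{rep.source1} vs {rep.source2} ({rep.verdict})")
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return fig

    def plot_gap(self, group: str | None = None, path=None):
        import matplotlib.pyplot as plt

        curve = self.gap_curve(group)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.errorbar(curve["k"], curve["gap"], yerr=curve["se"], marker="o")
        ax.set_xlabel("K")
        ax.set_ylabel("gap")
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return fig


def replace_values(ds: OmicsDataset, sample_ids) -> OmicsDataset:
    """Restrict a dataset to the fitted cohort (post-alignment sample set)."""
    keep = [s for s in sample_ids if s in ds.sample_ids]
    return ds.subset_samples(keep)
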