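"""Run configuration shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Knobs for a full integrative-phenotyping run.

    Attributes
    ----------
    grid_n : int
        Smoothing grid resolution n; profiles have (n+1)^2 points.
    k_max : int
        Largest cluster count scanned by the gap statistic.
    gap_B : int
        Number of uniform reference sets for the gap statistic.
    filter_mean_quantile, filter_sd_quantile : float
        Quantile cutoffs for the low-mean / low-SD feature filters
        (expression-style sources; set 0 for clinical tables).
    homogeneity_max_offdiag : float
        Largest off-diagonal fraction of a cross-tabulation still called
        "homogeneous" when deciding whether to merge two omics sources.
    anova_alpha : float
        Bonferroni-adjusted p cutoff for post-clustering biomarker selection.
    seed : int
        Seed for every stochastic stage (MDS restarts, gap references, ...).
    """

    grid_n: int = 50
    k_max: int = 6
    gap_B: int = 20
    filter_mean_quantile: float = 0.3
    filter_sd_quantile: float = 0.3
    homogeneity_max_offdiag: float = 0.20
    anova_alpha: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_n < 8:
            raise ValueError("grid_n must be >= 8")
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if self.gap_B < 10:
            raise ValueError("gap_B must be >= 10")
        for name in ("filter_mean_quantile", "filter_sd_quantile", "homogeneity_max_offdiag"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
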