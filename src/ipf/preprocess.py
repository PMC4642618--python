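"""Per-omics feature filtering and standardization.

Non-expressed (low mean) and non-informative (low standard deviation)
features are removed before integration; the surviving features are scaled
to zero mean and unit variance so no single source dominates the fused
feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import OmicsDataset


@dataclass
class FilterReport:
    """Audit trail of one filtering pass over an omics source."""

    omics: str
    kept_ids: list[str]
    dropped_low_mean_ids: list[str] = field(default_factory=list)
    dropped_low_sd_ids: list[str] = field(default_factory=list)
    dropped_constant_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(f, "kept") for f in self.kept_ids]
            + [(f, "low_mean") for f in self.dropped_low_mean_ids]
            + [(f, "low_sd") for f in self.dropped_low_sd_ids]
            + [(f, "constant") for f in self.dropped_constant_ids]
        )
        return pd.DataFrame(rows, columns=["feature_id", "status"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_features(
    ds: OmicsDataset, mean_q: float = 0.3, sd_q: float = 0.3
) -> tuple[OmicsDataset, FilterReport]:
    """Drop low-mean then low-SD continuous features; drop constants always.

    The mean filter removes continuous features whose (non-missing) mean lies
    below the ``mean_q`` quantile of all continuous feature means; the SD
    filter then removes those whose SD lies below the ``sd_q`` quantile of
    the remaining SDs.  Non-continuous features are exempt from both quantile
    stages and are removed only if constant.
    """
    if not 0.0 <= mean_q < 1.0 or not 0.0 <= sd_q < 1.0:
        raise ValueError("mean_q and sd_q must lie in [0, 1)")

    vals = ds.values
    means = vals.mean(axis=0, skipna=True)
    sds = vals.std(axis=0, ddof=1, skipna=True)

    constant = set(vals.columns[(sds.fillna(0.0) == 0.0)])
    cont = [f for f in vals.columns
            if ds.var_types[f] == "continuous" and f not in constant]

    low_mean: set[str] = set()
    if cont and mean_q > 0:
        cut = means[cont].quantile(mean_q)
        low_mean = {f for f in cont if means[f] < cut}

    remaining = [f for f in cont if f not in low_mean]
    low_sd: set[str] = set()
    if remaining and sd_q > 0:
        cut = sds[remaining].quantile(sd_q)
        low_sd = {f for f in remaining if sds[f] < cut}

    kept = [f for f in vals.columns
            if f not in constant and f not in low_mean and f not in low_sd]
    if not kept:
        raise ValueError(
            f"{ds.name}: filtering removed every feature; lower mean_q/sd_q"
        )
    report = FilterReport(
        omics=ds.name,
        kept_ids=kept,
        dropped_low_mean_ids=sorted(low_mean),
        dropped_low_sd_ids=sorted(low_sd),
        dropped_constant_ids=sorted(constant),
    )
    return ds.subset_features(kept), report


def standardize(ds: OmicsDataset) -> OmicsDataset:
    """Scale every non-categorical feature to mean 0, SD 1 (sample SD, n-1).

    Statistics are computed over non-missing entries; missing cells stay
    missing.  Categorical features keep their integer level codes — the
    mixed-type correlation, not the matrix, carries type awareness for them.
    """
    vals = ds.values.copy()
    for f in vals.columns:
        if ds.var_types[f] == "categorical":
            continue
        col = vals[f]
        sd = col.std(ddof=1, skipna=True)
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(
                f"{ds.name}: constant feature {f!r}; run filter_features first"
            )
        vals[f] = (col - col.mean(skipna=True)) / sd
    return OmicsDataset(ds.name, vals, ds.var_types.copy())
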