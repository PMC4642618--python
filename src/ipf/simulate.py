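"""Synthetic multi-omics cohorts with known cluster structure.

The generator plants K latent patient clusters and, per omics source, a block
of informative features whose cluster means are separated by a chosen effect
size; the remaining features are pure noise.  Non-continuous variable types
(binary / ordinal / categorical) are produced by thresholding a latent
Gaussian feature at balanced quantile cut-points, which preserves the cluster
signal in discretised form.  Missing cells can be inserted uniformly.  All
randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import OmicsDataset

#: default level counts when discretising a latent Gaussian
_LEVELS = {"binary": 2, "ordinal": 4, "categorical": 3}


@dataclass
class OmicsSpec:
    """Shape of one simulated omics source.

    ``var_type_mix`` maps type tag to the fraction of features carrying it
    (missing mass goes to continuous); ``None`` means all-continuous.
    ``n_informative`` overrides the source-level noise fraction when set.
    """

    n_features: int
    n_informative: int | None = None
    var_type_mix: dict[str, float] | None = None
    name: str | None = None


@dataclass
class SimSpec:
    """Full description of a simulated cohort.

    ``effect_size`` is the separation between adjacent cluster centroids in
    units of ``within_sd`` (the within-cluster standard deviation);
    ``noise_fraction`` is the fraction of features per omics with no cluster
    signal (used when an ``OmicsSpec`` does not pin ``n_informative``).
    """

    n_samples: int = 90
    k_true: int = 3
    omics_specs: list[OmicsSpec] = field(
        default_factory=lambda: [OmicsSpec(n_features=60)]
    )
    effect_size: float = 3.0
    within_sd: float = 1.0
    noise_fraction: float = 0.5
    missing_rate: float = 0.0
    balanced: bool = True
    dirichlet_alpha: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.k_true > self.n_samples:
            raise ValueError("k_true cannot exceed n_samples")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        for os_ in self.omics_specs:
            if os_.n_informative is not None and os_.n_informative > os_.n_features:
                raise ValueError("n_informative cannot exceed n_features")


@dataclass
class SimResult:
    datasets: list[OmicsDataset]
    true_labels: pd.Series  # per-sample cluster id, 1..K
    informative_mask: list[np.ndarray]  # per-omics boolean, feature order
    alt_labels: pd.Series | None = None  # second partition (heterogeneous pairs)


# ----------------------------------------------------------------------
def _draw_labels(n: int, k: int, rng: np.random.Generator, balanced: bool,
                 alpha: float) -> np.ndarray:
    """Cluster ids 1..k for n samples; balanced or Dirichlet-skewed sizes."""
    if balanced:
        labels = np.repeat(np.arange(1, k + 1), int(np.ceil(n / k)))[:n]
    else:
        p = rng.dirichlet(np.full(k, alpha))
        labels = rng.choice(np.arange(1, k + 1), size=n, p=p)
        # every cluster keeps at least one member
        for c in range(1, k + 1):
            if not (labels == c).any():
                labels[rng.integers(n)] = c
    rng.shuffle(labels)
    return labels


def _feature_structure(spec: SimSpec, ospec: OmicsSpec,
                       rng_struct: np.random.Generator) -> dict:
    """Cohort-invariant feature model of one omics source: which features
    are informative, the cluster-to-level assignment of each, the variable
    types, and the categorical code shuffles.  Drawn from the structure RNG
    only, so a test cohort simulated from the same spec shares it."""
    p, k = ospec.n_features, spec.k_true
    n_inf = (ospec.n_informative if ospec.n_informative is not None
             else int(round(p * (1.0 - spec.noise_fraction))))
    mask = np.zeros(p, dtype=bool)
    idx = rng_struct.choice(p, size=n_inf, replace=False)
    mask[idx] = True
    sep = spec.effect_size * spec.within_sd
    # random assignment of clusters to equally spaced, centred levels
    levels = {
        int(j): (rng_struct.permutation(k) - (k - 1) / 2.0) * sep for j in idx
    }
    types = _type_assignment(p, ospec.var_type_mix, rng_struct)
    code_perms = {
        j: rng_struct.permutation(_LEVELS["categorical"])
        for j in range(p)
        if types[j] == "categorical"
    }
    return {"mask": mask, "levels": levels, "types": types,
            "code_perms": code_perms}


def _latent_features(labels: np.ndarray, spec: SimSpec, structure: dict,
                     rng_sample: np.random.Generator) -> np.ndarray:
    """Continuous latent matrix (samples x features) for one cohort."""
    n = len(labels)
    p = len(structure["mask"])
    X = rng_sample.normal(0.0, spec.within_sd, size=(n, p))
    for j, levels in structure["levels"].items():
        X[:, j] += levels[labels - 1]
    return X


def _discretise(x: np.ndarray, n_levels: int,
                code_perm: np.ndarray | None = None) -> np.ndarray:
    """Threshold a latent vector into balanced integer level codes 0..L-1."""
    qs = np.quantile(x, np.linspace(0, 1, n_levels + 1)[1:-1])
    codes = np.searchsorted(qs, x, side="right").astype(float)
    if code_perm is not None:  # destroy ordering for sign-free categoricals
        codes = code_perm[codes.astype(int)].astype(float)
    return codes


def _type_assignment(n_features: int, mix: dict[str, float] | None,
                     rng: np.random.Generator) -> np.ndarray:
    types = np.array(["continuous"] * n_features, dtype=object)
    if not mix:
        return types
    counts = {t: int(round(f * n_features)) for t, f in mix.items() if t != "continuous"}
    order = rng.permutation(n_features)
    pos = 0
    for t, c in counts.items():
        types[order[pos:pos + c]] = t
        pos += c
    return types


def _insert_missing(X: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return X
    mask = rng.random(X.shape) < rate
    # keep at least one observed value per row and per column
    for i in np.flatnonzero(mask.all(axis=1)):
        mask[i, rng.integers(X.shape[1])] = False
    for j in np.flatnonzero(mask.all(axis=0)):
        mask[rng.integers(X.shape[0]), j] = False
    X = X.copy()
    X[mask] = np.nan
    return X


def _build_omics(labels: np.ndarray, spec: SimSpec, structure: dict,
                 sample_ids: list[str], name: str,
                 rng_sample: np.random.Generator
                 ) -> tuple[OmicsDataset, np.ndarray]:
    X = _latent_features(labels, spec, structure, rng_sample)
    types = structure["types"]
    for j in range(X.shape[1]):
        t = types[j]
        if t != "continuous":
            X[:, j] = _discretise(
                X[:, j], _LEVELS[t], structure["code_perms"].get(j)
            )
    X = _insert_missing(X, spec.missing_rate, rng_sample)
    fids = [f"{name}_f{j:04d}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, index=sample_ids, columns=fids)
    ds = OmicsDataset(name, df, pd.Series(types, index=fids))
    return ds, structure["mask"]


def _rngs(spec: SimSpec, cohort: int) -> tuple[np.random.Generator, np.random.Generator]:
    # structure RNG depends on the spec seed only -> shared across cohorts
    return (
        np.random.default_rng(spec.seed),
        np.random.default_rng([spec.seed, cohort]),
    )


def _sample_ids(n: int, cohort: int) -> list[str]:
    prefix = "s" if cohort == 0 else f"c{cohort}s"
    return [f"{prefix}{j:04d}" for j in range(n)]


# ----------------------------------------------------------------------
def simulate(spec: SimSpec, cohort: int = 0, n_samples: int | None = None) -> SimResult:
    """Generate a cohort where every omics source is driven by the same
    latent patient partition.

    ``cohort`` indexes independent cohorts drawn from the same population:
    the feature structure (informative features, cluster-mean assignments,
    variable types) is identical across cohorts of one spec, while cluster
    memberships, noise and missingness are redrawn — the setting of a
    discovery/validation split.
    """
    n = n_samples or spec.n_samples
    rng_struct, rng_sample = _rngs(spec, cohort)
    sample_ids = _sample_ids(n, cohort)
    labels = _draw_labels(n, spec.k_true, rng_sample, spec.balanced,
                          spec.dirichlet_alpha)
    datasets, masks = [], []
    for m, ospec in enumerate(spec.omics_specs):
        name = ospec.name or f"omics{m + 1}"
        structure = _feature_structure(spec, ospec, rng_struct)
        ds, mask = _build_omics(labels, spec, structure, sample_ids, name,
                                rng_sample)
        datasets.append(ds)
        masks.append(mask)
    return SimResult(datasets, pd.Series(labels, index=sample_ids), masks)


def homogeneous_pair(spec: SimSpec, cohort: int = 0) -> SimResult:
    """Two omics sources driven by the same true partition."""
    spec = _as_pair(spec)
    return simulate(spec, cohort=cohort)


def heterogeneous_pair(spec: SimSpec, cohort: int = 0) -> SimResult:
    """Two omics sources driven by independent partitions of the same samples,
    so their cluster solutions cross-tabulate with large off-diagonal mass."""
    spec = _as_pair(spec)
    rng_struct, rng_sample = _rngs(spec, cohort)
    sample_ids = _sample_ids(spec.n_samples, cohort)
    labels1 = _draw_labels(spec.n_samples, spec.k_true, rng_sample,
                           spec.balanced, spec.dirichlet_alpha)
    labels2 = _draw_labels(spec.n_samples, spec.k_true, rng_sample,
                           spec.balanced, spec.dirichlet_alpha)
    datasets, masks = [], []
    for m, (ospec, lab) in enumerate(zip(spec.omics_specs, (labels1, labels2))):
        name = ospec.name or f"omics{m + 1}"
        structure = _feature_structure(spec, ospec, rng_struct)
        ds, mask = _build_omics(lab, spec, structure, sample_ids, name,
                                rng_sample)
        datasets.append(ds)
        masks.append(mask)
    return SimResult(datasets, pd.Series(labels1, index=sample_ids), masks,
                     alt_labels=pd.Series(labels2, index=sample_ids))


def _as_pair(spec: SimSpec) -> SimSpec:
    if len(spec.omics_specs) == 2:
        return spec
    if len(spec.omics_specs) == 1:
        o = spec.omics_specs[0]
        return replace(spec, omics_specs=[replace(o, name=None), replace(o, name=None)])
    raise ValueError("pair generators need 1 or 2 omics specs")
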