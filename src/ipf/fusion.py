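"""Feature fusion: concatenation, mixed-type dissimilarity, 2D non-metric
MDS embedding of features, and per-patient surface smoothing.

This is the heart of the framework.  Features from all omics sources are
stacked into one set, a correlation-based dissimilarity ``D = (1 - R) / 2``
is computed between every pair of features (with a type-aware choice of
correlation), non-metric MDS places the features in the unit square so that
correlated features co-locate, and each patient's intensities are smoothed
over that map with a thin-plate spline to yield a fixed-length profile
vector — the numeric content of a feature topology plot (FTP).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.spatial.distance import cdist
from scipy.stats import chi2_contingency, pearsonr, spearmanr
from sklearn.manifold import MDS

from .datasets import OmicsDataset

logger = logging.getLogger("ipf")

MIN_COMPLETE_PAIRS = 3


# ======================================================================
# concatenation
# ======================================================================
@dataclass
class ConcatenatedFeatures:
    """Vertically stacked features from all sources.

    ``matrix`` is features x samples; ``origin`` maps each feature to the
    label of the omics source it came from.
    """

    matrix: pd.DataFrame
    origin: pd.Series
    var_types: pd.Series

    @property
    def feature_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    def split_by_origin(self) -> dict[str, pd.DataFrame]:
        return {
            src: self.matrix.loc[self.origin == src]
            for src in self.origin.unique()
        }


def concatenate(datasets: list[OmicsDataset]) -> ConcatenatedFeatures:
    """Stack sample-aligned datasets feature-wise (rows = features)."""
    if not datasets:
        raise ValueError("no datasets to concatenate")
    ref = datasets[0].sample_ids
    for ds in datasets[1:]:
        if ds.sample_ids != ref:
            raise ValueError(
                f"datasets are not sample-aligned ({ds.name}); run align_samples"
            )
    blocks, origins, types = [], [], []
    for ds in datasets:
        blocks.append(ds.values.T)
        origins.append(pd.Series(ds.name, index=ds.feature_ids))
        types.append(ds.var_types)
    matrix = pd.concat(blocks, axis=0)
    if matrix.index.has_duplicates:
        dups = sorted(matrix.index[matrix.index.duplicated()].unique())
        raise ValueError(f"duplicate feature ids across sources: {dups[:10]}")
    return ConcatenatedFeatures(matrix, pd.concat(origins), pd.concat(types))


# ======================================================================
# mixed-type correlation and dissimilarity
# ======================================================================
def _cramers_v(x: np.ndarray, y: np.ndarray) -> float:
    """Cramer's V association in [0, 1] from a contingency table."""
    table = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    n = table.sum()
    chi2 = chi2_contingency(table, correction=False).statistic
    denom = n * (min(table.shape) - 1)
    return float(np.sqrt(chi2 / denom)) if denom > 0 else 0.0


def _bin_continuous(x: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Quartile-bin a continuous partner for contingency-based association."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="right").astype(float)


def mixed_correlation(x: np.ndarray, y: np.ndarray, tx: str, ty: str) -> float:
    """Correlation between two feature vectors, dispatched on variable type.

    continuous-continuous -> Pearson; any pair involving an ordinal ->
    Spearman; binary-continuous -> point-biserial (Pearson on the 0/1
    coding); binary-binary -> phi; any pair involving a categorical ->
    Cramer's V (non-negative, used as-is).  Only pairwise-complete
    observations enter; fewer than 3 complete pairs, or a constant member,
    gives 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < MIN_COMPLETE_PAIRS:
        warnings.warn("fewer than 3 complete pairs; correlation set to 0")
        return 0.0
    if "categorical" in (tx, ty):
        xv = x if tx != "continuous" else _bin_continuous(x)
        yv = y if ty != "continuous" else _bin_continuous(y)
        return _cramers_v(xv, yv)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant feature in pair; correlation set to 0")
        return 0.0
    if "ordinal" in (tx, ty):
        r = spearmanr(x, y).statistic
    else:  # Pearson covers continuous, point-biserial and phi
        r = pearsonr(x, y).statistic
    return float(r) if np.isfinite(r) else 0.0


def correlation_matrix(concat: ConcatenatedFeatures) -> pd.DataFrame:
    """Type-aware feature-feature correlation matrix R in [-1, 1].

    Pearson and Spearman blocks are computed with pairwise-complete pandas
    correlations; pairs involving a categorical feature fall back to a
    Cramer's V loop.  Undefined entries (constant features, too few complete
    pairs) are set to 0 — the neutral midpoint of the dissimilarity scale —
    so the matrix stays complete for MDS.
    """
    df = concat.matrix.T  # samples x features
    types = concat.var_types
    p = df.shape[1]

    pear = df.corr(method="pearson", min_periods=MIN_COMPLETE_PAIRS).to_numpy()
    is_ord = (types == "ordinal").to_numpy()
    is_cat = (types == "categorical").to_numpy()

    R = pear
    if is_ord.any():
        spear = df.corr(method="spearman", min_periods=MIN_COMPLETE_PAIRS).to_numpy()
        use_sp = (is_ord[:, None] | is_ord[None, :]) & ~(
            is_cat[:, None] | is_cat[None, :]
        )
        R = np.where(use_sp, spear, R)

    if is_cat.any():
        cat_idx = np.flatnonzero(is_cat)
        X = df.to_numpy()
        for i in cat_idx:
            for j in range(p):
                if j == i:
                    continue
                xi, xj = X[:, i], X[:, j]
                ok = ~(np.isnan(xi) | np.isnan(xj))
                if ok.sum() < MIN_COMPLETE_PAIRS:
                    R[i, j] = R[j, i] = 0.0
                    continue
                yj = xj[ok] if types.iloc[j] != "continuous" else _bin_continuous(xj[ok])
                v = _cramers_v(xi[ok], yj)
                R[i, j] = R[j, i] = v

    n_undef = int(np.isnan(R).sum())
    if n_undef:
        warnings.warn(
            f"{n_undef} undefined correlation entries set to 0 "
            "(constant features or too few complete pairs)"
        )
        R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    return pd.DataFrame(R, index=df.columns, columns=df.columns)


@dataclass
class FeatureDissimilarity:
    """D = (1 - R) / 2 with the underlying correlation matrix kept for audit."""

    D: pd.DataFrame
    R: pd.DataFrame

    def validate(self) -> None:
        d = self.D.to_numpy()
        assert np.allclose(d, d.T, atol=1e-12), "D must be symmetric"
        assert np.allclose(np.diag(d), 0.0), "D diagonal must be 0"
        assert d.min() >= -1e-12 and d.max() <= 1.0 + 1e-12, "D entries in [0,1]"


def dissimilarity(R: pd.DataFrame) -> FeatureDissimilarity:
    """Map correlations to distances: identical features at 0, perfectly
    anti-correlated ones at 1, uncorrelated ones at the 0.5 midpoint."""
    arr = R.to_numpy(dtype=float)
    if np.nanmax(np.abs(arr)) > 1.0 + 1e-9:
        raise ValueError("correlation entries must lie in [-1, 1]")
    if not np.allclose(arr, arr.T, atol=1e-9):
        raise ValueError("correlation matrix must be symmetric")
    D = (1.0 - arr) / 2.0
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, 1.0)
    out = FeatureDissimilarity(
        pd.DataFrame(D, index=R.index, columns=R.columns), R.copy()
    )
    out.validate()
    return out


# ======================================================================
# non-metric MDS embedding
# ======================================================================
@dataclass
class FeatureEmbedding:
    """2D feature coordinates, min-max rescaled to the unit square.

    ``coords_raw`` keeps the unscaled stress-minimising configuration: the
    per-axis rescaling that maps the layout onto the unit square is not an
    isometry, so geometric checks (and any distance-based reasoning about
    the configuration itself) should use the raw coordinates.
    """

    coords: pd.DataFrame  # index = feature id, columns = (u1, u2)
    stress: float
    coords_raw: np.ndarray | None = None

    @property
    def feature_ids(self) -> list[str]:
        return list(self.coords.index)


def _classical_mds_init(D: np.ndarray) -> np.ndarray:
    """Deterministic torgerson (classical) MDS used to initialise the
    non-metric stress minimisation."""
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:2]
    lam = np.clip(w[order], 0.0, None)
    X = V[:, order] * np.sqrt(lam)
    if X.shape[1] < 2:
        X = np.hstack([X, np.zeros((n, 2 - X.shape[1]))])
    # fix eigenvector sign for reproducibility
    for a in range(2):
        j = int(np.argmax(np.abs(X[:, a])))
        if X[j, a] < 0:
            X[:, a] = -X[:, a]
    return X


def _rescale_unit_square(X: np.ndarray) -> np.ndarray:
    out = np.empty_like(X)
    for a in range(X.shape[1]):
        lo, hi = X[:, a].min(), X[:, a].max()
        out[:, a] = 0.5 if hi == lo else (X[:, a] - lo) / (hi - lo)
    return out


def embed(
    dissim: FeatureDissimilarity,
    seed: int = 0,
    max_iter: int = 300,
    eps: float = 1e-6,
) -> FeatureEmbedding:
    """Non-metric (Kruskal stress) MDS of the feature dissimilarities to 2D.

    The optimisation minimises stress over monotone transforms of D, so only
    the rank order of feature dissimilarities matters.  A classical-MDS
    start makes the result deterministic for a given seed; coordinates are
    rescaled so each axis spans [0, 1].
    """
    D = dissim.D.to_numpy(dtype=float)
    n = D.shape[0]
    if n < 3:
        coords = np.linspace(0.0, 1.0, n)[:, None].repeat(2, axis=1)
        return FeatureEmbedding(
            pd.DataFrame(coords, index=dissim.D.index, columns=["u1", "u2"]),
            0.0,
            coords.copy(),
        )
    init = _classical_mds_init(D)
    mds = MDS(
        n_components=2,
        metric=False,
        dissimilarity="precomputed",
        n_init=1,
        max_iter=max_iter,
        eps=eps,
        random_state=seed,
        normalized_stress=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        X = mds.fit_transform(D, init=init)
    stress = float(mds.stress_)
    if not np.isfinite(X).all():
        raise RuntimeError("MDS produced non-finite coordinates")
    raw = X.copy()
    X = _rescale_unit_square(X)
    return FeatureEmbedding(
        pd.DataFrame(X, index=dissim.D.index, columns=["u1", "u2"]), stress, raw
    )


# ======================================================================
# thin-plate spline smoothing of per-patient intensities
# ======================================================================
def _tps_eta(r: np.ndarray) -> np.ndarray:
    """2D thin-plate radial basis r^2 log r, with eta(0) = 0."""
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz])
    return out


def _farthest_point_knots(coords: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point subset of the feature locations."""
    uniq = np.unique(coords, axis=0)
    if len(uniq) <= k:
        return uniq
    chosen = [0]
    d = np.linalg.norm(uniq - uniq[0], axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(uniq - uniq[nxt], axis=1))
    return uniq[np.sort(chosen)]


class ThinPlateSmoother:
    """Penalised thin-plate regression spline on 2D coordinates.

    A knot-based basis (radial terms at up to ``n_knots`` farthest-point
    knots plus an unpenalised linear polynomial) is fitted by penalised
    least squares; the smoothing parameter is chosen per response column by
    generalized cross-validation over a log-spaced grid.  The polynomial
    null space guarantees exact reproduction of constant and linear
    surfaces at any penalty.
    """

    def __init__(
        self,
        coords: np.ndarray,
        n_knots: int = 60,
        lambdas: np.ndarray | None = None,
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        p = coords.shape[0]
        k = min(n_knots, max(4, p // 2))
        if k < 4:
            warnings.warn("very few features; reducing thin-plate basis")
            k = 4
        self.knots = _farthest_point_knots(coords, k)
        k = len(self.knots)
        E = _tps_eta(cdist(self.knots, self.knots))
        Tk = np.column_stack([np.ones(k), self.knots])
        self.Z = null_space(Tk.T)  # (k, k-3); radial coeffs orthogonal to poly
        self.penalty = self.Z.T @ E @ self.Z
        q = self.Z.shape[1] + 3
        self.penalty_full = np.zeros((q, q))
        self.penalty_full[: self.Z.shape[1], : self.Z.shape[1]] = self.penalty
        self.lambdas = (
            np.logspace(-6, 4, 15) if lambdas is None else np.asarray(lambdas)
        )
        self.coords = coords
        self._B = self.basis(coords)

    def basis(self, pts: np.ndarray) -> np.ndarray:
        rad = _tps_eta(cdist(pts, self.knots)) @ self.Z
        poly = np.column_stack([np.ones(len(pts)), pts])
        return np.hstack([rad, poly])

    def fit(self, Y: np.ndarray) -> "TPSFit":
        """Fit one column per response; Y is (n_points, n_responses)."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] != self._B.shape[0]:
            Y = Y.T
        B = self._B
        n, q = B.shape
        BtB = B.T @ B
        BtY = B.T @ Y
        best_gcv = np.full(Y.shape[1], np.inf)
        best_coef = np.zeros((q, Y.shape[1]))
        best_lam = np.zeros(Y.shape[1])
        for lam in self.lambdas:
            A = BtB + lam * self.penalty_full
            try:
                coef = np.linalg.solve(A, BtY)
                Ainv_BtB = np.linalg.solve(A, BtB)
            except np.linalg.LinAlgError:
                coef, *_ = np.linalg.lstsq(A, BtY, rcond=None)
                Ainv_BtB, *_ = np.linalg.lstsq(A, BtB, rcond=None)
            edf = float(np.trace(Ainv_BtB))
            resid = Y - B @ coef
            rss = (resid ** 2).sum(axis=0)
            denom = max(n - edf, 1e-8) ** 2
            gcv = n * rss / denom
            better = gcv < best_gcv
            best_gcv = np.where(better, gcv, best_gcv)
            best_lam = np.where(better, lam, best_lam)
            best_coef[:, better] = coef[:, better]
        return TPSFit(self, best_coef, best_lam, best_gcv)


@dataclass
class TPSFit:
    smoother: ThinPlateSmoother
    coef: np.ndarray
    lambdas: np.ndarray
    gcv: np.ndarray

    def predict(self, pts: np.ndarray) -> np.ndarray:
        """Evaluate the fitted surfaces at (m, 2) points -> (m, n_responses)."""
        return self.smoother.basis(np.asarray(pts, dtype=float)) @ self.coef


def unit_grid(grid_n: int) -> np.ndarray:
    """(grid_n+1)^2 x 2 grid points (s/n, t/n), row-major in s then t."""
    ticks = np.arange(grid_n + 1) / grid_n
    s, t = np.meshgrid(ticks, ticks, indexing="ij")
    return np.column_stack([s.ravel(), t.ravel()])


@dataclass
class SmoothedProfiles:
    """Per-patient smoothed intensity vectors on the (n+1)^2 unit-square grid.

    Row j of ``values`` is patient j's profile c_j — the numeric content of
    that patient's feature topology plot for the given source.
    """

    values: pd.DataFrame  # samples x (grid_n+1)^2
    grid_n: int
    source: str

    def __post_init__(self) -> None:
        expected = (self.grid_n + 1) ** 2
        if self.values.shape[1] != expected:
            raise ValueError(
                f"profile length {self.values.shape[1]} != (n+1)^2 = {expected}"
            )
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("profiles contain non-finite values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def profile(self, patient_id: str) -> np.ndarray:
        return self.values.loc[patient_id].to_numpy()

    def as_image(self, patient_id: str) -> np.ndarray:
        n = self.grid_n + 1
        return self.profile(patient_id).reshape(n, n)

    def write(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")


def smooth_patients(
    embedding: FeatureEmbedding,
    values: pd.DataFrame,
    grid_n: int = 50,
    source: str = "",
    n_knots: int = 60,
) -> SmoothedProfiles:
    """Smooth every patient's feature intensities over the 2D embedding.

    ``values`` is samples x features (standardized); its features must all
    carry embedding coordinates.  Features missing for a given patient are
    excluded from that patient's fit.  Returns the (grid_n+1)^2-point
    profile per patient.
    """
    feats = list(values.columns)
    missing = [f for f in feats if f not in embedding.coords.index]
    if missing:
        raise ValueError(f"features without embedding coordinates: {missing[:5]}")
    coords = embedding.coords.loc[feats].to_numpy()
    Y = values.to_numpy(dtype=float).T  # features x samples
    grid = unit_grid(grid_n)

    nan_mask = np.isnan(Y)
    if not nan_mask.any():
        smoother = ThinPlateSmoother(coords, n_knots=n_knots)
        G = smoother.fit(Y).predict(grid)  # grid-points x samples
        out = G.T
    else:
        if nan_mask.all(axis=0).any():
            bad = [s for s, m in zip(values.index, nan_mask.all(axis=0)) if m]
            raise ValueError(f"all-missing patients: {bad}")
        out = np.empty((Y.shape[1], grid.shape[0]))
        # batch patients sharing a missingness pattern: one basis per pattern
        patterns: dict[bytes, list[int]] = {}
        for j in range(Y.shape[1]):
            patterns.setdefault(nan_mask[:, j].tobytes(), []).append(j)
        for key, cols in patterns.items():
            keep = ~np.frombuffer(key, dtype=bool)
            smoother = ThinPlateSmoother(coords[keep], n_knots=n_knots)
            G = smoother.fit(Y[np.ix_(keep, cols)]).predict(grid)
            out[cols] = G.T
    return SmoothedProfiles(
        pd.DataFrame(out, index=values.index), grid_n, source
    )


# ======================================================================
# feature topology plot rendering
# ======================================================================
def ftp_render(
    profile: np.ndarray,
    grid_n: int,
    ax=None,
    vmin: float | None = None,
    vmax: float | None = None,
    title: str = "",
    levels: int = 30,
):
    """Filled-contour feature topology plot on the unit square.

    High intensities render red, intermediate yellow, low blue.  Pass a
    shared (vmin, vmax) when several plots must be comparable.
    """
    import matplotlib.pyplot as plt

    img = np.asarray(profile, dtype=float).reshape(grid_n + 1, grid_n + 1)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    vmin = float(img.min()) if vmin is None else vmin
    vmax = float(img.max()) if vmax is None else vmax
    if vmax <= vmin:  # constant profile
        vmax = vmin + 1e-9
    ticks = np.arange(grid_n + 1) / grid_n
    cs = ax.contourf(
        ticks,
        ticks,
        img.T,  # img[s, t] at (u1=s/n, u2=t/n): u1 on x-axis
        levels=np.linspace(vmin, vmax, levels),
        cmap="RdYlBu_r",
        extend="both",
    )
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title, fontsize=9)
    return cs
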