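"""Space-for-time substitution (SFT) diagnostic via m-out-of-n bootstrap.

A Random-Forest regressor trained on *spatial* MBC observations is used to
predict *temporal* change in global MBC over 1992–2013 under a warming
trend.  If MBC declines with temperature across space, the model predicts
a temporal decline even when the true temporal sensitivity is zero — the
space-for-time artifact.  The diagnostic:

repeat ``reps`` times (m rows drawn with replacement from the n
observations): fit a Random Forest on the subsample; compute the
subsample's univariate spatial MBC–temperature slope; restrict the
prediction grid to cells within the model's area of applicability
(Mahalanobis-distance or dissimilarity-index mask); predict annual global
MBC totals for 1992–2013 and summarize them as a change rate (% yr^-1).
A positive correlation between per-replicate change rate and spatial slope
across replicates indicates that the predicted temporal trend is inherited
from the spatial gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestRegressor

from .simulate import CONTINUOUS_PREDICTORS, LAND_COVER_CLASSES, WorldGrid

FEATURE_NAMES = list(CONTINUOUS_PREDICTORS) + [f"lc_{c}" for c in LAND_COVER_CLASSES]


def encode_predictors(df: pd.DataFrame) -> np.ndarray:
    """Design matrix with land cover one-hot encoded against the fixed
    global class list, so subsamples missing a class remain alignable."""
    X = df[list(CONTINUOUS_PREDICTORS)].to_numpy(dtype=float)
    lc = np.asarray(df["land_cover"].astype(str))
    dummies = np.column_stack([(lc == c).astype(float) for c in LAND_COVER_CLASSES])
    return np.column_stack([X, dummies])


def spatial_slope(sample: pd.DataFrame) -> float:
    """Univariate OLS slope of MBC on annual temperature across sites."""
    if len(sample) < 3:
        raise ValueError("spatial slope needs >= 3 observations")
    t = sample["temperature"].to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("temperature constant across sample: slope undefined")
    return float(stats.linregress(t, sample["mbc"].to_numpy(dtype=float)).slope)


class RandomForestMBC:
    """Random-Forest regression of MBC on the ten environmental predictors.

    Thin deterministic wrapper around scikit-learn: fixed feature encoding,
    ``n_trees`` trees, one third of the features considered per split,
    unlimited depth, single-threaded so results are bit-reproducible for a
    given seed.
    """

    def __init__(self, n_trees: int = 500, max_features: float = 1 / 3, seed: int = 0):
        self.model = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=int(seed) % (2**31),
            n_jobs=1,
            bootstrap=True,
        )
        self._fitted = False

    def fit(self, train: pd.DataFrame) -> "RandomForestMBC":
        X = encode_predictors(train)
        self.model.fit(X, train["mbc"].to_numpy(dtype=float))
        self._fitted = True
        return self

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("model not fitted")
        return self.model.predict(encode_predictors(df))

    def predict_encoded(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("model not fitted")
        return self.model.predict(X)

    @property
    def continuous_importances(self) -> np.ndarray:
        """Impurity importances of the nine continuous predictors
        (land-cover dummies excluded), renormalized to sum to one."""
        imp = self.model.feature_importances_[: len(CONTINUOUS_PREDICTORS)]
        s = imp.sum()
        return imp / s if s > 0 else np.full(len(imp), 1.0 / len(imp))


def fit_mbc_model(train: pd.DataFrame, seed: int = 0, **kw) -> RandomForestMBC:
    """Convenience constructor+fit (see :class:`RandomForestMBC`)."""
    return RandomForestMBC(seed=seed, **kw).fit(train)


def predict_global_series(
    model: RandomForestMBC, grid: WorldGrid, mask: np.ndarray | None = None
) -> np.ndarray:
    """Area-weighted global MBC total per year over the valid cells.

    Invalid cells are excluded from every year equally, so the series is
    comparable across years.
    """
    if mask is None:
        mask = np.ones(grid.n_cells, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("coverage mask is empty: no valid cells to predict")
    # stack the 22 annual predictor matrices and predict in one call
    blocks = [encode_predictors(grid.predictors_for_year(int(y)))[mask] for y in grid.years]
    X = np.vstack(blocks)
    pred = model.predict_encoded(X).reshape(len(grid.years), -1)
    return pred @ grid.area[mask]


def change_rate(
    totals: np.ndarray,
    years: np.ndarray | None = None,
    denominator: str = "period_mean",
) -> tuple[float, float]:
    """Linear trend of global MBC expressed as % yr^-1.

    OLS slope of total vs year, divided by the period-mean total (or the
    initial-year total with ``denominator='initial'``), times 100.  Returns
    ``(rate, se_rate)`` with the SE propagated from the year-trend fit.
    """
    totals = np.asarray(totals, dtype=float)
    if years is None:
        years = np.arange(len(totals))
    if not np.all(np.isfinite(totals)):
        raise ValueError("totals must be finite")
    res = stats.linregress(np.asarray(years, dtype=float), totals)
    denom = float(np.mean(totals)) if denominator == "period_mean" else float(totals[0])
    if denom == 0:
        raise ValueError("zero mean total: change rate undefined")
    return 100.0 * res.slope / denom, 100.0 * res.stderr / abs(denom)


# ---------------------------------------------------------------------------
# area-of-applicability masks


def _continuous_matrix(df: pd.DataFrame) -> np.ndarray:
    return df[list(CONTINUOUS_PREDICTORS)].to_numpy(dtype=float)


def coverage_mask_mahalanobis(
    train: pd.DataFrame, grid_predictors: pd.DataFrame, quantile: float = 0.975
) -> np.ndarray:
    """Cells within the chi-square ``quantile`` Mahalanobis ellipsoid of the
    training predictor cloud (continuous predictors only).

    The training covariance is ridge-regularized if ill-conditioned.
    """
    Xt = _continuous_matrix(train)
    Xg = _continuous_matrix(grid_predictors)
    mu = Xt.mean(axis=0)
    cov = np.cov(Xt, rowvar=False)
    eps = 1e-8 * np.trace(cov) / cov.shape[0]
    for _ in range(8):
        try:
            cinv = np.linalg.inv(cov)
            break
        except np.linalg.LinAlgError:
            cov = cov + eps * np.eye(cov.shape[0])
            eps *= 10
    else:
        raise np.linalg.LinAlgError("training covariance singular even after regularization")
    d = Xg - mu
    d2 = np.einsum("ij,jk,ik->i", d, cinv, d)
    return d2 <= stats.chi2.ppf(quantile, df=Xt.shape[1])


def dissimilarity_index(
    train: pd.DataFrame,
    grid_predictors: pd.DataFrame,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Per-cell dissimilarity index and the training-derived threshold.

    DI = (distance to the nearest training point in standardized,
    importance-weighted predictor space) / (mean pairwise training
    distance).  The threshold is the upper whisker (Q3 + 1.5 IQR) of the
    training points' leave-one-out DI.
    """
    Xt = _continuous_matrix(train)
    if len(Xt) < 2:
        raise ValueError("dissimilarity index needs >= 2 training points")
    sd = Xt.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    w = np.ones(Xt.shape[1]) if weights is None else np.asarray(weights, dtype=float)
    Zt = (Xt - Xt.mean(axis=0)) / sd * w
    Zg = (_continuous_matrix(grid_predictors) - Xt.mean(axis=0)) / sd * w

    pair = cdist(Zt, Zt)
    mean_pair = float(pair[np.triu_indices(len(Zt), k=1)].mean())
    if mean_pair == 0:
        raise ValueError("degenerate training set: all points coincide")
    np.fill_diagonal(pair, np.inf)
    di_train = pair.min(axis=1) / mean_pair
    q1, q3 = np.percentile(di_train, [25, 75])
    threshold = float(q3 + 1.5 * (q3 - q1))

    di_grid = cdist(Zg, Zt).min(axis=1) / mean_pair
    return di_grid, threshold


def coverage_mask_dissimilarity(
    train: pd.DataFrame,
    grid_predictors: pd.DataFrame,
    weights: np.ndarray | None = None,
    threshold: float | None = None,
) -> np.ndarray:
    """Cells whose dissimilarity index is within the training threshold."""
    di, thr = dissimilarity_index(train, grid_predictors, weights=weights)
    return di <= (threshold if threshold is not None else thr)


# ---------------------------------------------------------------------------
# the bootstrap diagnostic


@dataclass
class SFTResults:
    """Across-replicate summary of the space-for-time diagnostic."""

    per_rep: pd.DataFrame           # rep_id, spatial_slope, change_rate, change_rate_se, coverage_fraction, n_unique
    mean_change_rate: float         # % yr^-1
    ci_low: float
    ci_high: float
    pearson_r: float
    r_p_value: float
    n_failed: int
    config: dict = field(default_factory=dict)

    @property
    def reps(self) -> int:
        return len(self.per_rep)

    def summary(self) -> str:
        lines = [
            "Space-for-time bootstrap diagnostic",
            f"  replicates             : {self.reps} (failed: {self.n_failed})",
            f"  mean change rate       : {self.mean_change_rate: .4f} % yr^-1",
            f"  95% CI (across reps)   : [{self.ci_low: .4f}, {self.ci_high: .4f}]",
            f"  corr(rate, slope)      : r = {self.pearson_r:.3f}, p = {self.r_p_value:.3g}",
            f"  mean spatial slope     : {self.per_rep['spatial_slope'].mean(): .3f} mmol kg^-1 K^-1",
            f"  mean coverage fraction : {self.per_rep['coverage_fraction'].mean():.3f}",
        ]
        return "\n".join(lines)


class SFTBootstrap:
    """m-out-of-n bootstrap of Random-Forest global MBC predictions.

    Parameters
    ----------
    data
        Spatial observation table (``mbc`` plus the ten predictors).
    grid
        :class:`~mbcwarm.simulate.WorldGrid` with 22 annual layers.
    m, reps
        Subsample size (drawn with replacement) and number of replicates
        (defaults 500 and 200, the published protocol for n = 762).
    mask_method
        ``'mahalanobis'``, ``'dissimilarity'`` or ``'none'``.
    shared_mask
        If True, predictions use the single layer of cells valid in *every*
        replicate's mask instead of per-replicate masks.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        grid: WorldGrid,
        m: int = 500,
        reps: int = 200,
        mask_method: str = "mahalanobis",
        shared_mask: bool = False,
        n_trees: int = 500,
        max_features: float = 1 / 3,
        mahalanobis_quantile: float = 0.975,
        rate_denominator: str = "period_mean",
    ):
        if reps < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        if m > 10 * len(data):
            raise ValueError("subsample size m implausibly larger than the dataset")
        if mask_method not in ("mahalanobis", "dissimilarity", "none"):
            raise ValueError(f"unknown mask_method {mask_method!r}")
        self.data = data.reset_index(drop=True)
        self.grid = grid
        self.m = int(m)
        self.reps = int(reps)
        self.mask_method = mask_method
        self.shared_mask = shared_mask
        self.n_trees = n_trees
        self.max_features = max_features
        self.mahalanobis_quantile = mahalanobis_quantile
        self.rate_denominator = rate_denominator

    def _rep_mask(self, sample: pd.DataFrame, model: RandomForestMBC) -> np.ndarray:
        base = self.grid.predictors_for_year(int(self.grid.years[0]))
        if self.mask_method == "mahalanobis":
            return coverage_mask_mahalanobis(sample, base, self.mahalanobis_quantile)
        if self.mask_method == "dissimilarity":
            return coverage_mask_dissimilarity(sample, base, weights=model.continuous_importances)
        return np.ones(self.grid.n_cells, dtype=bool)

    def fit(self, seed: int = 0) -> SFTResults:
        """Run the bootstrap; deterministic given ``seed``."""
        ss = np.random.SeedSequence(seed)
        rep_seeds = ss.spawn(self.reps)
        n = len(self.data)

        rows, masks, models, samples = [], [], [], []
        failures = 0
        for rep, rs in enumerate(rep_seeds):
            rng = np.random.default_rng(rs)
            idx = rng.integers(0, n, size=self.m)
            sample = self.data.iloc[idx].reset_index(drop=True)
            try:
                slope = spatial_slope(sample)
                model = fit_mbc_model(
                    sample,
                    seed=int(rng.integers(2**31)),
                    n_trees=self.n_trees,
                    max_features=self.max_features,
                )
                mask = self._rep_mask(sample, model)
            except (ValueError, np.linalg.LinAlgError):
                failures += 1
                continue
            rows.append(
                dict(rep_id=rep, spatial_slope=slope, n_unique=len(np.unique(idx)))
            )
            masks.append(mask)
            models.append(model)
            samples.append(sample)

        if self.shared_mask:
            shared = np.logical_and.reduce(masks) if masks else None
            if shared is None or not shared.any():
                raise ValueError("shared coverage mask is empty across replicates")
            masks = [shared] * len(masks)

        for row, model, mask in zip(rows, models, masks):
            totals = predict_global_series(model, self.grid, mask)
            rate, rate_se = change_rate(totals, self.grid.years, self.rate_denominator)
            row["change_rate"] = rate
            row["change_rate_se"] = rate_se
            row["coverage_fraction"] = float(mask.mean())

        per_rep = pd.DataFrame(rows)
        rates = per_rep["change_rate"].to_numpy()
        mean = float(rates.mean())
        half = 1.96 * rates.std(ddof=1) / np.sqrt(len(rates))
        r, p = stats.pearsonr(rates, per_rep["spatial_slope"].to_numpy())
        return SFTResults(
            per_rep=per_rep,
            mean_change_rate=mean,
            ci_low=mean - half,
            ci_high=mean + half,
            pearson_r=float(r),
            r_p_value=float(p),
            n_failed=failures,
            config=dict(
                m=self.m,
                reps=self.reps,
                mask_method=self.mask_method,
                shared_mask=self.shared_mask,
                n_trees=self.n_trees,
                max_features=self.max_features,
                mahalanobis_quantile=self.mahalanobis_quantile,
                rate_denominator=self.rate_denominator,
                seed=seed,
            ),
        )
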