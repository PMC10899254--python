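"""Effect sizes and random-effects pooling for paired warming experiments.

The effect metric is the natural-log response ratio

    LN(RR) = ln(MBC_warmed) - ln(MBC_control),

with delta-method sampling variance ``sd_w^2/(n_w m_w^2) + sd_c^2/(n_c m_c^2)``
when per-arm dispersion is reported.  Pooling uses the DerSimonian–Laird
moment estimator of the between-study variance tau^2; subgroup pooling
splits the studies into warming-magnitude (or duration) bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .simulate import default_bin_labels

Z975 = 1.959963984540054  # normal 97.5% quantile


def log_response_ratio(records: pd.DataFrame) -> pd.DataFrame:
    """Compute LN(RR) effect sizes for a table of paired measurements.

    Parameters
    ----------
    records
        One row per control/warming pair with columns ``mbc_warmed``,
        ``mbc_control`` and, optionally, ``sd_warmed``, ``sd_control``,
        ``n_warmed``, ``n_control``.  Other columns are carried through.

    Returns
    -------
    DataFrame with ``yi`` (LN(RR)) and ``vi`` (sampling variance; NaN where
    dispersion is unreported).

    Raises
    ------
    ValueError
        If any MBC value is nonpositive (the log ratio is undefined).
    """
    mw = records["mbc_warmed"].to_numpy(dtype=float)
    mc = records["mbc_control"].to_numpy(dtype=float)
    bad = (mw <= 0) | (mc <= 0)
    if bad.any():
        which = records.index[bad].tolist()
        raise ValueError(f"nonpositive MBC in records {which}: log response ratio undefined")
    out = records.copy()
    out["yi"] = np.log(mw) - np.log(mc)
    vi = np.full(len(out), np.nan)
    have = all(c in records.columns for c in ("sd_warmed", "sd_control", "n_warmed", "n_control"))
    if have:
        sw = records["sd_warmed"].to_numpy(dtype=float)
        sc = records["sd_control"].to_numpy(dtype=float)
        nw = records["n_warmed"].to_numpy(dtype=float)
        nc = records["n_control"].to_numpy(dtype=float)
        ok = np.isfinite(sw) & np.isfinite(sc) & (nw > 0) & (nc > 0)
        if np.any(sw[ok] < 0) or np.any(sc[ok] < 0):
            raise ValueError("negative SD encountered")
        vi[ok] = sw[ok] ** 2 / (nw[ok] * mw[ok] ** 2) + sc[ok] ** 2 / (nc[ok] * mc[ok] ** 2)
    out["vi"] = vi
    return out


@dataclass
class MetaResults:
    """Pooled random-effects estimate for one set of studies."""

    k: int
    mu: float
    se_mu: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    I2: float
    p_value: float
    method: str = "DL"

    @property
    def significant_decrease(self) -> bool:
        """Warming 'significantly decreased' MBC: the whole 95% CI is below 0."""
        return self.ci_high < 0

    def summary(self) -> str:
        lines = [
            "Random-effects meta-analysis (DerSimonian-Laird)"
            if self.method == "DL"
            else f"Random-effects meta-analysis ({self.method})",
            f"  k studies        : {self.k}",
            f"  pooled LN(RR)    : {self.mu: .4f}  (SE {self.se_mu:.4f})",
            f"  95% CI           : [{self.ci_low: .4f}, {self.ci_high: .4f}]",
            f"  tau^2            : {self.tau2:.5f}",
            f"  Q (heterogeneity): {self.Q:.3f}   I^2: {self.I2:.1f}%",
            f"  p (mu = 0)       : {self.p_value:.4g}",
        ]
        return "\n".join(lines)


class RandomEffectsMeta:
    """Random-effects meta-analysis model for LN(RR) effect sizes.

    Parameters
    ----------
    yi
        Effect sizes.
    vi
        Sampling variances.  May be ``None``/NaN for some or all studies:
        partially missing variances are imputed from the mean coefficient of
        variation of the reporting studies (on the vi scale), and a fully
        unreported set falls back to an unweighted method-of-moments fit.

    Examples
    --------
    >>> res = RandomEffectsMeta([0.1, 0.3], [0.01, 0.02]).fit()
    >>> round(res.mu, 4)
    0.175
    """

    def __init__(self, yi: Sequence[float], vi: Sequence[float] | None = None):
        self.yi = np.asarray(yi, dtype=float)
        if vi is None:
            self.vi = np.full(len(self.yi), np.nan)
        else:
            self.vi = np.asarray(vi, dtype=float)
        if self.yi.shape != self.vi.shape:
            raise ValueError("yi and vi must have the same length")
        if len(self.yi) < 2:
            raise ValueError("random-effects pooling requires k >= 2 studies")
        if not np.all(np.isfinite(self.yi)):
            raise ValueError("effect sizes must be finite")
        known = np.isfinite(self.vi)
        if np.any(self.vi[known] <= 0):
            raise ValueError("sampling variances must be positive where reported")

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "RandomEffectsMeta":
        """Build directly from a paired-measurement table (see
        :func:`log_response_ratio`)."""
        eff = log_response_ratio(records)
        return cls(eff["yi"], eff["vi"])

    def _filled_vi(self) -> tuple[np.ndarray, str]:
        known = np.isfinite(self.vi)
        if known.all():
            return self.vi, "DL"
        if not known.any():
            return self.vi, "unweighted"
        vi = self.vi.copy()
        vi[~known] = float(np.mean(self.vi[known]))
        return vi, "DL(imputed-vi)"

    def fit(self) -> MetaResults:
        """Pool the studies; returns a :class:`MetaResults`."""
        yi = self.yi
        k = len(yi)
        vi, method = self._filled_vi()

        if method == "unweighted":
            # method-of-moments on raw effects: mu = mean, tau^2 = sample var
            mu = float(np.mean(yi))
            tau2 = float(np.var(yi, ddof=1))
            se = float(np.sqrt(tau2 / k))
            Q = float(np.sum((yi - mu) ** 2) / max(tau2, np.finfo(float).tiny)) if tau2 > 0 else 0.0
            I2 = max(0.0, (Q - (k - 1)) / Q) * 100 if Q > 0 else 0.0
        else:
            w = 1.0 / vi
            mu_f = float(np.sum(w * yi) / np.sum(w))
            Q = float(np.sum(w * (yi - mu_f) ** 2))
            denom = np.sum(w) - np.sum(w**2) / np.sum(w)
            tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
            ws = 1.0 / (vi + tau2)
            mu = float(np.sum(ws * yi) / np.sum(ws))
            se = float(np.sum(ws) ** -0.5)
            I2 = max(0.0, (Q - (k - 1)) / Q) * 100 if Q > 0 else 0.0

        z = mu / se if se > 0 else np.inf * np.sign(mu) if mu != 0 else 0.0
        p = float(2 * stats.norm.sf(abs(z)))
        return MetaResults(
            k=k,
            mu=mu,
            se_mu=se,
            ci_low=mu - Z975 * se,
            ci_high=mu + Z975 * se,
            tau2=tau2,
            Q=Q,
            I2=float(I2),
            p_value=p,
            method=method,
        )


@dataclass
class BinSpec:
    """Ordered, exhaustive, non-overlapping bins over a moderator.

    Closure convention: interior intervals are left-closed/right-open
    ``[lo, hi)``; the first bin is open at its lower edge (``<1`` means
    ``(0, 1)``), and the last bin is closed at both ends (``4-5`` is
    ``[4, 5]``).
    """

    edges: Sequence[float] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing with >= 2 values")
        if self.labels is None:
            self.labels = default_bin_labels(e)
        if len(self.labels) != len(e) - 1:
            raise ValueError("need one label per interval")

    @classmethod
    def warming_magnitude(cls) -> "BinSpec":
        """The five warming-magnitude groups: <1, 1-2, 2-3, 3-4, 4-5 °C."""
        return cls(edges=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0))

    @classmethod
    def duration(cls) -> "BinSpec":
        """Duration groups: <3, 3-6, 6-30 years."""
        return cls(edges=(0.0, 3.0, 6.0, 30.0), labels=("<3", "3-6", "6-30"))

    def assign(self, values: Sequence[float]) -> np.ndarray:
        """Map each value to exactly one bin label; out-of-range raises."""
        v = np.asarray(values, dtype=float)
        e = np.asarray(self.edges, dtype=float)
        out_of_range = (v <= e[0]) | (v > e[-1])
        if out_of_range.any():
            raise ValueError(
                f"values outside ({e[0]:g}, {e[-1]:g}]: "
                f"{v[out_of_range][:5].tolist()} (bins must be exhaustive)"
            )
        idx = np.searchsorted(e, v, side="right") - 1   # [lo, hi)
        idx = np.minimum(idx, len(e) - 2)               # value == last edge -> last bin
        return np.asarray(self.labels, dtype=object)[idx]


def subgroup_meta(effects: pd.DataFrame, bins: BinSpec, by: str = "warming_magnitude") -> dict:
    """Pool effects within each bin of a moderator column.

    Returns a mapping label -> :class:`MetaResults` for poolable bins
    (k >= 2); bins with a single study map to ``None`` (reported, never
    silently dropped); empty bins are absent.
    """
    labels = bins.assign(effects[by])
    out: dict[str, MetaResults | None] = {}
    for lab in bins.labels:
        sub = effects.loc[labels == lab]
        if len(sub) == 0:
            continue
        if len(sub) < 2:
            out[lab] = None
        else:
            out[lab] = RandomEffectsMeta(sub["yi"], sub["vi"]).fit()
    return out


@dataclass
class QuadraticFit:
    """OLS fit of LN(RR) on warming magnitude and its square."""

    coef: np.ndarray        # (intercept, linear, quadratic)
    r2_adj: float
    p_value: float          # overall F-test
    n: int
    model: object = field(repr=False, default=None)

    def predict(self, dT: Sequence[float]) -> np.ndarray:
        dT = np.asarray(dT, dtype=float)
        return self.coef[0] + self.coef[1] * dT + self.coef[2] * dT**2


def fit_quadratic_response(effects: pd.DataFrame, by: str = "warming_magnitude") -> QuadraticFit:
    """Quadratic dose-response: LN(RR) ~ dT + dT^2 (with intercept)."""
    if len(effects) < 4:
        raise ValueError("quadratic fit requires at least 4 studies")
    dT = effects[by].to_numpy(dtype=float)
    if np.ptp(dT) == 0:
        raise ValueError("warming magnitude is constant: design is collinear")
    X = sm.add_constant(np.column_stack([dT, dT**2]))
    fit = sm.OLS(effects["yi"].to_numpy(dtype=float), X).fit()
    return QuadraticFit(
        coef=np.asarray(fit.params),
        r2_adj=float(fit.rsquared_adj),
        p_value=float(fit.f_pvalue),
        n=int(fit.nobs),
        model=fit,
    )
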