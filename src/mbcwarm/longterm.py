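"""Per-site regressions of long-term in-situ MBC on annual temperature.

Each multi-year site series gets a simple OLS fit of MBC against annual
mean temperature; the slope's 95% confidence interval uses the
t-distribution with n-2 degrees of freedom (series run from 3 to ~10
years, where normal intervals would be anti-conservative).  "No
significant correlation" at a site means its CI spans zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SiteSlopeResult:
    site_id: str
    slope: float            # mmol kg^-1 per °C
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return not (self.ci_low <= 0.0 <= self.ci_high)


def site_slope(series: pd.DataFrame, site_id: str = "") -> SiteSlopeResult:
    """OLS slope of MBC on annual temperature for one site series.

    ``series`` needs columns ``mbc`` and ``temp`` (and optionally ``year``,
    used only for validation).  Requires n >= 3 and non-constant
    temperature.
    """
    mbc = series["mbc"].to_numpy(dtype=float)
    temp = series["temp"].to_numpy(dtype=float)
    n = len(series)
    if n < 3:
        raise ValueError(f"site {site_id or '?'}: need >= 3 years, got {n}")
    if np.ptp(temp) == 0:
        raise ValueError(f"site {site_id or '?'}: temperature is constant, slope undefined")
    if "year" in series.columns:
        yrs = series["year"].to_numpy()
        if np.any(np.diff(np.sort(yrs)) == 0):
            raise ValueError(f"site {site_id or '?'}: duplicate years in series")

    # plain OLS, done directly so a zero-variance MBC series yields a clean
    # (slope 0, p 1) answer instead of linregress's NaN correlation
    tc = temp - temp.mean()
    sxx = float(tc @ tc)
    slope = float(tc @ (mbc - mbc.mean())) / sxx
    resid = mbc - mbc.mean() - slope * tc
    s2 = float(resid @ resid) / (n - 2)
    se = float(np.sqrt(s2 / sxx))
    tcrit = float(stats.t.ppf(0.975, n - 2))
    if se == 0.0:
        p = 1.0 if slope == 0.0 else 0.0
    else:
        p = float(2 * stats.t.sf(abs(slope) / se, n - 2))
    return SiteSlopeResult(
        site_id=site_id,
        slope=slope,
        se=se,
        ci_low=slope - tcrit * se,
        ci_high=slope + tcrit * se,
        p_value=p,
        n=n,
    )


def fit_all_sites(table: pd.DataFrame) -> pd.DataFrame:
    """Fit every site in a long-format (site_id, year, mbc, temp) table.

    Returns one row per site with the slope, its t-based 95% CI, p-value
    and series length — the data content of a per-site slope figure.
    """
    rows = []
    for sid, sub in table.groupby("site_id", sort=True):
        r = site_slope(sub, site_id=str(sid))
        rows.append(
            dict(
                site_id=r.site_id,
                slope=r.slope,
                se=r.se,
                ci_low=r.ci_low,
                ci_high=r.ci_high,
                p_value=r.p_value,
                n=r.n,
                significant=r.significant,
            )
        )
    return pd.DataFrame(rows)
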