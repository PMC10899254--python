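"""Synthetic-data generators with known ground truth.

Three families of inputs are emulated:

* paired warming/control MBC measurements from field warming experiments
  (:func:`generate_warming_pairs`), with controllable per-bin true effects
  and optional one-sided suppression of studies (publication bias);
* multi-year in-situ MBC series with a known temporal temperature
  sensitivity (:func:`generate_longterm_series`);
* a spatial "world" (:func:`generate_world`): an abstract grid of cells with
  ten environmental predictors, annual temperature layers for 1992–2013
  under a linear warming trend, and a set of MBC observations sampled from
  the grid's baseline year.  The spatial MBC–temperature slope and the true
  temporal sensitivity are *independent* knobs, so a spurious
  space-for-time signal can be constructed (negative spatial slope, zero
  temporal sensitivity) or switched off.

All generators are deterministic given their seed; truth columns are
prefixed ``true_``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

YEARS = np.arange(1992, 2014)  # 22 annual layers
N_YEARS = len(YEARS)

#: fixed global land-cover vocabulary; subsamples missing a class stay alignable
LAND_COVER_CLASSES = ("forest", "grassland", "cropland", "shrubland", "bare")

CONTINUOUS_PREDICTORS = (
    "temperature",
    "soc",
    "ph",
    "precipitation",
    "clay",
    "sand",
    "nitrogen",
    "ndvi",
    "elevation",
)
PREDICTORS = CONTINUOUS_PREDICTORS + ("land_cover",)


def default_bin_labels(edges: Sequence[float]) -> list[str]:
    """Human-readable labels for warming-magnitude bins: '<1', '1-2', ..."""
    edges = list(edges)
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == edges[0] and lo <= 0:
            labels.append(f"<{hi:g}")
        else:
            labels.append(f"{lo:g}-{hi:g}")
    return labels


@dataclass
class WarmingSimConfig:
    """World definition for the paired warming-experiment generator.

    Defaults emulate the compiled field-warming evidence: 130 pairs across
    five warming-magnitude bins, a small positive true effect at 1–2 °C, a
    decline only above 4 °C, and no publication bias.
    """

    n_pairs: int = 130
    bin_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "<1": 0.0,
            "1-2": 0.08,
            "2-3": 0.0,
            "3-4": 0.0,
            "4-5": -0.15,
        }
    )
    bin_edges: Sequence[float] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    between_study_sd: float = 0.15
    within_sd_frac: float = 0.20
    cv_log_sd: float = 0.5      # spread of per-study relative SDs around within_sd_frac
    replicates_range: tuple[int, int] = (3, 10)
    duration_range: tuple[float, float] = (1.0, 12.0)
    control_mean: float = 60.0          # mmol kg^-1, log-normal median
    control_log_sd: float = 0.5
    suppress_prob: float = 0.0
    suppress_cutoff: float = 0.0
    suppress_side: str = "below"        # drop studies with LN(RR) below/above cutoff
    seed: int = 0

    def validate(self) -> None:
        if not self.bin_effects:
            raise ValueError("bin_effects must name at least one warming-magnitude bin")
        edges = np.asarray(self.bin_edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        labels = default_bin_labels(edges)
        unknown = set(self.bin_effects) - set(labels)
        if unknown:
            raise ValueError(f"bin_effects keys {sorted(unknown)} not among bins {labels}")
        if self.within_sd_frac <= 0:
            raise ValueError("within_sd_frac must be > 0 (use a tiny value for the noiseless limit)")
        if not 0.0 <= self.suppress_prob <= 1.0:
            raise ValueError("suppress_prob must lie in [0, 1]")
        if self.suppress_side not in ("below", "above"):
            raise ValueError("suppress_side must be 'below' or 'above'")
        if self.n_pairs < 2 * len(self.bin_effects):
            raise ValueError("need at least 2 pairs per populated bin")


def generate_warming_pairs(cfg: WarmingSimConfig) -> pd.DataFrame:
    """Simulate paired warming/control MBC measurements.

    Each record carries observed arm means (with replicate-level sampling
    error), per-arm SDs equal to ``within_sd_frac`` times the arm mean,
    replicate counts, the warming magnitude (drawn within its bin), the
    experiment duration, and the generating truth (``true_lnrr``).  Records
    whose *observed* LN(RR) falls on the suppressed side of
    ``suppress_cutoff`` are dropped with probability ``suppress_prob``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    edges = np.asarray(cfg.bin_edges, dtype=float)
    labels = default_bin_labels(edges)
    bins = [lab for lab in labels if lab in cfg.bin_effects]

    # spread n_pairs as evenly as possible over the populated bins
    base, extra = divmod(cfg.n_pairs, len(bins))
    counts = {lab: base + (1 if i < extra else 0) for i, lab in enumerate(bins)}

    rows = []
    rid = 0
    for lab in bins:
        lo, hi = edges[labels.index(lab)], edges[labels.index(lab) + 1]
        for _ in range(counts[lab]):
            dT = rng.uniform(max(lo, 1e-3), hi)
            duration = rng.uniform(*cfg.duration_range)
            n_c = int(rng.integers(cfg.replicates_range[0], cfg.replicates_range[1] + 1))
            n_w = int(rng.integers(cfg.replicates_range[0], cfg.replicates_range[1] + 1))
            mu_c = cfg.control_mean * np.exp(rng.normal(0.0, cfg.control_log_sd))
            true_lnrr = cfg.bin_effects[lab] + rng.normal(0.0, cfg.between_study_sd)
            mu_w = mu_c * np.exp(true_lnrr)
            # study-level measurement precision varies widely in field
            # compilations; a common relative SD applies to both arms
            cv = cfg.within_sd_frac * np.exp(rng.normal(0.0, cfg.cv_log_sd))
            sd_c = cv * mu_c
            sd_w = cv * mu_w
            # replicate-level sampling error on the reported arm means
            m_c = max(mu_c + rng.normal(0.0, sd_c / np.sqrt(n_c)), 1e-6)
            m_w = max(mu_w + rng.normal(0.0, sd_w / np.sqrt(n_w)), 1e-6)
            rows.append(
                dict(
                    study_id=f"S{rid:03d}",
                    site_id=f"site{rid:03d}",
                    mbc_control=m_c,
                    mbc_warmed=m_w,
                    sd_control=cv * m_c,
                    sd_warmed=cv * m_w,
                    n_control=n_c,
                    n_warmed=n_w,
                    warming_magnitude=dT,
                    duration=duration,
                    latitude=rng.uniform(-60.0, 75.0),
                    longitude=rng.uniform(-180.0, 180.0),
                    bin=lab,
                    true_lnrr=true_lnrr,
                )
            )
            rid += 1

    df = pd.DataFrame(rows)
    if cfg.suppress_prob > 0.0:
        lnrr = np.log(df["mbc_warmed"].to_numpy() / df["mbc_control"].to_numpy())
        if cfg.suppress_side == "below":
            at_risk = lnrr < cfg.suppress_cutoff
        else:
            at_risk = lnrr > cfg.suppress_cutoff
        drop = at_risk & (rng.random(len(df)) < cfg.suppress_prob)
        df = df.loc[~drop].reset_index(drop=True)
    return df


def generate_longterm_series(
    n_sites: int = 6,
    years_per_site: tuple[int, int] = (3, 10),
    temp_sensitivity: float = 0.0,
    noise_sd: float = 3.0,
    seed: int = 0,
    baseline_range: tuple[float, float] = (30.0, 100.0),
    temp_anomaly_sd: float = 0.7,
) -> pd.DataFrame:
    """Simulate multi-year in-situ MBC series at ``n_sites`` sites.

    Per site: ``MBC(year) = baseline + temp_sensitivity * (T(year) - T_mean)
    + noise``, with annual temperatures fluctuating around a site mean.
    Series lengths are drawn uniformly in ``years_per_site`` (real compiled
    series run from 3 up to 10 years).
    """
    lo, hi = years_per_site
    if lo < 2:
        raise ValueError("years_per_site below 2: per-site regression impossible")
    if not (lo <= hi):
        raise ValueError("years_per_site must be an increasing pair")
    rng = np.random.default_rng(seed)
    frames = []
    for s in range(n_sites):
        n = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(1990, 2015))
        years = np.arange(start, start + n)
        t_mean = rng.uniform(0.0, 15.0)
        temps = t_mean + rng.normal(0.0, temp_anomaly_sd, n)
        baseline = rng.uniform(*baseline_range)
        mbc = baseline + temp_sensitivity * (temps - t_mean) + rng.normal(0.0, noise_sd, n)
        frames.append(
            pd.DataFrame(
                dict(site_id=f"L{s:02d}", year=years, mbc=mbc, temp=temps)
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# spatial world


def _default_latent_corr() -> np.ndarray:
    """Correlation structure among the nine continuous predictors.

    Two independent blocks.  A "climate/terrain" block (temperature, pH,
    clay, sand, elevation) carries realistic collinearity with temperature;
    a "resource" block (soil organic carbon, precipitation, nitrogen, NDVI)
    is inter-correlated but *independent of temperature by construction*:
    these are the predictors that feed the MBC signal, and keeping them
    orthogonal to temperature makes the configured spatial MBC-temperature
    slope the entire dependence -- marginal and conditional alike -- so it
    can honestly be dialed to zero.
    """
    # order: temperature, soc, ph, precipitation, clay, sand, nitrogen, ndvi, elevation
    c = np.eye(len(CONTINUOUS_PREDICTORS))

    def set_(i, j, v):
        c[i, j] = c[j, i] = v

    set_(0, 2, 0.20)    # warm cells slightly more alkaline
    set_(0, 4, 0.10)
    set_(0, 8, -0.40)   # warm cells lie lower
    set_(2, 4, 0.30)
    set_(2, 5, -0.35)
    set_(4, 5, -0.55)   # texture components anti-correlate
    set_(1, 6, 0.60)    # carbon-rich soils carry more nitrogen
    set_(1, 3, 0.15)
    set_(1, 7, 0.30)
    set_(3, 7, 0.45)    # wetter cells are greener
    set_(6, 7, 0.25)
    assert np.linalg.eigvalsh(c).min() > 0.05
    return c


@dataclass
class WorldSimConfig:
    """World definition for the spatial grid and observation set.

    ``spatial_slope_true`` sets how MBC declines with temperature *across
    space* (mmol kg^-1 per °C); ``temporal_sensitivity_true`` sets how a
    cell's MBC actually responds to its own warming *over time*.  The two
    are independent, which is the point: the space-for-time artifact is the
    regime ``spatial_slope_true < 0`` with ``temporal_sensitivity_true = 0``.
    """

    n_cells: int = 2000
    n_obs: int = 762
    spatial_slope_true: float = -8.0
    temporal_sensitivity_true: float = 0.0
    warming_1992_2013: float = 0.28      # °C, linear over the 22 years
    predictor_cov: np.ndarray | None = None
    noise_sd: float = 15.0               # mmol kg^-1, residual spatial noise
    mbc_center: float = 200.0            # mmol kg^-1 at the mean-temperature cell
    temp_mean: float = 8.0
    temp_sd: float = 6.0
    other_effect_scale: float = 1.0      # scales non-temperature predictor effects
    seed: int = 0

    def validate(self) -> None:
        if self.n_obs > self.n_cells:
            raise ValueError("n_obs cannot exceed n_cells")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.predictor_cov is not None:
            c = np.asarray(self.predictor_cov, dtype=float)
            if c.shape != (len(CONTINUOUS_PREDICTORS),) * 2:
                raise ValueError("predictor_cov must be 9x9 (continuous predictors)")


@dataclass
class WorldGrid:
    """Per-cell predictor fields for 1992–2013 on an abstract lattice.

    Only temperature varies across years (linear warming); all other
    predictors are static.  ``true_mbc`` holds the ground-truth cell
    trajectories implied by ``temporal_sensitivity_true``.
    """

    static: pd.DataFrame                 # n_cells rows, all PREDICTORS (baseline temperature)
    temperature: np.ndarray              # (n_cells, 22)
    area: np.ndarray                     # (n_cells,)
    true_mbc: np.ndarray                 # (n_cells, 22)
    years: np.ndarray = field(default_factory=lambda: YEARS.copy())

    @property
    def n_cells(self) -> int:
        return len(self.static)

    def predictors_for_year(self, year: int) -> pd.DataFrame:
        """Predictor table for one year (temperature layer swapped in)."""
        i = int(np.where(self.years == year)[0][0])
        out = self.static.copy()
        out["temperature"] = self.temperature[:, i]
        return out

    def true_global_total(self, year: int) -> float:
        i = int(np.where(self.years == year)[0][0])
        return float(np.sum(self.area * self.true_mbc[:, i]))

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format cell x year table (for CSV export)."""
        frames = []
        for y in self.years:
            f = self.predictors_for_year(int(y))
            f.insert(0, "year", int(y))
            f.insert(0, "cell_id", np.arange(self.n_cells))
            f["area"] = self.area
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def _transform_predictors(
    z: np.ndarray, r: np.ndarray, cfg: WorldSimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Map latent Gaussians to plausible predictor ranges.

    ``z`` are the correlated latents (so predictors show realistic
    inter-correlations, including with temperature); ``r`` are the same
    latents residualized against the temperature latent, used where a
    quantity must stay independent of temperature by construction (the
    land-cover assignment, which feeds an offset into MBC).
    """
    t = cfg.temp_mean + cfg.temp_sd * z[:, 0]
    soc = np.exp(3.0 + 0.6 * z[:, 1])                    # g kg^-1
    ph = np.clip(6.0 + 1.0 * z[:, 2], 3.5, 9.0)
    precip = np.exp(6.5 + 0.7 * z[:, 3])                 # mm yr^-1
    comp = np.exp(np.column_stack([0.8 * z[:, 4], 0.8 * z[:, 5], np.zeros(len(z))]))
    comp = 100.0 * comp / comp.sum(axis=1, keepdims=True)  # clay/sand/silt composition
    clay, sand = comp[:, 0], comp[:, 1]
    nitrogen = np.exp(0.5 + 0.5 * z[:, 6])               # g kg^-1
    ndvi = 0.1 + 0.8 / (1.0 + np.exp(-0.9 * z[:, 7]))
    elevation = np.exp(6.0 + 0.9 * z[:, 8])              # m
    # land cover tied to greenness (temperature-independent residual part)
    score = 0.8 * r[:, 7] + 0.6 * rng.standard_normal(len(z))
    qs = np.quantile(score, [0.25, 0.5, 0.75, 0.9])
    lc_idx = np.searchsorted(qs, score)
    land_cover = pd.Categorical.from_codes(
        4 - lc_idx, categories=list(LAND_COVER_CLASSES)
    )
    return pd.DataFrame(
        dict(
            temperature=t,
            soc=soc,
            ph=ph,
            precipitation=precip,
            clay=clay,
            sand=sand,
            nitrogen=nitrogen,
            ndvi=ndvi,
            elevation=elevation,
            land_cover=land_cover,
        )
    )


_LC_OFFSETS = {"forest": 12.0, "grassland": 4.0, "cropland": -4.0, "shrubland": 0.0, "bare": -12.0}


def generate_world(cfg: WorldSimConfig) -> tuple[pd.DataFrame, WorldGrid]:
    """Build the spatial world and its observation set.

    Baseline (1992) MBC per cell is linear in temperature with slope
    ``spatial_slope_true`` plus modest contributions from the other
    predictors plus noise, floored at a small positive value.  The 22
    annual temperature layers apply ``warming_1992_2013`` linearly; true
    cell MBC responds to that warming only through
    ``temporal_sensitivity_true``.  Observations are drawn (without
    replacement) from the grid's baseline year.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    corr = cfg.predictor_cov if cfg.predictor_cov is not None else _default_latent_corr()
    chol = np.linalg.cholesky(np.asarray(corr, dtype=float))
    z = rng.standard_normal((cfg.n_cells, len(CONTINUOUS_PREDICTORS))) @ chol.T
    # residualize every latent against the temperature latent (empirically,
    # so the orthogonality is exact in-sample); the MBC signal below is
    # built from these residuals, making spatial_slope_true the *entire*
    # MBC-temperature dependence across space -- a knob that can honestly
    # be set to zero
    zt = z[:, 0] - z[:, 0].mean()
    proj = (z - z.mean(axis=0)).T @ zt / (zt @ zt)
    r = z - z.mean(axis=0) - np.outer(zt, proj)
    static = _transform_predictors(z, r, cfg, rng)

    t0 = static["temperature"].to_numpy()
    s = cfg.other_effect_scale
    other = s * (
        10.0 * r[:, 1]      # carbon-rich soils
        + 3.0 * r[:, 3]     # wetter cells
        + 4.0 * r[:, 6]     # nitrogen
        + 8.0 * r[:, 7]     # greenness
        + np.asarray([_LC_OFFSETS[c] for c in static["land_cover"]])
    )
    other = other - other.mean()
    mbc0 = (
        cfg.mbc_center
        + cfg.spatial_slope_true * (t0 - cfg.temp_mean)
        + other
        + rng.normal(0.0, cfg.noise_sd, cfg.n_cells)
    )
    mbc0 = np.maximum(mbc0, 0.5)  # MBC is a stock: strictly positive

    frac = (YEARS - YEARS[0]) / (YEARS[-1] - YEARS[0])
    temperature = t0[:, None] + cfg.warming_1992_2013 * frac[None, :]
    true_mbc = mbc0[:, None] + cfg.temporal_sensitivity_true * (temperature - t0[:, None])

    area = np.ones(cfg.n_cells)
    grid = WorldGrid(static=static, temperature=temperature, area=area, true_mbc=true_mbc)

    obs_idx = rng.choice(cfg.n_cells, size=cfg.n_obs, replace=False)
    obs = static.iloc[obs_idx].reset_index(drop=True).copy()
    obs.insert(0, "cell_id", obs_idx)
    obs["mbc"] = mbc0[obs_idx]
    return obs, grid
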