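"""Plain-CSV readers/writers and run manifests.

Every table travels as an ordinary CSV with a documented header; a YAML
manifest next to the outputs records the generating configuration and the
seed so any run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

#: column order for paired warming/control measurement tables
EFFECT_RECORD_COLUMNS = [
    "study_id",
    "site_id",
    "mbc_control",
    "mbc_warmed",
    "sd_control",
    "sd_warmed",
    "n_control",
    "n_warmed",
    "warming_magnitude",
    "duration",
    "latitude",
    "longitude",
]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(path: str | Path, config: Any, seed: int | None = None, **extra: Any) -> None:
    """Record a run's configuration (dataclass or mapping) and seed as YAML."""
    doc = {"config": _jsonable(config)}
    if seed is not None:
        doc["seed"] = int(seed)
    doc.update(_jsonable(extra))
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_config(path: str | Path) -> dict:
    """Load a nested key/value configuration file (YAML)."""
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out or {}


def write_effect_records(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in EFFECT_RECORD_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


def read_effect_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"mbc_control", "mbc_warmed", "warming_magnitude"} - set(df.columns)
    if missing:
        raise ValueError(f"effect-record CSV missing required columns: {sorted(missing)}")
    return df


def write_meta_results(results: Mapping[str, Any], path: str | Path) -> None:
    """One row per bin: pooled effect, CI, heterogeneity (None -> unpoolable)."""
    rows = []
    for label, r in results.items():
        if r is None:
            rows.append(dict(bin=label, poolable=False))
        else:
            rows.append(
                dict(
                    bin=label,
                    poolable=True,
                    k=r.k,
                    mu=r.mu,
                    se_mu=r.se_mu,
                    ci_low=r.ci_low,
                    ci_high=r.ci_high,
                    tau2=r.tau2,
                    Q=r.Q,
                    I2=r.I2,
                    p_value=r.p_value,
                    method=r.method,
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_forest_data(effects: pd.DataFrame, pooled, path: str | Path) -> None:
    """Forest-plot data: per-study yi/vi rows plus a pooled summary row."""
    rows = effects[["yi", "vi"]].copy()
    rows["label"] = effects.get("study_id", pd.Series(range(len(effects)))).astype(str)
    rows["kind"] = "study"
    summary = pd.DataFrame(
        [dict(yi=pooled.mu, vi=pooled.se_mu**2, label="pooled", kind="pooled")]
    )
    pd.concat([rows, summary], ignore_index=True).to_csv(path, index=False)


def write_funnel_data(yi, vi, path: str | Path, imputed=None) -> None:
    df = pd.DataFrame({"yi": np.asarray(yi, float), "si": np.sqrt(np.asarray(vi, float))})
    df["imputed"] = False if imputed is None else np.asarray(imputed, bool)
    df.to_csv(path, index=False)


def write_bias_assessments(assessments: Mapping[str, Any], path: str | Path) -> None:
    rows = []
    for label, a in assessments.items():
        if a is None:
            rows.append(dict(bin=label, testable=False))
            continue
        rows.append(
            dict(
                bin=label,
                testable=True,
                k=a.k,
                egger_intercept=a.egger_intercept,
                egger_p=a.egger_p,
                k0=a.k0,
                side=a.side,
                adjusted=a.adjusted,
                mu_unadjusted=a.mu_unadjusted.mu,
                ci_low_unadjusted=a.mu_unadjusted.ci_low,
                ci_high_unadjusted=a.mu_unadjusted.ci_high,
                mu_adjusted=a.mu_adjusted.mu,
                ci_low_adjusted=a.mu_adjusted.ci_low,
                ci_high_adjusted=a.mu_adjusted.ci_high,
            )
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_site_series(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"site_id", "year", "mbc", "temp"} - set(df.columns)
    if missing:
        raise ValueError(f"site-series CSV missing required columns: {sorted(missing)}")
    return df


def write_world(obs: pd.DataFrame, grid, out_dir: str | Path) -> None:
    """Spatial observations plus the grid as a long cell x year CSV."""
    out = Path(out_dir)
    obs.to_csv(out / "spatial_observations.csv", index=False)
    grid.to_long_frame().to_csv(out / "world_grid.csv", index=False)


def read_world(out_dir: str | Path):
    """Inverse of :func:`write_world`; rebuilds the WorldGrid object."""
    from .simulate import PREDICTORS, WorldGrid

    out = Path(out_dir)
    obs = pd.read_csv(out / "spatial_observations.csv")
    long = pd.read_csv(out / "world_grid.csv")
    years = np.sort(long["year"].unique())
    base = long[long["year"] == years[0]].sort_values("cell_id").reset_index(drop=True)
    static = base[list(PREDICTORS)].copy()
    n_cells = len(base)
    temperature = np.empty((n_cells, len(years)))
    for i, y in enumerate(years):
        sub = long[long["year"] == y].sort_values("cell_id")
        temperature[:, i] = sub["temperature"].to_numpy()
    grid = WorldGrid(
        static=static,
        temperature=temperature,
        area=base["area"].to_numpy(dtype=float),
        true_mbc=np.zeros_like(temperature),
        years=np.asarray(years, dtype=int),
    )
    return obs, grid
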