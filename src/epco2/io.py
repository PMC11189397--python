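"""Table readers/writers and run configuration.

All inputs are plain delimited text: a per-sample table (one row per
sediment sample), two-column ``(age_ma, value)`` compilations for foram
d13C, auxiliary SSTs and sea level, and a long-format regional dSST table
``(age_ma, region, dsst_c[, dsst_sd])``.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .params import ForcingParams, McConfig, ProxyParams, load_params_yaml
from .records import REGIONS, PCO2Estimate, SampleRecord, SensitivityResult

__all__ = [
    "read_sample_table",
    "read_two_column",
    "read_dsst_table",
    "estimates_frame",
    "sensitivity_frame",
    "RunConfig",
    "load_run_config",
]

log = logging.getLogger(__name__)

STERANE_SUFFIXES = ("c27", "c28", "c29")


def _cell(row, col) -> float | None:
    if col not in row or row[col] is None:
        return None
    v = row[col]
    if isinstance(v, float) and math.isnan(v):
        return None
    return float(v)


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read the per-sample CSV into validated records.

    Rows that violate a record invariant (e.g. sterane fractions not
    summing to 1) are rejected with a warning naming the line; the run
    continues with the remaining rows. Missing mandatory columns raise.
    """
    df = pd.read_csv(path)
    for col in ("sample_id", "age_ma"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    records: list[SampleRecord] = []
    for idx, row in df.iterrows():
        deltas, fracs = [], []
        for sfx in STERANE_SUFFIXES:
            d = _cell(row, f"d13c_sterane_{sfx}")
            f = _cell(row, f"frac_sterane_{sfx}")
            if d is not None and f is not None:
                deltas.append(d)
                fracs.append(f)
        gdgt = {}
        for col in ("gdgt_1", "gdgt_2", "gdgt_3", "cren_prime"):
            v = _cell(row, col)
            if v is not None:
                gdgt[col] = v
        try:
            records.append(
                SampleRecord(
                    sample_id=str(row["sample_id"]),
                    age=float(row["age_ma"]),
                    depth=_cell(row, "depth_mbsf"),
                    delta_phytane=_cell(row, "d13c_phytane"),
                    sterane_deltas=deltas or None,
                    sterane_fractions=fracs or None,
                    delta_alkenone=_cell(row, "d13c_alkenone"),
                    gdgt_abundances=gdgt or None,
                )
            )
        except ValueError as exc:
            log.warning("%s line %d rejected: %s", path, idx + 2, exc)
    return records


def read_two_column(path: str | Path) -> tuple[list[float], list[float]]:
    """Read an (age_ma, value) compilation, sorted by age."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (age_ma, value)")
    age_col = "age_ma" if "age_ma" in df.columns else df.columns[0]
    val_col = "value" if "value" in df.columns else df.columns[1]
    df = df[[age_col, val_col]].dropna().sort_values(age_col)
    return df[age_col].tolist(), df[val_col].tolist()


def read_dsst_table(path: str | Path) -> dict[str, list[tuple[float, float, float]]]:
    """Read the regional dSST table into {region: [(age, dsst, sd), ...]}."""
    df = pd.read_csv(path)
    for col in ("age_ma", "region", "dsst_c"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    bad = set(df["region"]) - set(REGIONS)
    if bad:
        raise ValueError(f"{path}: unknown region label(s) {sorted(bad)}")
    out: dict[str, list[tuple[float, float, float]]] = {}
    has_sd = "dsst_sd" in df.columns
    for region, grp in df.groupby("region"):
        grp = grp.sort_values("age_ma")
        sds = grp["dsst_sd"] if has_sd else [float("nan")] * len(grp)
        out[str(region)] = [
            (float(a), float(v), float(s) if has_sd and not math.isnan(s) else ForcingParams().dsst_sd_default)
            for a, v, s in zip(grp["age_ma"], grp["dsst_c"], sds)
        ]
    return out


def estimates_frame(estimates: Sequence[PCO2Estimate]) -> pd.DataFrame:
    cols = [
        "sample_id", "age", "biomarker", "epsilon_p", "pco2_mean", "pco2_sd",
        "pco2_median", "pco2_q16", "pco2_q84", "co2aq", "n_draws", "n_retained",
        "frac_rejected", "reliable",
    ]
    df = pd.DataFrame([dataclasses.asdict(e) for e in estimates])
    if df.empty:
        return pd.DataFrame(columns=cols).rename(columns={"age": "age_ma"})
    return df[cols].rename(columns={"age": "age_ma"})


def sensitivity_frame(results: Sequence[SensitivityResult]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    order = ["region", "mode", "slope", "slope_se", "intercept", "r2",
             "degrees_c_per_doubling", "n_points"]
    return df[order] if not df.empty else pd.DataFrame(columns=order)


@dataclass
class RunConfig:
    """Paths plus parameter blocks for one pipeline run."""

    samples: Path | None = None
    foram: Path | None = None
    dsst: Path | None = None
    aux_sst: Path | None = None
    params_file: Path | None = None
    outdir: Path = Path("epco2_out")
    proxy_params: ProxyParams = field(default_factory=ProxyParams)
    mc: McConfig = field(default_factory=McConfig)
    forcing: ForcingParams = field(default_factory=ForcingParams)

    def resolved_params(self) -> ProxyParams:
        if self.params_file is not None:
            return load_params_yaml(self.params_file)
        return self.proxy_params


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration.

    Recognised keys: ``samples, foram, dsst, aux_sst, params_file, outdir``
    (paths, resolved relative to the config file), ``n_draws, seed``
    (Monte Carlo) and ``f2x_mode, n0, dsst_sd`` (forcing overrides).
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent
    cfg = RunConfig()
    for key in ("samples", "foram", "dsst", "aux_sst", "params_file", "outdir"):
        if key in raw and raw[key] is not None:
            setattr(cfg, key, base / str(raw[key]))
    mc_kwargs = {}
    if "n_draws" in raw:
        mc_kwargs["n_draws"] = int(raw["n_draws"])
    if "seed" in raw:
        mc_kwargs["seed"] = int(raw["seed"])
    if mc_kwargs:
        cfg.mc = dataclasses.replace(cfg.mc, **mc_kwargs)
    f_kwargs = {}
    if "f2x_mode" in raw:
        f_kwargs["f2x_mode"] = str(raw["f2x_mode"])
    if "n0" in raw:
        f_kwargs["n0"] = float(raw["n0"])
    if "dsst_sd" in raw:
        f_kwargs["dsst_sd_default"] = float(raw["dsst_sd"])
    if f_kwargs:
        cfg.forcing = dataclasses.replace(cfg.forcing, **f_kwargs)
    return cfg


def write_metadata(path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
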