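"""Forward-model generator of synthetic pipeline inputs with known truth.

Emulates a mid-Miocene-to-Pleistocene organic-rich drill-site dataset:
~35 samples spanning 0.3-15 Ma whose true pCO2 declines linearly from
650 ppmv at 15 Ma to 280 ppmv at 0.3 Ma. For each sample age the proxy
chain is inverted exactly — K0 from the true SST, CO2(aq) = pCO2 * K0,
epsilon_p = epsilon_f - b/CO2(aq), delta_d from the true foraminiferal
d13C and SST, delta_p from the epsilon_p definition — and biomarker d13C
values are the implied lipid values plus per-observable noise. GDGT
abundances are back-solved from the true SST through the TEX86-H inverse;
the oldest few samples are emitted without GDGTs (mirroring below-detection
isoGDGTs in deep sections) together with an auxiliary-site SST series for
gap-filling. Regional dSST series are slope * (dR_CO2 + dR_LI) + noise in
0.125-Ma bins, so an ECS fit recovers the chosen slopes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .forcing import rf_co2, rf_land_ice, sea_level
from .params import ForcingParams, ProxyParams
from .proxy import delta_co2aq_from_foram, delta_p_from_epsilon, henry_k0
from .records import REGIONS
from .tex86 import tex86_from_sst

__all__ = ["TruthScenario", "SyntheticDataset", "generate_dataset", "generate_sensitivity_truth"]

DSST_BIN_MA = 0.125
STERANE_FRACTIONS = (0.40, 0.35, 0.25)  # C27 : C28 : C29
ALKENONE_MAX_AGE = 4.0  # alkenones present only in the most recent 4 Myr


def _linear(age_young: float, v_young: float, age_old: float, v_old: float):
    def curve(age):
        return v_young + (v_old - v_young) * (np.asarray(age, float) - age_young) / (
            age_old - age_young
        )

    return curve


@dataclass(frozen=True)
class TruthScenario:
    """Ground truth for one synthetic dataset.

    Default curves are linear in age: pCO2 650 -> 280 ppmv, site SST
    25 -> 12 degC and foram d13C 2.4 -> 1.0 per-mil over 15 -> 0.3 Ma.
    ``slopes`` are the per-region temperature sensitivities (K per W m^-2)
    written into the dSST series. Noise SDs: 0.3 per-mil on each lipid
    d13C, 1 degC SST-equivalent on GDGTs, 0.1 per-mil on the foram
    compilation, 1.5 degC on binned dSST.
    """

    n_samples: int = 35
    age_range: tuple[float, float] = (0.3, 15.0)
    seed: int = 0
    pco2_curve: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: _linear(0.3, 280.0, 15.0, 650.0)
    )
    sst_curve: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: _linear(0.3, 12.0, 15.0, 25.0)
    )
    delta_foram_curve: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: _linear(0.3, 1.0, 15.0, 2.4)
    )
    slopes: Mapping[str, float] = field(
        default_factory=lambda: {"nh_high": 3.1, "nh_mid": 2.3, "sh_mid": 2.2, "tropics": 1.3}
    )
    noise_d13c: float = 0.3
    noise_gdgt_sst: float = 1.0
    noise_foram: float = 0.1
    noise_dsst: float = 1.5
    n_missing_gdgt: int = 3  # oldest samples emitted without GDGTs

    def __post_init__(self) -> None:
        if self.n_samples < 5:
            raise ValueError("n_samples must be >= 5")
        lo, hi = self.age_range
        if not (0 <= lo < hi):
            raise ValueError("bad age_range")


@dataclass
class SyntheticDataset:
    """Generated tables in the CSV dialects the pipeline reads, plus truth."""

    samples: pd.DataFrame
    foram: pd.DataFrame
    dsst: pd.DataFrame
    sea_level: pd.DataFrame
    aux_sst: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("samples", "foram", "dsst", "sea_level", "aux_sst", "truth"):
            p = outdir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False, float_format="%.10g")
            paths[name] = p
        return paths


def generate_sensitivity_truth(
    scenario: TruthScenario,
    rng: np.random.Generator | None = None,
    fparams: ForcingParams = ForcingParams(),
) -> pd.DataFrame:
    """Regional dSST series: slope * (dR_CO2 + dR_LI) + noise, in 0.125-Ma
    bins over the scenario's age range, one row per (bin, region)."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 1)
    lo, hi = scenario.age_range
    ages = np.arange(np.floor(lo / DSST_BIN_MA) * DSST_BIN_MA, hi + DSST_BIN_MA / 2, DSST_BIN_MA)
    ages = np.clip(ages, lo, hi)
    forcing = rf_co2(scenario.pco2_curve(ages), fparams) + rf_land_ice(
        sea_level(ages, fparams), fparams
    )
    rows = []
    for region in REGIONS:
        slope = float(scenario.slopes.get(region, 0.0))
        dsst = slope * forcing
        if scenario.noise_dsst > 0:
            dsst = dsst + rng.normal(0.0, scenario.noise_dsst, ages.size)
        rows.append(
            pd.DataFrame(
                {
                    "age_ma": ages,
                    "region": region,
                    "dsst_c": dsst,
                    "dsst_sd": scenario.noise_dsst if scenario.noise_dsst > 0 else 0.0,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_dataset(
    scenario: TruthScenario = TruthScenario(),
    params: ProxyParams = ProxyParams(),
    fparams: ForcingParams = ForcingParams(),
) -> SyntheticDataset:
    """Generate all pipeline inputs from the scenario's ground truth.

    Raises if the scenario implies a saturated proxy (epsilon_p >=
    epsilon_f) at any sample age.
    """
    rng = np.random.default_rng(scenario.seed)
    lo, hi = scenario.age_range
    ages = np.linspace(lo, hi, scenario.n_samples)

    pco2 = np.asarray(scenario.pco2_curve(ages), float)
    sst = np.asarray(scenario.sst_curve(ages), float)
    foram = np.asarray(scenario.delta_foram_curve(ages), float)
    if np.any(pco2 <= 0):
        raise ValueError("scenario pCO2 curve must be positive over the age range")

    k0 = henry_k0(sst, params.salinity)
    co2aq = pco2 * k0  # ppmv * mol kg^-1 atm^-1 -> umol kg^-1
    eps_p = params.epsilon_f.center - params.b.center / co2aq
    bad = eps_p >= params.epsilon_f.center - params.saturation_floor
    if np.any(bad):
        raise ValueError(
            f"scenario saturates the proxy at age(s) {ages[bad].round(2).tolist()} Ma"
        )
    delta_d = delta_co2aq_from_foram(foram, sst)
    delta_p = delta_p_from_epsilon(delta_d, eps_p)

    def lipid(offset_center: float, n: int) -> np.ndarray:
        noisy = delta_p - offset_center
        if scenario.noise_d13c > 0:
            noisy = noisy + rng.normal(0.0, scenario.noise_d13c, n)
        return noisy

    n = ages.size
    d_phytane = lipid(params.offset_phytane.center, n)
    d_sterane = lipid(params.offset_sterane.center, n)
    d_alkenone = lipid(params.offset_alkenone.center, n)

    # spread the sterane target over three compounds; the noise is centred
    # so the abundance-weighted mean stays exactly on target
    fr = np.array(STERANE_FRACTIONS)
    st = np.empty((n, 3))
    for i in range(n):
        e = rng.normal(0.0, scenario.noise_d13c, 3) if scenario.noise_d13c > 0 else np.zeros(3)
        st[i] = d_sterane[i] + e - float(np.dot(fr, e))

    # GDGTs back-solved from (noisy) SST; oldest samples lack them
    sst_for_gdgt = sst + (
        rng.normal(0.0, scenario.noise_gdgt_sst, n) if scenario.noise_gdgt_sst > 0 else 0.0
    )
    sst_for_gdgt = np.minimum(sst_for_gdgt, 38.0)
    ratio = np.array([tex86_from_sst(s) for s in sst_for_gdgt])
    missing = np.zeros(n, dtype=bool)
    if scenario.n_missing_gdgt > 0:
        missing[np.argsort(ages)[-scenario.n_missing_gdgt:]] = True

    alk_ok = ages <= ALKENONE_MAX_AGE
    depth = 9.0 + (ages - lo) / (hi - lo) * (1038.0 - 9.0)

    samples = pd.DataFrame(
        {
            "sample_id": [f"SYN-{i:03d}" for i in range(n)],
            "age_ma": ages,
            "depth_mbsf": depth,
            "d13c_phytane": d_phytane,
            "d13c_sterane_c27": st[:, 0],
            "d13c_sterane_c28": st[:, 1],
            "d13c_sterane_c29": st[:, 2],
            "frac_sterane_c27": fr[0],
            "frac_sterane_c28": fr[1],
            "frac_sterane_c29": fr[2],
            "d13c_alkenone": np.where(alk_ok, d_alkenone, np.nan),
            "gdgt_1": np.where(missing, np.nan, 1.0 - ratio),
            "gdgt_2": np.where(missing, np.nan, 0.5 * ratio),
            "gdgt_3": np.where(missing, np.nan, 0.3 * ratio),
            "cren_prime": np.where(missing, np.nan, 0.2 * ratio),
        }
    )

    # foram compilation on a dense regular grid (exact for linear curves)
    grid = np.linspace(max(0.0, lo - 0.5), hi + 0.5, 160)
    fvals = np.asarray(scenario.delta_foram_curve(grid), float)
    if scenario.noise_foram > 0:
        fvals = fvals + rng.normal(0.0, scenario.noise_foram, grid.size)
    foram_tbl = pd.DataFrame({"age_ma": grid, "value": fvals})

    # auxiliary-site SST series for gap-filling (true curve + GDGT noise)
    aux_grid = np.linspace(lo, hi, 60)
    aux_vals = np.asarray(scenario.sst_curve(aux_grid), float)
    if scenario.noise_gdgt_sst > 0:
        aux_vals = aux_vals + rng.normal(0.0, scenario.noise_gdgt_sst, aux_grid.size)
    aux_tbl = pd.DataFrame({"age_ma": aux_grid, "value": aux_vals})

    sl_tbl = pd.DataFrame(fparams.sea_level_knots, columns=["age_ma", "value"])
    dsst_tbl = generate_sensitivity_truth(scenario, rng, fparams)

    truth = pd.DataFrame(
        {
            "sample_id": samples["sample_id"],
            "age_ma": ages,
            "pco2_true": pco2,
            "co2aq_true": co2aq,
            "epsilon_p_true": eps_p,
            "sst_true": sst,
            "delta_foram_true": foram,
            "delta_p_true": delta_p,
        }
    )
    return SyntheticDataset(samples, foram_tbl, dsst_tbl, sl_tbl, aux_tbl, truth)
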