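"""Radiative forcing, errors-in-variables regression and climate sensitivity.

CO2 forcing follows the polynomial-in-ln formulation

    dR_CO2 = [a1 (C - C0)^2 + b1 |C - C0| + c1 N0 + 5.36] ln(C / C0)

with C in ppm and N0 in ppb. Land-ice (albedo) forcing is reconstructed
sea level (m) times 0.0308 W m^-3, sea level being linearly interpolated
between a handful of tie points. Regional sensitivity is the slope of a
York-type errors-in-both-variables fit of dSST against forcing: against
dR_CO2 alone it is Earth-system sensitivity (ESS, slow feedbacks
included), against dR_CO2 + dR_LI it is the specific sensitivity
S_[CO2,LI] used here as ECS. Slopes in K/(W m^-2) convert to degC per CO2
doubling through the forcing of one doubling. The global number
area-weights tropics (50.0%), mid-latitudes (36.6%, NH/SH averaged) and
high latitudes (13.4%).
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .params import ForcingParams
from .proxy import interpolate_series
from .records import REGIONS, PCO2Estimate, SensitivityResult

__all__ = [
    "rf_co2",
    "rf_co2_derivative",
    "sea_level",
    "rf_land_ice",
    "exclude_saturated_tropics",
    "york_regression",
    "YorkFit",
    "regional_sensitivity",
    "global_weighted",
    "sensitivity_table",
    "AREA_WEIGHTS",
    "TROPICS_SATURATION_AGE",
]

log = logging.getLogger(__name__)

AREA_WEIGHTS = {"tropics": 0.500, "mid": 0.366, "high": 0.134}
# alkenone-unsaturation SSTs at tropical sites saturate (ratio -> 1.00)
# beyond this age; those dSST values are excluded from fits
TROPICS_SATURATION_AGE = 8.0


def rf_co2(c, params: ForcingParams = ForcingParams()):
    """Radiative forcing (W m^-2) of CO2 concentration ``c`` (ppm) relative
    to the reference ``params.c0_ref``. Zero at the reference, negative
    below it."""
    carr = np.asarray(c, dtype=float)
    if np.any(carr <= 0):
        raise ValueError("CO2 concentration must be positive")
    d = carr - params.c0_ref
    coeff = params.a1 * d**2 + params.b1 * np.abs(d) + params.c1 * params.n0 + 5.36
    out = coeff * np.log(carr / params.c0_ref)
    return out if out.ndim else float(out)


def rf_co2_derivative(c, params: ForcingParams = ForcingParams()):
    """d(rf_co2)/dC at ``c`` (W m^-2 ppm^-1); used to map pCO2 uncertainty
    into forcing uncertainty by the delta method."""
    carr = np.asarray(c, dtype=float)
    d = carr - params.c0_ref
    coeff = params.a1 * d**2 + params.b1 * np.abs(d) + params.c1 * params.n0 + 5.36
    dcoeff = 2.0 * params.a1 * d + params.b1 * np.sign(d)
    out = dcoeff * np.log(carr / params.c0_ref) + coeff / carr
    return out if out.ndim else float(out)


def sea_level(age, params: ForcingParams = ForcingParams()):
    """Sea level (m above present) at ``age`` Ma, linear between tie points."""
    knots_a = np.array([a for a, _ in params.sea_level_knots])
    knots_v = np.array([v for _, v in params.sea_level_knots])
    t = np.asarray(age, dtype=float)
    if np.any(t < knots_a[0]) or np.any(t > knots_a[-1]):
        raise ValueError(
            f"age outside sea-level knot range [{knots_a[0]}, {knots_a[-1]}] Ma"
        )
    out = np.interp(t, knots_a, knots_v)
    return out if out.ndim else float(out)


def rf_land_ice(sea_level_m, params: ForcingParams = ForcingParams()):
    """Land-ice (albedo) forcing: sea level (m) times ``li_coeff`` (W m^-3)."""
    out = np.asarray(sea_level_m, dtype=float) * params.li_coeff
    return out if out.ndim else float(out)


def exclude_saturated_tropics(
    pairs: Iterable[tuple[float, float, str]],
    max_age: float = TROPICS_SATURATION_AGE,
) -> list[tuple[float, float, str]]:
    """Drop tropics (age, dSST, region) pairs older than ``max_age`` Ma;
    other regions pass through untouched."""
    kept, removed = [], 0
    for age, dsst, region in pairs:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        if region == "tropics" and age > max_age:
            removed += 1
            continue
        kept.append((age, dsst, region))
    if removed:
        log.info("excluded %d saturated tropics pairs older than %.1f Ma", removed, max_age)
    return kept


class YorkFit:
    """Result of a York errors-in-variables fit."""

    __slots__ = ("slope", "slope_se", "intercept", "intercept_se", "r2", "n_iter")

    def __init__(self, slope, slope_se, intercept, intercept_se, r2, n_iter):
        self.slope = slope
        self.slope_se = slope_se
        self.intercept = intercept
        self.intercept_se = intercept_se
        self.r2 = r2
        self.n_iter = n_iter

    def __iter__(self):  # (slope, slope_se, intercept, r2) unpacking
        return iter((self.slope, self.slope_se, self.intercept, self.r2))

    def __repr__(self):
        return (
            f"YorkFit(slope={self.slope:.6g} +/- {self.slope_se:.2g}, "
            f"intercept={self.intercept:.6g}, r2={self.r2:.3f})"
        )


def york_regression(
    x: Sequence[float],
    y: Sequence[float],
    sx: Sequence[float] | float,
    sy: Sequence[float] | float,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> YorkFit:
    """Straight-line fit with measurement errors in both variables.

    Iteratively reweighted least squares in the York formulation with zero
    x-y error correlation; converges when the slope changes by less than
    ``tol`` between iterations. ``r2`` is the squared Pearson correlation
    of the raw (x, y), reported as a descriptive goodness-of-fit. Zero
    errors are allowed (the fit degrades gracefully to the weighted or
    ordinary least-squares limit).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("york_regression needs n >= 3 points")
    sx = np.broadcast_to(np.asarray(sx, dtype=float), x.shape).copy()
    sy = np.broadcast_to(np.asarray(sy, dtype=float), y.shape).copy()
    if np.any(sx < 0) or np.any(sy < 0):
        raise ValueError("error bars must be >= 0")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: no spread in x")
    # floor zero errors far below the data scale so weights stay finite
    xfloor = max(np.ptp(x), np.abs(x).max(), 1.0) * 1e-12
    yfloor = max(np.ptp(y), np.abs(y).max(), 1.0) * 1e-12
    wx = 1.0 / np.maximum(sx, xfloor) ** 2
    wy = 1.0 / np.maximum(sy, yfloor) ** 2

    # OLS start
    b = float(np.polyfit(x, y, 1)[0])
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = wx * wy / (wx + b * b * wy)
        xbar = np.sum(w * x) / np.sum(w)
        ybar = np.sum(w * y) / np.sum(w)
        u = x - xbar
        v = y - ybar
        beta = w * (u / wy + b * v / wx)
        b_new = float(np.sum(w * beta * v) / np.sum(w * beta * u))
        if abs(b_new - b) < tol:
            b = b_new
            break
        b = b_new
    else:
        raise RuntimeError(
            f"york_regression did not converge in {max_iter} iterations "
            f"(last slope {b!r})"
        )

    w = wx * wy / (wx + b * b * wy)
    xbar = np.sum(w * x) / np.sum(w)
    ybar = np.sum(w * y) / np.sum(w)
    a = ybar - b * xbar
    beta = w * ((x - xbar) / wy + b * (y - ybar) / wx)
    x_adj = xbar + beta
    xa_bar = np.sum(w * x_adj) / np.sum(w)
    u_adj = x_adj - xa_bar
    var_b = 1.0 / np.sum(w * u_adj**2)
    var_a = 1.0 / np.sum(w) + xa_bar**2 * var_b
    r = np.corrcoef(x, y)[0, 1]
    return YorkFit(b, float(np.sqrt(var_b)), a, float(np.sqrt(var_a)), float(r * r), n_iter)


def regional_sensitivity(
    pco2_series: Sequence[tuple[float, float, float]],
    dsst_series: Sequence[tuple[float, float]] | Sequence[tuple[float, float, float]],
    mode: str,
    params: ForcingParams = ForcingParams(),
    region: str = "tropics",
) -> SensitivityResult:
    """Temperature sensitivity of one latitudinal region.

    ``pco2_series``: (age Ma, pCO2 mean ppmv, pCO2 SD ppmv) per sample —
    the phytane-based record. ``dsst_series``: the region's binned dSST
    compilation as (age, dSST[, dSST SD]); it is interpolated onto the
    sample ages. ``mode`` "ESS" regresses dSST on dR_CO2; "ECS" on
    dR_CO2 + dR_LI. Tropics pairs older than the saturation age are
    excluded before fitting.
    """
    if mode not in ("ESS", "ECS"):
        raise ValueError("mode must be 'ESS' or 'ECS'")
    pc = sorted(pco2_series)
    ds = sorted(dsst_series)
    ds_ages = np.array([r[0] for r in ds])
    ds_vals = np.array([r[1] for r in ds])
    ds_sds = np.array([r[2] if len(r) > 2 else params.dsst_sd_default for r in ds])

    ages, xs, sxs, ys, sys_ = [], [], [], [], []
    for age, pmean, psd in pc:
        if region == "tropics" and age > TROPICS_SATURATION_AGE:
            continue
        vals, in_rng = interpolate_series([age], ds_ages, ds_vals)
        if not in_rng[0]:
            log.warning("age %.3f Ma outside dSST compilation; pair dropped", age)
            continue
        sds, _ = interpolate_series([age], ds_ages, ds_sds)
        x = rf_co2(pmean, params)
        sx = abs(rf_co2_derivative(pmean, params)) * psd
        if mode == "ECS":
            x += rf_land_ice(sea_level(age, params), params)
        ages.append(age)
        xs.append(x)
        sxs.append(sx)
        ys.append(float(vals[0]))
        sys_.append(float(sds[0]))
    if len(xs) < 3:
        raise ValueError(f"{region}/{mode}: only {len(xs)} matched pairs (< 3)")
    fit = york_regression(xs, ys, sxs, sys_)
    return SensitivityResult(
        region=region,
        mode=mode,
        slope=fit.slope,
        slope_se=fit.slope_se,
        intercept=fit.intercept,
        r2=min(max(fit.r2, 0.0), 1.0),
        degrees_c_per_doubling=fit.slope * params.f2x,
        n_points=len(xs),
    )


def global_weighted(regional: Mapping[str, float]) -> float:
    """Area-weighted global value: 0.500 tropics + 0.366 mid + 0.134 high,
    the mid (and high) contribution being the mean of the hemispheres
    present."""
    if "tropics" not in regional:
        raise ValueError("missing region: tropics")
    mids = [v for k, v in regional.items() if k in ("nh_mid", "sh_mid")]
    highs = [v for k, v in regional.items() if k in ("nh_high", "sh_high")]
    missing = [name for name, vals in (("mid-latitudes", mids), ("high-latitudes", highs)) if not vals]
    if missing:
        raise ValueError("missing region(s): " + ", ".join(missing))
    return (
        AREA_WEIGHTS["tropics"] * regional["tropics"]
        + AREA_WEIGHTS["mid"] * float(np.mean(mids))
        + AREA_WEIGHTS["high"] * float(np.mean(highs))
    )


def sensitivity_table(
    phytane_estimates: Sequence[PCO2Estimate],
    dsst_by_region: Mapping[str, Sequence[tuple[float, float]]],
    params: ForcingParams = ForcingParams(),
    modes: Sequence[str] = ("ECS", "ESS"),
) -> list[SensitivityResult]:
    """Regional fits for every region present plus the area-weighted global
    row, for each requested mode. Only phytane-based estimates are used."""
    pco2 = [
        (e.age, e.pco2_mean, e.pco2_sd)
        for e in phytane_estimates
        if e.biomarker == "phytane"
    ]
    if not pco2:
        raise ValueError("no phytane-based pCO2 estimates supplied")
    out: list[SensitivityResult] = []
    for mode in modes:
        slopes: dict[str, float] = {}
        per_doubling: dict[str, float] = {}
        for region in REGIONS:
            if region not in dsst_by_region:
                continue
            res = regional_sensitivity(
                pco2, dsst_by_region[region], mode, params, region=region
            )
            out.append(res)
            slopes[region] = res.slope
            per_doubling[region] = res.degrees_c_per_doubling
        g_slope = global_weighted(slopes)
        out.append(
            SensitivityResult(
                region="global",
                mode=mode,
                slope=g_slope,
                slope_se=float("nan"),
                intercept=float("nan"),
                r2=0.0,  # not meaningful for the weighted aggregate
                degrees_c_per_doubling=global_weighted(per_doubling),
                n_points=sum(1 for r in out if r.mode == mode and r.region != "global"),
            )
        )
    return out
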