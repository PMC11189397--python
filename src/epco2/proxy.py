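"""Closed-form geochemistry of the epsilon_p pCO2 proxy.

The chain: a biomarker lipid d13C is corrected to biomass (``delta_p``);
the dissolved-CO2 d13C (``delta_d``) comes from foraminiferal calcite
corrected for the temperature-dependent CO2(aq)/HCO3- fractionation;
photosynthetic fractionation is

    epsilon_p = 1000 [ (delta_d + 1000)/(delta_p + 1000) - 1 ]

and CO2(aq) = b / (epsilon_f - epsilon_p) (uM), converted to atmospheric
pCO2 (uatm ~ ppmv) through the Henry's-law solubility K0(T, S).
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "weighted_sterane_delta",
    "biomass_from_lipid",
    "co2aq_hco3_fractionation",
    "delta_co2aq_from_foram",
    "epsilon_p",
    "delta_p_from_epsilon",
    "henry_k0",
    "pco2_point",
    "ProxySaturationError",
    "interpolate_series",
]

# Mook-type CO2(aq)/HCO3- fractionation coefficients, per-mil with T in K:
# eps = MOOK_A - MOOK_B / T
MOOK_A = 24.12
MOOK_B = 9866.0

SST_RANGE = (-2.0, 45.0)
SALINITY_RANGE = (0.0, 45.0)


class ProxySaturationError(ValueError):
    """epsilon_p at or above epsilon_f: CO2(aq) is undefined (proxy saturated)."""


def weighted_sterane_delta(deltas: Sequence[float], fractions: Sequence[float]) -> float:
    """Fractional-abundance-weighted mean d13C of the sterane pool."""
    d = np.asarray(deltas, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if d.size == 0 or d.shape != f.shape:
        raise ValueError("deltas and fractions must be equal-length and non-empty")
    if np.any(f < 0):
        raise ValueError("sterane fractions must be non-negative")
    tot = f.sum()
    if tot <= 0:
        raise ValueError("sterane fractions sum to zero")
    return float((d * f).sum() / tot)


def biomass_from_lipid(delta_lipid: float, offset: float) -> float:
    """Biomass d13C from lipid d13C; biomass is 13C-enriched by ``offset``."""
    if not (np.isfinite(delta_lipid) and np.isfinite(offset)):
        raise ValueError("non-finite input")
    return delta_lipid + offset


def co2aq_hco3_fractionation(sst):
    """Temperature-dependent fractionation of CO2(aq) relative to HCO3-,
    per-mil, negative in the oceanic range (CO2(aq) is 13C-depleted)."""
    t = np.asarray(sst, dtype=float)
    return MOOK_A - MOOK_B / (t + 273.15)


def delta_co2aq_from_foram(delta_foram, sst):
    """d13C of dissolved CO2 from foraminiferal d13C (taken as HCO3-) at a
    given SST, combining the fractionation multiplicatively on the
    (delta + 1000) scale."""
    t = np.asarray(sst, dtype=float)
    if np.any(t < SST_RANGE[0]) or np.any(t > SST_RANGE[1]):
        raise ValueError(f"sst outside {SST_RANGE} degC")
    eps = co2aq_hco3_fractionation(t)
    out = (np.asarray(delta_foram, dtype=float) + 1000.0) * (1.0 + eps / 1000.0) - 1000.0
    return out if out.ndim else float(out)


def epsilon_p(delta_d, delta_p):
    """Photosynthetic carbon-isotope fractionation (per-mil) from the d13C
    of dissolved CO2 and of phytoplankton biomass."""
    dp = np.asarray(delta_p, dtype=float)
    if np.any(dp <= -1000.0):
        raise ValueError("delta_p must exceed -1000 per-mil")
    out = 1000.0 * ((np.asarray(delta_d, dtype=float) + 1000.0) / (dp + 1000.0) - 1.0)
    return out if out.ndim else float(out)


def delta_p_from_epsilon(delta_d, eps_p):
    """Inverse of :func:`epsilon_p` in delta_p (used by the forward model)."""
    out = (np.asarray(delta_d, dtype=float) + 1000.0) / (
        1.0 + np.asarray(eps_p, dtype=float) / 1000.0
    ) - 1000.0
    return out if out.ndim else float(out)


def henry_k0(sst, salinity=35.0):
    """CO2 solubility in seawater, mol kg^-1 atm^-1 (Weiss-type ln-polynomial
    in temperature and salinity). Decreases with both temperature and
    salinity."""
    t = np.asarray(sst, dtype=float)
    s = np.asarray(salinity, dtype=float)
    if np.any(t < SST_RANGE[0]) or np.any(t > SST_RANGE[1]):
        raise ValueError(f"sst outside {SST_RANGE} degC")
    if np.any(s < SALINITY_RANGE[0]) or np.any(s > SALINITY_RANGE[1]):
        raise ValueError(f"salinity outside {SALINITY_RANGE} PSU")
    tk = (t + 273.15) / 100.0
    ln_k0 = (
        -60.2409
        + 93.4517 / tk
        + 23.3585 * np.log(tk)
        + s * (0.023517 - 0.023656 * tk + 0.0047036 * tk**2)
    )
    out = np.exp(ln_k0)
    return out if out.ndim else float(out)


def pco2_point(eps_p: float, b: float, eps_f: float, k0: float) -> tuple[float, float]:
    """CO2(aq) (umol kg^-1) and pCO2 (ppmv) from one epsilon_p value.

    Raises :class:`ProxySaturationError` when epsilon_p >= epsilon_f.
    """
    if b <= 0 or k0 <= 0:
        raise ValueError("b and k0 must be positive")
    denom = eps_f - eps_p
    if denom <= 0:
        raise ProxySaturationError(
            f"epsilon_p={eps_p} >= epsilon_f={eps_f}: pCO2 undefined"
        )
    co2aq = b / denom  # umol kg^-1
    pco2 = co2aq / k0  # (umol kg^-1) / (mol kg^-1 atm^-1) = uatm ~ ppmv
    return co2aq, pco2


def interpolate_series(
    target_ages: Sequence[float],
    series_ages: Sequence[float],
    series_values: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear interpolation of a compilation onto target ages.

    Returns ``(values, in_range)``; targets outside the series span get the
    edge value but are flagged False so callers can exclude them rather
    than trust an extrapolation.
    """
    sa = np.asarray(series_ages, dtype=float)
    sv = np.asarray(series_values, dtype=float)
    if sa.size < 2 or sa.shape != sv.shape:
        raise ValueError("series must have >= 2 equal-length points")
    if np.any(np.diff(sa) <= 0):
        raise ValueError("series ages must be strictly increasing")
    t = np.asarray(target_ages, dtype=float)
    vals = np.interp(t, sa, sv)
    in_range = (t >= sa[0]) & (t <= sa[-1])
    return vals, in_range
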