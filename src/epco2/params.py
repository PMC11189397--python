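"""Proxy constants, uncertainty distributions and forcing parameters.

Defaults are the values used throughout the reconstruction: the lumped
physiological parameter ``b`` (carbon demand per supply, 168 +/- 43 SD
per-mil kg uM^-1, normal), the maximum Rubisco fractionation ``epsilon_f``
(26.5 +/- 1.5 per-mil, uniform), per-biomarker lipid-to-biomass isotopic
offsets, and a +/- 4 degC SD on TEX86-derived sea-surface temperature.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "Distribution",
    "ProxyParams",
    "McConfig",
    "ForcingParams",
    "load_params_yaml",
]


@dataclass(frozen=True)
class Distribution:
    """A one-dimensional uncertainty spec: normal (center, SD) or
    uniform (center +/- half-width)."""

    dist: str  # "normal" | "uniform"
    center: float
    spread: float  # SD for normal, half-width for uniform

    def __post_init__(self) -> None:
        if self.dist not in ("normal", "uniform"):
            raise ValueError(f"unknown distribution kind {self.dist!r}")
        if self.spread < 0:
            raise ValueError("spread must be >= 0")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.spread == 0.0:
            return np.full(size, self.center)
        if self.dist == "normal":
            return rng.normal(self.center, self.spread, size)
        return rng.uniform(self.center - self.spread, self.center + self.spread, size)


def _norm(center: float, sd: float) -> Distribution:
    return Distribution("normal", center, sd)


@dataclass(frozen=True)
class ProxyParams:
    """Constants of the epsilon_p -> pCO2 chain with their uncertainties.

    ``b`` in per-mil kg uM^-1; offsets and epsilon_f in per-mil;
    ``sst_sd`` in degC; ``salinity`` in PSU (used in the Henry's-law
    solubility; the reconstruction holds it at a modern open-ocean 35).
    """

    b: Distribution = field(default_factory=lambda: _norm(168.0, 43.0))
    epsilon_f: Distribution = field(
        default_factory=lambda: Distribution("uniform", 26.5, 1.5)
    )
    offset_phytane: Distribution = field(default_factory=lambda: _norm(3.5, 1.3))
    offset_sterane: Distribution = field(default_factory=lambda: _norm(4.5, 3.0))
    offset_alkenone: Distribution = field(default_factory=lambda: _norm(3.9, 0.4))
    sst_sd: float = 4.0
    salinity: float = 35.0
    # per-draw estimates with epsilon_f - epsilon_p below this floor are
    # rejected as proxy-saturated
    saturation_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.b.center <= 0 or self.epsilon_f.center <= 0:
            raise ValueError("b and epsilon_f centers must be positive")
        if self.sst_sd < 0:
            raise ValueError("sst_sd must be >= 0")

    def offset_for(self, biomarker: str) -> Distribution:
        try:
            return {
                "phytane": self.offset_phytane,
                "sterane": self.offset_sterane,
                "alkenone": self.offset_alkenone,
            }[biomarker]
        except KeyError:
            raise ValueError(f"unknown biomarker {biomarker!r}") from None

    def exact(self) -> "ProxyParams":
        """Copy with all spreads collapsed to zero (deterministic chain)."""
        z = lambda d: replace(d, spread=0.0)
        return replace(
            self,
            b=z(self.b),
            epsilon_f=z(self.epsilon_f),
            offset_phytane=z(self.offset_phytane),
            offset_sterane=z(self.offset_sterane),
            offset_alkenone=z(self.offset_alkenone),
            sst_sd=0.0,
        )


@dataclass(frozen=True)
class McConfig:
    """Monte Carlo settings: number of draws, master seed, and whether the
    interpolated foraminiferal d13C itself is perturbed (off by default)."""

    n_draws: int = 10_000
    seed: int = 0
    perturb_foram: bool = False
    foram_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")


@dataclass(frozen=True)
class ForcingParams:
    """Radiative-forcing constants.

    CO2 forcing uses the polynomial-in-ln formulation
    ``[a1 (C-C0)^2 + b1 |C-C0| + c1 N0 + 5.36] ln(C/C0)`` with C in ppm and
    N0 (background N2O) in ppb. Land-ice forcing is sea level (m) times
    ``li_coeff`` (W m^-3), with sea level linearly interpolated between the
    tie points in ``sea_level_knots``.
    """

    a1: float = 2.4e-7
    b1: float = 7.2e-4
    c1: float = 2.1e-4
    c0_ref: float = 280.0
    n0: float = 270.0
    li_coeff: float = 0.0308
    sea_level_knots: tuple[tuple[float, float], ...] = (
        (0.0, 0.0),
        (3.2, 24.0),
        (10.0, 67.0),
        (14.9, 66.0),
        (19.5, 105.0),
    )
    # forcing per CO2 doubling used to convert K/(W m^-2) slopes into
    # degC per doubling: "full" = rf_co2(2*C0) with this polynomial
    # (~3.907), "simple" = 5.36 ln 2 (~3.715)
    f2x_mode: str = "full"
    dsst_sd_default: float = 1.5

    def __post_init__(self) -> None:
        ages = [a for a, _ in self.sea_level_knots]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("sea_level_knots must be strictly increasing in age")
        if self.c0_ref <= 0:
            raise ValueError("c0_ref must be positive")
        if self.f2x_mode not in ("full", "simple"):
            raise ValueError("f2x_mode must be 'full' or 'simple'")

    @property
    def f2x(self) -> float:
        if self.f2x_mode == "simple":
            return 5.36 * float(np.log(2.0))
        from .forcing import rf_co2  # local import avoids a cycle

        return rf_co2(2.0 * self.c0_ref, self)


def _dist_from_mapping(m: dict) -> Distribution:
    return Distribution(str(m["dist"]), float(m["center"]), float(m["spread"]))


def load_params_yaml(path) -> ProxyParams:
    """Read a ProxyParams YAML file.

    Layout mirrors the dataclass: distribution-valued fields are mappings
    ``{dist: normal|uniform, center: x, spread: y}``; scalar fields are
    plain numbers. Absent keys keep their defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in ("b", "epsilon_f", "offset_phytane", "offset_sterane", "offset_alkenone"):
        if key in raw:
            kwargs[key] = _dist_from_mapping(raw[key])
    for key in ("sst_sd", "salinity", "saturation_floor"):
        if key in raw:
            kwargs[key] = float(raw[key])
    return ProxyParams(**kwargs)
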