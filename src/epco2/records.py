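"""Per-sample record types carried through the reconstruction."""
from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["SampleRecord", "PCO2Estimate", "SensitivityResult", "BIOMARKERS", "REGIONS"]

BIOMARKERS = ("phytane", "sterane", "alkenone")
REGIONS = ("nh_high", "nh_mid", "sh_mid", "tropics")

_D13C_LO, _D13C_HI = -60.0, 10.0


def _check_d13c(name: str, value: float | None) -> None:
    if value is None:
        return
    if not math.isfinite(value) or not (_D13C_LO <= value <= _D13C_HI):
        raise ValueError(f"{name}={value} outside sane d13C range [{_D13C_LO}, {_D13C_HI}] per-mil")


@dataclass
class SampleRecord:
    """One sediment sample: age, biomarker d13C values, GDGT fractional
    abundances, and fields filled downstream (SST, foram-derived d13C).

    d13C values are per-mil VPDB real numbers (-26.8 means depleted).
    Sterane d13C comes as per-compound values with fractional abundances
    that must sum to 1.
    """

    sample_id: str
    age: float  # Ma, larger = older
    depth: float | None = None  # mbsf
    delta_phytane: float | None = None
    sterane_deltas: list[float] | None = None
    sterane_fractions: list[float] | None = None
    delta_alkenone: float | None = None
    gdgt_abundances: dict[str, float] | None = None
    sst: float | None = None  # degC, filled by the TEX86 stage
    sst_provenance: str | None = None  # "tex86h" | "gap-filled"
    delta_foram: float | None = None  # filled by compilation interpolation
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"sample {self.sample_id}: age must be >= 0")
        _check_d13c("delta_phytane", self.delta_phytane)
        _check_d13c("delta_alkenone", self.delta_alkenone)
        if (self.sterane_deltas is None) != (self.sterane_fractions is None):
            raise ValueError(
                f"sample {self.sample_id}: sterane deltas and fractions must come together"
            )
        if self.sterane_deltas is not None:
            if len(self.sterane_deltas) != len(self.sterane_fractions):
                raise ValueError(f"sample {self.sample_id}: sterane lists differ in length")
            for d in self.sterane_deltas:
                _check_d13c("sterane delta", d)
            fr = self.sterane_fractions
            if any(f < 0 for f in fr):
                raise ValueError(f"sample {self.sample_id}: negative sterane fraction")
            if abs(sum(fr) - 1.0) > 1e-6:
                raise ValueError(
                    f"sample {self.sample_id}: sterane fractions sum to {sum(fr):.6f}, not 1"
                )

    def has_biomarker(self, biomarker: str) -> bool:
        if biomarker == "phytane":
            return self.delta_phytane is not None
        if biomarker == "sterane":
            return self.sterane_deltas is not None and len(self.sterane_deltas) > 0
        if biomarker == "alkenone":
            return self.delta_alkenone is not None
        raise ValueError(f"unknown biomarker {biomarker!r}")

    def lipid_delta(self, biomarker: str) -> float:
        """Representative lipid d13C for a biomarker class (abundance-weighted
        for steranes)."""
        from .proxy import weighted_sterane_delta

        if not self.has_biomarker(biomarker):
            raise ValueError(f"sample {self.sample_id} lacks {biomarker} d13C")
        if biomarker == "phytane":
            return float(self.delta_phytane)
        if biomarker == "sterane":
            return weighted_sterane_delta(self.sterane_deltas, self.sterane_fractions)
        return float(self.delta_alkenone)


@dataclass(frozen=True)
class PCO2Estimate:
    """Monte Carlo pCO2 summary for one (sample, biomarker) pair."""

    sample_id: str
    age: float
    biomarker: str
    epsilon_p: float  # per-mil, at distribution centers
    pco2_mean: float  # ppmv
    pco2_sd: float  # ppmv
    pco2_median: float
    pco2_q16: float
    pco2_q84: float
    co2aq: float  # umol kg^-1, at distribution centers
    n_draws: int
    n_retained: int
    frac_rejected: float
    reliable: bool

    def __post_init__(self) -> None:
        if self.pco2_sd < 0:
            raise ValueError("pco2_sd must be >= 0")


@dataclass(frozen=True)
class SensitivityResult:
    """Regional or global temperature sensitivity to forcing.

    ``slope`` is in K per W m^-2; ``degrees_c_per_doubling`` is slope times
    the forcing of one CO2 doubling. ``mode`` is "ESS" (forcing = CO2 only)
    or "ECS" (CO2 + land ice).
    """

    region: str
    mode: str
    slope: float
    slope_se: float
    intercept: float
    r2: float
    degrees_c_per_doubling: float
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("ESS", "ECS"):
            raise ValueError("mode must be 'ESS' or 'ECS'")
        if not (-1e-9 <= self.r2 <= 1 + 1e-9):
            raise ValueError("r2 out of [0, 1]")
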