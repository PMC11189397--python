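"""TEX86-H sea-surface temperatures from isoGDGT fractional abundances.

TEX86 is the ring-distribution ratio of glycerol dibiphytanyl glycerol
tetraethers; the -H calibration SST = 68.4 log10(TEX86) + 38.6 targets
warm-ocean settings. Samples whose minor isoGDGTs fell below detection get
their SST gap-filled by age interpolation from auxiliary-site series.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .proxy import interpolate_series
from .records import SampleRecord

__all__ = [
    "GdgtComposition",
    "tex86_ratio",
    "sst_tex86h",
    "tex86_from_sst",
    "gap_fill_sst",
    "TEX86H_SLOPE",
    "TEX86H_INTERCEPT",
]

log = logging.getLogger(__name__)

TEX86H_SLOPE = 68.4  # degC per log10 unit
TEX86H_INTERCEPT = 38.6  # degC at TEX86 = 1


@dataclass(frozen=True)
class GdgtComposition:
    """Fractional abundances of the TEX86 isoGDGTs; ``cren_prime`` is the
    crenarchaeol regio-isomer."""

    gdgt1: float
    gdgt2: float
    gdgt3: float
    cren_prime: float

    def __post_init__(self) -> None:
        if min(self.gdgt1, self.gdgt2, self.gdgt3, self.cren_prime) < 0:
            raise ValueError("GDGT abundances must be non-negative")


def tex86_ratio(comp: GdgtComposition) -> float:
    """(GDGT-2 + GDGT-3 + cren') / (GDGT-1 + GDGT-2 + GDGT-3 + cren')."""
    num = comp.gdgt2 + comp.gdgt3 + comp.cren_prime
    den = comp.gdgt1 + num
    if den <= 0:
        raise ValueError("all-zero GDGT composition")
    return num / den


def sst_tex86h(ratio: float) -> float:
    """SST (degC) from the TEX86 ratio via the -H log calibration."""
    if not (0.0 < ratio <= 1.0):
        raise ValueError(f"TEX86 ratio {ratio} outside (0, 1]")
    return TEX86H_SLOPE * math.log10(ratio) + TEX86H_INTERCEPT


def tex86_from_sst(sst: float) -> float:
    """Inverse calibration; valid for SST <= the ratio-1 ceiling (38.6 degC)."""
    if sst > TEX86H_INTERCEPT:
        raise ValueError(f"SST {sst} above TEX86-H ceiling {TEX86H_INTERCEPT}")
    return 10.0 ** ((sst - TEX86H_INTERCEPT) / TEX86H_SLOPE)


def _comp_from_record(rec: SampleRecord) -> GdgtComposition | None:
    g = rec.gdgt_abundances
    if not g:
        return None
    try:
        comp = GdgtComposition(
            g.get("gdgt_1", 0.0), g.get("gdgt_2", 0.0), g.get("gdgt_3", 0.0),
            g.get("cren_prime", 0.0),
        )
    except ValueError:
        return None
    if comp.gdgt1 + comp.gdgt2 + comp.gdgt3 + comp.cren_prime <= 0:
        return None
    return comp


def average_aux_series(
    aux_series: Iterable[Sequence[tuple[float, float]]],
) -> list[tuple[float, float]]:
    """Age-wise average of several auxiliary-site (age, SST) series.

    Each series is interpolated onto the union of all ages; at each age the
    mean over series covering that age is taken.
    """
    series = [sorted(s) for s in aux_series if len(s) >= 2]
    if not series:
        raise ValueError("no usable auxiliary series")
    ages = np.unique(np.concatenate([[a for a, _ in s] for s in series]))
    acc = np.zeros(ages.size)
    cnt = np.zeros(ages.size)
    for s in series:
        sa = np.array([a for a, _ in s])
        sv = np.array([v for _, v in s])
        vals, in_rng = interpolate_series(ages, sa, sv)
        acc[in_rng] += vals[in_rng]
        cnt[in_rng] += 1
    keep = cnt > 0
    return list(zip(ages[keep].tolist(), (acc[keep] / cnt[keep]).tolist()))


def gap_fill_sst(
    records: Sequence[SampleRecord],
    aux_series: Sequence[tuple[float, float]] | None = None,
) -> list[SampleRecord]:
    """Fill the ``sst`` field of every record.

    Records with a computable TEX86 ratio get their own TEX86-H SST
    (provenance "tex86h"); records without GDGT data are interpolated from
    ``aux_series`` (provenance "gap-filled", nearest-knot at the edges). A
    record that can be filled neither way keeps ``sst=None`` and is flagged;
    a measured TEX86-H SST is never overwritten.
    """
    out: list[SampleRecord] = []
    aux_ages = aux_vals = None
    if aux_series:
        srt = sorted(aux_series)
        aux_ages = np.array([a for a, _ in srt])
        aux_vals = np.array([v for _, v in srt])
    for rec in records:
        comp = _comp_from_record(rec)
        if comp is not None:
            rec.sst = sst_tex86h(tex86_ratio(comp))
            rec.sst_provenance = "tex86h"
        elif aux_ages is not None and aux_ages.size >= 2:
            vals, in_rng = interpolate_series([rec.age], aux_ages, aux_vals)
            rec.sst = float(vals[0])
            rec.sst_provenance = "gap-filled"
            if not in_rng[0]:
                rec.flags.append("sst-edge-extended")
                log.warning(
                    "sample %s age %.3f outside aux SST coverage; nearest-knot value used",
                    rec.sample_id, rec.age,
                )
        else:
            rec.flags.append("sst-missing")
            log.warning("sample %s: no GDGTs and no aux coverage; SST missing", rec.sample_id)
        out.append(rec)
    return out
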