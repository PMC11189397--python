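"""Monte Carlo propagation of proxy-parameter uncertainty to pCO2.

Every draw resamples the physiological parameter b, the Rubisco
fractionation epsilon_f, the per-biomarker lipid-biomass offset and the
SST, then re-runs the whole chain (delta_p, delta_d, epsilon_p, K0, pCO2).
Draws in which the proxy saturates (epsilon_f - epsilon_p at or below the
floor) are rejected and counted, not truncated. Each (sample, biomarker)
pair gets an independent RNG substream derived from the master seed and the
sample id, so estimates do not depend on processing order.
"""
from __future__ import annotations

import logging
import zlib
from typing import Sequence

import numpy as np

from .params import McConfig, ProxyParams
from .proxy import delta_co2aq_from_foram, epsilon_p, henry_k0, pco2_point
from .records import BIOMARKERS, PCO2Estimate, SampleRecord

__all__ = ["propagate", "propagate_record_set", "substream"]

log = logging.getLogger(__name__)

MAX_REJECT_FRAC = 0.5


def substream(seed: int, sample_id: str, biomarker: str) -> np.random.Generator:
    """Deterministic per-(sample, biomarker) RNG independent of iteration
    order, keyed by a CRC32 of the identifiers."""
    key = zlib.crc32(f"{sample_id}|{biomarker}".encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _center_chain(
    record: SampleRecord, biomarker: str, params: ProxyParams
) -> tuple[float, float, float]:
    """Deterministic chain at distribution centers -> (eps_p, co2aq, pco2)."""
    delta_lipid = record.lipid_delta(biomarker)
    dp = delta_lipid + params.offset_for(biomarker).center
    dd = delta_co2aq_from_foram(record.delta_foram, record.sst)
    ep = epsilon_p(dd, dp)
    k0 = henry_k0(record.sst, params.salinity)
    co2aq, pco2 = pco2_point(ep, params.b.center, params.epsilon_f.center, k0)
    return ep, co2aq, pco2


def propagate(
    record: SampleRecord,
    biomarker: str,
    params: ProxyParams,
    mc: McConfig,
) -> PCO2Estimate:
    """Monte Carlo pCO2 for one sample and biomarker.

    Requires the record to carry that biomarker's d13C, an SST, and an
    interpolated foraminiferal d13C. Reproducible given ``mc.seed``.
    """
    if not record.has_biomarker(biomarker):
        raise ValueError(f"sample {record.sample_id} lacks {biomarker} d13C")
    if record.sst is None:
        raise ValueError(f"sample {record.sample_id} lacks SST")
    if record.delta_foram is None:
        raise ValueError(f"sample {record.sample_id} lacks foram d13C")

    rng = substream(mc.seed, record.sample_id, biomarker)
    n = mc.n_draws
    delta_lipid = record.lipid_delta(biomarker)

    b = params.b.sample(rng, n)
    ef = params.epsilon_f.sample(rng, n)
    offset = params.offset_for(biomarker).sample(rng, n)
    if params.sst_sd > 0:
        sst = rng.normal(record.sst, params.sst_sd, n)
    else:
        sst = np.full(n, float(record.sst))
    # keep SST draws inside the solubility formulation's validity range
    sst = np.clip(sst, -2.0, 45.0)
    dfor = np.full(n, float(record.delta_foram))
    if mc.perturb_foram and mc.foram_sd > 0:
        dfor = dfor + rng.normal(0.0, mc.foram_sd, n)

    dp = delta_lipid + offset
    dd = delta_co2aq_from_foram(dfor, sst)
    ep = epsilon_p(dd, dp)
    k0 = henry_k0(sst, params.salinity)

    ok = (ef - ep) > params.saturation_floor
    ok &= b > 0
    co2aq = np.where(ok, b / np.where(ok, ef - ep, 1.0), np.nan)
    pco2 = co2aq / k0
    ok &= np.isfinite(pco2) & (pco2 > 0)

    retained = pco2[ok]
    n_ret = int(retained.size)
    frac_rej = 1.0 - n_ret / n
    if n_ret == 0:
        raise ValueError(
            f"sample {record.sample_id}/{biomarker}: every draw rejected (saturated)"
        )
    reliable = frac_rej <= MAX_REJECT_FRAC
    if not reliable:
        log.warning(
            "sample %s/%s: %.0f%% of draws rejected; estimate flagged unreliable",
            record.sample_id, biomarker, 100 * frac_rej,
        )

    ep_c, co2aq_c, _ = _center_chain(record, biomarker, params)
    q16, med, q84 = np.percentile(retained, [15.865, 50.0, 84.135])
    return PCO2Estimate(
        sample_id=record.sample_id,
        age=record.age,
        biomarker=biomarker,
        epsilon_p=ep_c,
        pco2_mean=float(retained.mean()),
        pco2_sd=float(retained.std(ddof=1)) if n_ret > 1 else 0.0,
        pco2_median=float(med),
        pco2_q16=float(q16),
        pco2_q84=float(q84),
        co2aq=co2aq_c,
        n_draws=n,
        n_retained=n_ret,
        frac_rejected=frac_rej,
        reliable=reliable,
    )


def propagate_record_set(
    records: Sequence[SampleRecord],
    params: ProxyParams,
    mc: McConfig,
    biomarkers: Sequence[str] = BIOMARKERS,
) -> list[PCO2Estimate]:
    """Per-biomarker estimates for every record with sufficient data.

    Records lacking an SST, a foram d13C or the biomarker are skipped with a
    logged reason. Output order follows input order then biomarker order;
    the per-record substreams make each estimate independent of that order.
    """
    if not records:
        raise ValueError("empty record set")
    out: list[PCO2Estimate] = []
    for rec in records:
        for bm in biomarkers:
            if not rec.has_biomarker(bm):
                continue
            if rec.sst is None or rec.delta_foram is None:
                log.warning(
                    "sample %s/%s skipped: missing %s",
                    rec.sample_id, bm, "SST" if rec.sst is None else "foram d13C",
                )
                continue
            out.append(propagate(rec, bm, params, mc))
    if not out:
        log.warning("no estimable (sample, biomarker) pairs in record set")
    return out
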