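"""Reconstruct a pCO2 record with Monte Carlo uncertainty, end to end.

Generates a synthetic drill-site dataset whose true pCO2 declines from
650 to 280 ppmv over 15 -> 0.3 Ma, runs the full reconstruction (TEX86-H
SSTs with gap-filling, foram-compilation interpolation, 5000-draw Monte
Carlo through the epsilon_p chain) and compares the recovered record with
the known truth at both ends.
"""
import tempfile
from pathlib import Path

from epco2 import McConfig, RunConfig, TruthScenario, generate_dataset, run_pipeline

scenario = TruthScenario(seed=42, n_samples=35)
dataset = generate_dataset(scenario)

with tempfile.TemporaryDirectory() as td:
    paths = dataset.write(td)
    cfg = RunConfig(
        samples=paths["samples"],
        foram=paths["foram"],
        aux_sst=paths["aux_sst"],
        outdir=Path(td) / "out",
    )
    cfg.mc = McConfig(n_draws=5000, seed=42)
    result = run_pipeline(cfg, write=False)

truth = dataset.truth.set_index("sample_id")
phytane = sorted(
    (e for e in result.estimates if e.biomarker == "phytane"), key=lambda e: e.age
)
print(f"{len(result.estimates)} estimates from {len(result.records)} samples\n")
print("age (Ma)   pCO2 mean+/-SD (ppmv)   median   truth")
for est in (phytane[0], phytane[len(phytane) // 2], phytane[-1]):
    t = truth.loc[est.sample_id, "pco2_true"]
    print(
        f"{est.age:7.2f}   {est.pco2_mean:7.0f} +/- {est.pco2_sd:4.0f}"
        f"          {est.pco2_median:6.0f}   {t:5.0f}"
    )
print()
print("The Monte Carlo mean sits above the truth at the old, high-pCO2 end:")
print("the 1/(eps_f - eps_p) map is convex, so compounded parameter")
print("uncertainty skews the draw distribution right. The median tracks the")
print("central chain; the SD is dominated by the b-parameter uncertainty.")
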