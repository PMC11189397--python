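"""Estimate Earth-system and equilibrium climate sensitivity.

Builds the full synthetic bundle (pCO2 samples plus regional dSST series
written with known per-region sensitivities), runs the pipeline, and
prints the regional and area-weighted global sensitivity table in both
K/(W m^-2) and degC per CO2 doubling. Also shows the pure aggregation
step on a set of published-style regional values.
"""
import tempfile
from pathlib import Path

from epco2 import McConfig, RunConfig, TruthScenario, generate_dataset, global_weighted, run_pipeline

scenario = TruthScenario(seed=7)  # dSST written with ECS slopes 3.1/2.3/2.2/1.3
dataset = generate_dataset(scenario)

with tempfile.TemporaryDirectory() as td:
    paths = dataset.write(td)
    cfg = RunConfig(
        samples=paths["samples"], foram=paths["foram"],
        dsst=paths["dsst"], aux_sst=paths["aux_sst"], outdir=Path(td) / "out",
    )
    cfg.mc = McConfig(n_draws=5000, seed=7)
    result = run_pipeline(cfg, write=False)

print("region    mode   K/Wm2    r2     degC/2xCO2   (truth slope)")
for r in result.sensitivity:
    truth = scenario.slopes.get(r.region, None) if r.mode == "ECS" else None
    extra = f"   ({truth})" if truth is not None else ""
    print(
        f"{r.region:9s} {r.mode}  {r.slope:6.2f}  {r.r2:5.2f}   {r.degrees_c_per_doubling:8.2f}{extra}"
    )
print()
print("ECS regresses dSST on CO2 + land-ice forcing; ESS on CO2 forcing")
print("alone, so ESS slopes come out higher wherever sea level varied.")
print("Recovered ECS slopes run above the written ones because the fit is")
print("told the full Monte Carlo pCO2 SD as an independent per-sample")
print("x-error, which overstates the actual scatter in this synthetic world.")
print()

# the aggregation step alone: area weights 50.0% tropics, 36.6% mid, 13.4% high
ess = {"tropics": 11.1, "nh_mid": 16.0, "sh_mid": 16.1, "nh_high": 18.8}
print(f"area-weighted global of {ess}:")
print(f"  {global_weighted(ess):.2f} degC per CO2 doubling")
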