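"""Forward-model generator: determinism, invariants, truth recovery."""
import numpy as np
import pandas as pd
import pytest

from epco2.forcing import regional_sensitivity
from epco2.io import RunConfig
from epco2.montecarlo import propagate
from epco2.params import McConfig, ProxyParams
from epco2.pipeline import run_pipeline
from epco2.records import SampleRecord
from epco2.synth import TruthScenario, generate_dataset, generate_sensitivity_truth
from epco2.tex86 import gap_fill_sst


class TestGenerateDataset:
    def test_deterministic_given_seed(self):
        a = generate_dataset(TruthScenario(seed=3))
        b = generate_dataset(TruthScenario(seed=3))
        for name in ("samples", "foram", "dsst", "sea_level", "aux_sst", "truth"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_different_seed_differs(self):
        a = generate_dataset(TruthScenario(seed=3))
        b = generate_dataset(TruthScenario(seed=4))
        assert not a.samples["d13c_phytane"].equals(b.samples["d13c_phytane"])

    def test_sterane_fractions_sum_to_one(self, default_dataset):
        s = default_dataset.samples
        tot = s[["frac_sterane_c27", "frac_sterane_c28", "frac_sterane_c29"]].sum(axis=1)
        assert np.allclose(tot, 1.0, atol=1e-9)

    def test_gdgt_nonnegative_and_ratio_in_range(self, default_dataset):
        s = default_dataset.samples.dropna(subset=["gdgt_1"])
        g = s[["gdgt_1", "gdgt_2", "gdgt_3", "cren_prime"]].to_numpy()
        assert np.all(g >= 0)
        ratio = g[:, 1:].sum(axis=1) / g.sum(axis=1)
        assert np.all((ratio > 0) & (ratio <= 1))

    def test_alkenones_only_recent(self, default_dataset):
        s = default_dataset.samples
        assert s.loc[s.age_ma > 4.0, "d13c_alkenone"].isna().all()
        assert s.loc[s.age_ma <= 4.0, "d13c_alkenone"].notna().all()

    def test_oldest_samples_lack_gdgts(self, default_dataset):
        s = default_dataset.samples.sort_values("age_ma")
        assert s.tail(3)["gdgt_1"].isna().all()
        assert s.head(5)["gdgt_1"].notna().all()

    def test_saturating_scenario_rejected(self):
        # absurdly high pCO2 drives epsilon_p through epsilon_f... the other
        # direction: tiny pCO2 saturates nothing, huge CO2 is fine; epsilon_p
        # >= epsilon_f happens when co2aq is large, i.e. eps_f - b/co2aq -> eps_f
        sc = TruthScenario(pco2_curve=lambda a: np.full_like(np.asarray(a, float), 2e5))
        with pytest.raises(ValueError, match="saturat"):
            generate_dataset(sc)

    def test_d13c_trend_rises_toward_present(self, noiseless_dataset):
        s = noiseless_dataset.samples.sort_values("age_ma")
        assert s["d13c_phytane"].iloc[0] > s["d13c_phytane"].iloc[-1]


class TestRoundTrip:
    def test_noiseless_pipeline_recovers_truth(self, noiseless_config, noiseless_dataset):
        res = run_pipeline(noiseless_config, write=False)
        assert res.status == "success"
        truth = noiseless_dataset.truth.set_index("sample_id")
        for est in res.estimates:
            t = truth.loc[est.sample_id]
            assert est.pco2_mean == pytest.approx(t.pco2_true, rel=1e-6)
            assert est.epsilon_p == pytest.approx(t.epsilon_p_true, rel=1e-6)
        # SSTs recovered exactly too (TEX86 inverse or exact interpolation)
        for rec in res.records:
            t = truth.loc[rec.sample_id]
            # CSV serialisation keeps 10 significant digits
            assert rec.sst == pytest.approx(t.sst_true, abs=1e-6)

    def test_noiseless_sensitivity_recovers_slopes(self, noiseless_config, noiseless_scenario):
        res = run_pipeline(noiseless_config, write=False)
        got = {r.region: r.slope for r in res.sensitivity if r.mode == "ECS"}
        for region, slope in noiseless_scenario.slopes.items():
            # residual error comes only from the 0.125-Ma dSST binning
            assert got[region] == pytest.approx(slope, rel=1e-3)

    def test_noisy_recovery_within_two_sd(self):
        """Monte Carlo mean within 2 SD of truth for >= 90% of samples,
        aggregated over replicate generation seeds."""
        hits = total = 0
        params = ProxyParams()
        for seed in range(12):
            ds = generate_dataset(TruthScenario(seed=seed, n_samples=12))
            truth = ds.truth.set_index("sample_id")
            f_ages = ds.foram["age_ma"].to_numpy()
            f_vals = ds.foram["value"].to_numpy()
            recs = []
            for row in ds.samples.itertuples():
                rec = SampleRecord(
                    sample_id=row.sample_id, age=row.age_ma,
                    delta_phytane=row.d13c_phytane,
                    gdgt_abundances=None if np.isnan(row.gdgt_1) else {
                        "gdgt_1": row.gdgt_1, "gdgt_2": row.gdgt_2,
                        "gdgt_3": row.gdgt_3, "cren_prime": row.cren_prime,
                    },
                )
                rec.delta_foram = float(np.interp(rec.age, f_ages, f_vals))
                recs.append(rec)
            aux = list(zip(ds.aux_sst["age_ma"], ds.aux_sst["value"]))
            recs = gap_fill_sst(recs, aux)
            for rec in recs:
                est = propagate(rec, "phytane", params, McConfig(n_draws=2000, seed=seed))
                t = truth.loc[rec.sample_id, "pco2_true"]
                total += 1
                hits += abs(est.pco2_mean - t) <= 2 * est.pco2_sd
        assert hits / total >= 0.90


class TestSensitivityTruth:
    def test_binned_to_eighth_ma(self):
        df = generate_sensitivity_truth(TruthScenario(seed=0))
        ages = np.sort(df.loc[df.region == "tropics", "age_ma"].unique())
        steps = np.diff(ages)[1:-1]  # interior steps (edges clipped to range)
        assert np.allclose(steps, 0.125)

    def test_zero_slope_ci_covers_zero(self):
        sc = TruthScenario(seed=5, slopes={"nh_mid": 0.0})
        df = generate_sensitivity_truth(sc)
        sub = df[df.region == "nh_mid"]
        series = list(zip(sub.age_ma, sub.dsst_c, sub.dsst_sd))
        pco2 = [(a, float(sc.pco2_curve(a)), 0.0) for a in np.linspace(0.5, 14.5, 20)]
        res = regional_sensitivity(pco2, series, "ECS", region="nh_mid")
        assert abs(res.slope) <= 2 * res.slope_se

    def test_written_files_identical_on_rerun(self, tmp_path):
        p1 = generate_dataset(TruthScenario(seed=8)).write(tmp_path / "a")
        p2 = generate_dataset(TruthScenario(seed=8)).write(tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()
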