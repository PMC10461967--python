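"""Population sampling, pipeline consistency and sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

from ricp.models import SAMPLED_CONDUCTANCES
from ricp.population import (SAMPLED_PARAMETERS, PopulationSpec, gkr_scan,
                             run_cell, run_population, sample_population,
                             spearman_sensitivity)


class TestSampling:
    def test_count_and_range(self):
        pop = sample_population(PopulationSpec(n=40, seed=1))
        assert len(pop) == 40
        for params, art in pop:
            for k in SAMPLED_CONDUCTANCES:
                assert 0.25 <= params.multipliers[k] <= 4.0
            assert params.C_m == 45.0  # model keeps the configured cell
            assert 0.25 * 45.0 <= art.C_m <= 4.0 * 45.0
            assert 0.25 * 20.0 <= art.R_access <= 4.0 * 20.0

    def test_seed_reproducibility(self):
        a = sample_population(PopulationSpec(n=10, seed=99))
        b = sample_population(PopulationSpec(n=10, seed=99))
        for (pa, aa), (pb, ab) in zip(a, b):
            assert pa.multipliers == pb.multipliers
            assert pa.C_m == pb.C_m and aa.R_access == ab.R_access

    def test_degenerate_range_is_baseline(self):
        (params, art), = sample_population(
            PopulationSpec(n=1, seed=0, range=(1.0, 1.0)))
        assert all(v == 1.0 for k, v in params.multipliers.items()
                   if k in SAMPLED_CONDUCTANCES)
        assert params.C_m == 45.0 and art.C_m == 45.0
        assert art.R_access == 20.0

    def test_uniform_distribution_supported(self):
        pop = sample_population(
            PopulationSpec(n=30, seed=2, distribution="uniform"))
        f = [p.multipliers["I_Kr"] for p, _ in pop]
        assert min(f) >= 0.25 and max(f) <= 4.0


class TestRunPopulation:
    def test_single_baseline_cell_all_features_finite(self, protocol):
        pop = sample_population(PopulationSpec(n=1, seed=0,
                                               range=(1.0, 1.0)))
        tab = run_population(pop, protocol)
        assert len(tab) == 1
        row = tab.iloc[0]
        for lab in ("I_6mV", "I_Kr", "I_CaL", "I_Na", "I_to", "I_K1",
                    "I_f", "I_Ks"):
            assert np.isfinite(row[lab])
        assert not row["failed"]

    def test_row_features_match_standalone_extraction(self, protocol):
        """Pipeline rows equal extract_vc_features run on the same trace."""
        from ricp.engine import simulate_vc
        from ricp.features import extract_vc_features
        from ricp.protocol import ricp_timepoints
        (params, art), = sample_population(PopulationSpec(n=1, seed=5))
        row = run_cell(params, art, protocol)
        trace = simulate_vc(params, art, protocol, dt=0.5, rtol=1e-6)
        feats = extract_vc_features(trace, ricp_timepoints())
        for lab, val in feats.items():
            assert row[lab] == pytest.approx(val, abs=1e-10)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            run_population([])


class TestSpearmanSensitivity:
    @staticmethod
    def table(n=60, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({f"mult_{k}": rng.uniform(0.25, 4.0, n)
                           for k in SAMPLED_CONDUCTANCES})
        df["C_m"] = rng.uniform(11.0, 180.0, n)
        df["R_access"] = rng.uniform(5.0, 80.0, n)
        for lab in ("I_6mV", "I_Kr", "I_CaL", "I_Na", "I_to", "I_K1",
                    "I_f", "I_Ks"):
            df[lab] = rng.normal(size=n)
        return df

    def test_monotone_dependence_gives_rho_one(self):
        df = self.table()
        df["I_Kr"] = np.exp(df["mult_I_Kr"])
        sens = spearman_sensitivity(df)
        assert sens.loc["mult_I_Kr", "I_Kr"] == pytest.approx(1.0)

    def test_independent_pairs_have_small_rho(self):
        rng = np.random.default_rng(1)
        df = self.table(n=500)
        df["I_Ks"] = rng.normal(size=500)  # independent of everything
        sens = spearman_sensitivity(df)
        assert abs(sens.loc["mult_I_Na", "I_Ks"]) < 0.2

    def test_constant_column_is_nan(self):
        df = self.table()
        df["I_6mV"] = 1.0
        sens = spearman_sensitivity(df)
        assert np.isnan(sens.loc["mult_I_Kr", "I_6mV"])

    def test_requires_ten_rows(self):
        with pytest.raises(ValueError):
            spearman_sensitivity(self.table(n=5))


class TestGkrScan:
    def test_unit_scale_matches_direct_simulation(self, baseline_artifact):
        from ricp.engine import simulate_cc
        from ricp.features import ap_features
        from ricp.models import ModelParameters
        df = gkr_scan([1.0], baseline_artifact)
        direct = ap_features(simulate_cc(ModelParameters(model_id="kernik"),
                                         baseline_artifact, 10_000.0,
                                         rtol=1e-6))
        assert df.MP.iloc[0] == pytest.approx(direct.MP, abs=1e-6)
        assert df.g_Kr_nS_per_pF.iloc[0] == pytest.approx(0.218025)

    def test_nonpositive_scale_rejected(self, baseline_artifact):
        with pytest.raises(ValueError):
            gkr_scan([-0.5], baseline_artifact)


class TestEnvelope:
    def test_value_above_population_max_is_flagged(self, kernik_population_table):
        """A current 5 A/F above the population maximum at the I_6mV point
        lies outside the population range."""
        from ricp.population import outside_population_range
        vals = kernik_population_table["I_6mV"]
        assert outside_population_range(vals.max() + 5.0, vals)
        assert not outside_population_range(vals.median(), vals)

    def test_baseline_inside_small_population_envelope(self, protocol):
        """The baseline cell's recorded trace lies (almost everywhere)
        inside the min-max envelope of a sampled population."""
        from ricp.engine import simulate_vc
        from ricp.models import ModelParameters
        from ricp.artifact import ArtifactParameters
        from ricp.population import (PopulationSpec, sample_population,
                                     trace_envelope)
        pop = sample_population(PopulationSpec(n=12, model_id="paci",
                                               seed=5))
        traces = [simulate_vc(p, a, protocol, dt=1.0, rtol=1e-6)
                  for p, a in pop]
        lo, hi = trace_envelope(traces)
        base = simulate_vc(ModelParameters(model_id="paci"),
                           ArtifactParameters(), protocol, dt=1.0,
                           rtol=1e-6)
        inside = (base.value >= lo - 0.1) & (base.value <= hi + 0.1)
        assert inside.mean() > 0.98

    def test_own_conductance_sensitivity_sanity(self, kernik_population_table):
        """Each segment's |rho| against its own conductance exceeds its
        |rho| against at least half of the other multipliers."""
        from ricp.population import spearman_sensitivity
        from ricp.models import SAMPLED_CONDUCTANCES
        sens = spearman_sensitivity(kernik_population_table)
        for seg in ("I_Na", "I_CaL", "I_Kr", "I_Ks", "I_to", "I_K1", "I_f"):
            own = abs(sens.loc[f"mult_{seg}", seg])
            others = [abs(sens.loc[f"mult_{k}", seg])
                      for k in SAMPLED_CONDUCTANCES if k != seg]
            beaten = sum(own > o for o in others)
            assert beaten >= len(others) / 2, seg
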