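"""Effective kinetics, three-stage parameters and timescale diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stochmet import (
    RateConstants,
    IrreversibleRegimeError,
    effective_kinetics,
    three_stage_params,
    timescale_diagnostics,
    load_rate_constants,
    preset,
    effective_preset,
    PRESETS,
)

from conftest import random_rate_constants


class TestEffectiveKinetics:
    def test_nominal_parameters_give_reference_pair(self, table1):
        ek = effective_kinetics(table1)
        assert ek.lambda_inf == pytest.approx(1080.0, rel=1e-12)
        assert ek.K == pytest.approx(8.0, rel=1e-12)
        assert ek.epsilon == pytest.approx(3000.0 / 4000.0, rel=1e-12)

    def test_saturation_identity(self, table1):
        # lambda_inf / K = epsilon * k_cat / k_c
        ek = effective_kinetics(table1)
        assert ek.lambda_inf / ek.K == pytest.approx(
            ek.epsilon * table1.k_cat / table1.k_c, rel=1e-12)
        assert ek.lambda_inf / ek.K == pytest.approx(135.0, rel=1e-12)

    def test_lambda_inf_linear_in_kcat_K_unchanged(self, table1):
        ek = effective_kinetics(table1)
        ek2 = effective_kinetics(table1.with_(k_cat=2 * table1.k_cat))
        assert ek2.lambda_inf == pytest.approx(2 * ek.lambda_inf, rel=1e-12)
        assert ek2.K == ek.K

    def test_irreversible_regime_signalled(self, table1):
        with pytest.raises(IrreversibleRegimeError):
            effective_kinetics(table1.with_(k_rev=0.0))

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_identity_property_random_parameters(self, seed):
        rc = random_rate_constants(np.random.default_rng(seed))
        if rc.k_rev == 0:
            return
        ek = effective_kinetics(rc)
        assert ek.lambda_inf > 0 and ek.K > 0
        assert 0 < ek.epsilon < 1
        assert ek.lambda_inf / ek.K == pytest.approx(
            ek.epsilon * rc.k_cat / rc.k_c, rel=1e-12)

    @given(st.integers(0, 10_000), st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_joint_kcat_krev_scaling_only_moves_K(self, seed, factor):
        # scaling k_cat and k_rev together keeps their ratio, so lambda_inf
        # is fixed and K scales inversely -- the construction used to sweep
        # K at constant lambda_inf
        rc = random_rate_constants(np.random.default_rng(seed))
        ek = effective_kinetics(rc)
        ek2 = effective_kinetics(rc.with_(k_cat=rc.k_cat * factor,
                                          k_rev=rc.k_rev * factor))
        assert ek2.lambda_inf == pytest.approx(ek.lambda_inf, rel=1e-12)
        assert ek2.K == pytest.approx(ek.K / factor, rel=1e-12)

    def test_scaled_binding_is_pmm_invariant(self, table1):
        ek = effective_kinetics(table1)
        ek2 = effective_kinetics(table1.scaled_binding(50.0))
        assert ek2.lambda_inf == pytest.approx(ek.lambda_inf, rel=1e-12)
        assert ek2.K == pytest.approx(ek.K, rel=1e-12)
        assert ek2.epsilon == pytest.approx(ek.epsilon, rel=1e-12)


class TestThreeStageParams:
    def test_nominal_dimensionless_groups(self, table1):
        tsp = three_stage_params(table1)
        assert tsp.gamma == pytest.approx(120.0, rel=1e-12)
        assert tsp.a == pytest.approx(108.0, rel=1e-12)
        assert tsp.b == pytest.approx(1.0, rel=1e-12)

    def test_root_identities(self, table1):
        tsp = three_stage_params(table1)
        assert tsp.alpha_plus + tsp.alpha_minus == pytest.approx(
            tsp.a + tsp.gamma, rel=1e-9)
        assert tsp.alpha_plus * tsp.alpha_minus == pytest.approx(
            tsp.a * table1.k_on / table1.delta, rel=1e-9)
        assert tsp.alpha_plus >= tsp.alpha_minus >= 0
        # the roots bracket gamma, which keeps the hypergeometric series
        # positive-termed
        assert tsp.alpha_minus <= tsp.gamma <= tsp.alpha_plus

    def test_silent_promoter_gives_zero_root(self, table1):
        tsp = three_stage_params(table1.with_(k_on=0.0))
        assert tsp.alpha_minus == 0.0
        assert tsp.alpha_plus == pytest.approx(tsp.a + tsp.gamma, rel=1e-12)
        assert tsp.mean_protein == 0.0

    def test_mean_protein_formula(self, table1):
        tsp = three_stage_params(table1)
        expected = (table1.k_tx / table1.delta) * (table1.k_tl / table1.k_deg) \
            * table1.k_on / (table1.k_on + table1.k_off)
        assert tsp.mean_protein == pytest.approx(expected, rel=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_vieta_property_random_parameters(self, seed):
        rc = random_rate_constants(np.random.default_rng(seed))
        tsp = three_stage_params(rc)
        prod = tsp.a * rc.k_on / rc.delta
        assert tsp.alpha_plus * tsp.alpha_minus == pytest.approx(
            prod, rel=1e-9, abs=1e-12)


class TestTimescaleDiagnostics:
    def test_nominal_separation_clean(self, table1):
        rep = timescale_diagnostics(table1)
        assert rep.fast == pytest.approx(4000.0)
        assert rep.fast > 10 * table1.k_cat
        assert rep.slow == min(rep.fast, rep.intermediate, rep.slow)
        assert rep.ok

    def test_marginal_binding_scale_flagged(self, table1):
        # k_1 n_s + k_m1 = 5 k_cat -> below the 10x default factor
        rc = table1.with_(k_1=3.6 * 5 / 2 / 3000, k_m1=3.6 * 5 / 2)
        rep = timescale_diagnostics(rc)
        assert not rep.ok
        assert any("fast-binding" in f for f in rep.flags)

    def test_configurable_factor(self, table1):
        rc = table1.scaled_binding(200.0)  # fast scale 20/s vs 3.62/s
        assert not timescale_diagnostics(rc, factor=10.0).ok
        assert timescale_diagnostics(rc, factor=5.0).ok


class TestConfigAndPresets:
    def test_doubling_time_of_nominal_dilution(self, table1):
        # delta = 2.5e-4 /s corresponds to ~46 min doubling
        assert table1.doubling_time / 60.0 == pytest.approx(46.2, abs=0.5)

    def test_yaml_and_json_round_trip(self, table1, tmp_path):
        import json
        import yaml
        d = table1.to_dict()
        p_yaml = tmp_path / "rc.yaml"
        p_yaml.write_text(yaml.safe_dump(d))
        p_json = tmp_path / "rc.json"
        p_json.write_text(json.dumps(d))
        assert load_rate_constants(p_yaml) == table1
        assert load_rate_constants(p_json) == table1

    def test_config_rejects_missing_and_unknown_keys(self, table1, tmp_path):
        import yaml
        d = table1.to_dict()
        d.pop("k_cat")
        d["bogus"] = 1.0
        p = tmp_path / "rc.yaml"
        p.write_text(yaml.safe_dump(d))
        with pytest.raises(ValueError, match="k_cat"):
            load_rate_constants(p)

    def test_all_presets_valid_and_fig1c_kinetics_fixed(self):
        for name, rc in PRESETS.items():
            assert rc.n_s > 0
        for name in ("fig1c_fast_off", "fig1c_balanced", "fig1c_slow_off"):
            ek = effective_kinetics(preset(name))
            assert (ek.lambda_inf, ek.K) == effective_preset("fig1c")

    def test_invalid_parameters_rejected(self, table1):
        with pytest.raises(ValueError):
            RateConstants(**{**table1.to_dict(), "k_cat": -1.0})
        with pytest.raises(ValueError):
            RateConstants(**{**table1.to_dict(), "n_s": 0})
        # k_rev, k_on, k_off may be zero
        RateConstants(**{**table1.to_dict(), "k_rev": 0.0, "k_on": 0.0})
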