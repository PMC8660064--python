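import dataclasses

import pytest

from sedem.errors import InputValidationError
from sedem.linkage import rank_correlation
from sedem.parameters import assemble_basic_parameters
from sedem.synthetic import (
    DEFAULT_EXPECTED_SIGNS,
    EffectConfig,
    ResponseEffect,
    TrialDesign,
    build_design,
    full_factorial,
    recovery_check,
    simulate_study,
    simulate_trial,
)


class TestBuildDesign:
    def test_thirteen_rows(self):
        assert len(build_design()) == 13

    def test_trial5_levels(self):
        d = {t.trial_id: t for t in build_design()}
        assert d["Trial-5"].granulation_time_s == 60.0
        assert d["Trial-5"].binder_concentration_pct == 15.0
        assert (d["Trial-5"].time_coded, d["Trial-5"].binder_coded) == (1, 1)

    def test_five_center_replicates(self):
        centers = [
            t.trial_id for t in build_design() if t.time_coded == 0 and t.binder_coded == 0
        ]
        assert centers == ["Trial-1", "Trial-3", "Trial-4", "Trial-6", "Trial-7"]

    def test_level_count_enforced(self):
        with pytest.raises(InputValidationError):
            build_design(time_levels=(30.0, 60.0))

    def test_full_factorial(self):
        runs = full_factorial((30.0, 45.0, 60.0), (5.0, 10.0, 15.0))
        assert len(runs) == 9
        assert len({(t.time_coded, t.binder_coded) for t in runs}) == 9


class TestSimulateTrial:
    def test_deterministic_for_fixed_seed(self):
        design = build_design()[4]
        a = simulate_trial(design, EffectConfig(), seed=7, trial_index=4)
        b = simulate_trial(design, EffectConfig(), seed=7, trial_index=4)
        assert a == b

    def test_different_seeds_differ(self):
        design = build_design()[4]
        a = simulate_trial(design, EffectConfig(), seed=7, trial_index=4)
        b = simulate_trial(design, EffectConfig(), seed=8, trial_index=4)
        assert a != b

    def test_outputs_satisfy_invariants(self):
        # constructing the records runs all dataclass validation
        for i, design in enumerate(build_design()):
            raw, qc = simulate_trial(design, EffectConfig(), seed=3, trial_index=i)
            params = assemble_basic_parameters(raw)
            assert params.Da <= params.Dc
            assert qc.friability_mass_after <= qc.friability_mass_before

    def test_zero_noise_zero_slopes_constant(self):
        cfg = EffectConfig().scaled_noise(0.0)
        cfg = EffectConfig(
            responses={
                k: dataclasses.replace(r, binder_slope=0.0, time_slope=0.0)
                for k, r in cfg.responses.items()
            },
            replicate_cv=0.0,
        )
        outs = [
            simulate_trial(d, cfg, seed=1, trial_index=i)
            for i, d in enumerate(build_design())
        ]
        base_raw, base_qc = outs[0]
        for raw, qc in outs[1:]:
            assert dataclasses.replace(raw, batch_id="x") == dataclasses.replace(
                base_raw, batch_id="x"
            )
            assert dataclasses.replace(qc, trial_id="x") == dataclasses.replace(
                base_qc, trial_id="x"
            )

    def test_noiseless_exactly_linear_in_coded_levels(self):
        cfg = EffectConfig().scaled_noise(0.0)
        study = {
            d.trial_id: simulate_trial(d, cfg, seed=0, trial_index=i)
            for i, d in enumerate(build_design())
        }
        icd = {t: s[0].compact_strengths[0] for t, s in study.items()}
        eff = cfg.responses["cohesion_N"]
        # Trial-13 is (time 0, binder +1); Trial-11 is (time +1, binder 0)
        assert icd["Trial-13"] - icd["Trial-1"] == pytest.approx(eff.binder_slope, abs=1e-9)
        assert icd["Trial-11"] - icd["Trial-1"] == pytest.approx(eff.time_slope, abs=1e-9)
        assert icd["Trial-5"] - icd["Trial-1"] == pytest.approx(
            eff.binder_slope + eff.time_slope, abs=1e-9
        )

    def test_center_replicates_differ_only_by_noise(self):
        cfg = EffectConfig().scaled_noise(0.0)
        study = simulate_study(cfg, seed=5)
        centers = [
            (raw, qc) for d, raw, qc in study if d.time_coded == 0 and d.binder_coded == 0
        ]
        first_raw = dataclasses.replace(centers[0][0], batch_id="c")
        for raw, _ in centers[1:]:
            assert dataclasses.replace(raw, batch_id="c") == first_raw

    def test_subseed_stability_when_adding_trials(self):
        cfg = EffectConfig()
        short = simulate_study(cfg, seed=11, design=build_design()[:5])
        long = simulate_study(cfg, seed=11, design=build_design())
        assert [s[1] for s in short] == [s[1] for s in long[:5]]

    def test_binder_cohesion_correlation_positive(self):
        study = simulate_study(EffectConfig(), seed=42)
        binder = [d.binder_coded for d, _, _ in study]
        icd = [assemble_basic_parameters(raw).Icd for _, raw, _ in study]
        assert rank_correlation(binder, icd) > 0


class TestRecoveryCheck:
    def test_noiseless_recovers_all_signs(self):
        study = simulate_study(EffectConfig().scaled_noise(0.0), seed=0)
        result = recovery_check(study)
        assert result.all_passed
        assert len(result.checks) == len(DEFAULT_EXPECTED_SIGNS)

    def test_inverted_slopes_invert_signs(self):
        cfg = EffectConfig().scaled_noise(0.0).with_inverted_slopes()
        result = recovery_check(simulate_study(cfg, seed=0))
        assert not result.all_passed
        assert all(not c.passed for c in result.checks)
        inverted_expectations = [(f, r, -s) for f, r, s in DEFAULT_EXPECTED_SIGNS]
        assert recovery_check(simulate_study(cfg, seed=0), inverted_expectations).all_passed

    def test_needs_nine_trials(self):
        study = simulate_study(EffectConfig(), seed=0)[:5]
        with pytest.raises(InputValidationError):
            recovery_check(study)

    def test_moderate_noise_mostly_recovers(self):
        hits = sum(
            recovery_check(simulate_study(EffectConfig(), seed=s)).all_passed
            for s in range(10)
        )
        assert hits >= 9


class TestResponseEffect:
    def test_negative_sd_rejected(self):
        with pytest.raises(InputValidationError):
            ResponseEffect(1.0, sd=-0.1)

    def test_truncation_to_bounds(self):
        import numpy as np

        eff = ResponseEffect(10.0, binder_slope=100.0, bounds=(0.0, 20.0))
        d = TrialDesign("t", 0, 1, 45.0, 15.0)
        assert eff.value(d, np.random.default_rng(0)) == 20.0
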