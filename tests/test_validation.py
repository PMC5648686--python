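"""Modeling efficiency, wastage estimation, cross-validation, ablations."""

import dataclasses
import math

import numpy as np
import pytest

from renlichen.pasture import WastageParameters, pack_districts, predict_final_biomass
from renlichen.validation import (
    AblationSpec,
    OptimizerConfig,
    estimate_wastage,
    loocv,
    modeling_efficiency,
    pearson_r,
    run_ablation,
)

FAST_OPT = OptimizerConfig(n_starts=4, maxfev=200)


def ef_oracle(obs, pred):
    """Independent two-pass evaluation with compensated summation."""
    mean = math.fsum(obs) / len(obs)
    sse = math.fsum((o - p) ** 2 for o, p in zip(obs, pred))
    sst = math.fsum((o - mean) ** 2 for o in obs)
    return 1.0 - sse / sst


def pearson_oracle(obs, pred):
    mo = math.fsum(obs) / len(obs)
    mp = math.fsum(pred) / len(pred)
    cov = math.fsum((o - mo) * (p - mp) for o, p in zip(obs, pred))
    vo = math.fsum((o - mo) ** 2 for o in obs)
    vp = math.fsum((p - mp) ** 2 for p in pred)
    return cov / math.sqrt(vo * vp)


class TestModelingEfficiency:
    def test_perfect_fit(self):
        obs = np.array([1.0, 2.0, 5.0])
        assert modeling_efficiency(obs, obs) == 1.0

    def test_mean_predictor_baseline(self):
        obs = np.array([100.0, 200.0, 300.0])
        assert modeling_efficiency(obs, np.full(3, obs.mean())) == 0.0

    def test_hand_value(self):
        obs = (100.0, 200.0, 300.0)
        pred = (110.0, 190.0, 310.0)
        assert modeling_efficiency(obs, pred) == pytest.approx(0.985)

    def test_identical_observations_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            modeling_efficiency([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            modeling_efficiency([1.0], [1.0])

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            n = rng.integers(3, 30)
            obs = rng.normal(300, 150, n)
            pred = obs + rng.normal(0, 60, n)
            assert modeling_efficiency(obs, pred) == pytest.approx(
                ef_oracle(obs, pred), abs=1e-9
            )

    def test_affine_invariance(self, rng):
        obs = rng.normal(0, 1, 15)
        pred = obs + rng.normal(0, 0.5, 15)
        base = modeling_efficiency(obs, pred)
        assert modeling_efficiency(3.5 * obs - 40, 3.5 * pred - 40) == pytest.approx(
            base, abs=1e-12
        )


class TestPearson:
    def test_affine_relation(self):
        obs = np.array([1.0, 2.0, 3.0, 7.0])
        assert pearson_r(obs, 2 * obs + 1) == pytest.approx(1.0)

    def test_anti_correlation(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert pearson_r(obs, -obs) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_oracle(self, rng):
        for _ in range(100):
            obs = rng.normal(0, 1, 12)
            pred = rng.normal(0, 1, 12)
            assert pearson_r(obs, pred) == pytest.approx(
                pearson_oracle(obs, pred), abs=1e-9
            )


class TestEstimateWastage:
    def test_zero_noise_recovery(self, synthetic_noisefree):
        records, truth = synthetic_noisefree
        params, ef = estimate_wastage(records, form="linear")
        est = params.as_free_vector()
        true = truth["params"].as_free_vector()
        assert ef > 0.999
        for e, t in zip(est, true):
            assert abs(e - t) <= 0.05 * max(t, 1.0)

    def test_constant_form_constraint(self, synthetic_noisefree):
        records, _ = synthetic_noisefree
        params, _ = estimate_wastage(records, form="constant", optimizer_config=FAST_OPT)
        assert params.p_wi_1 == params.p_wi_2
        assert params.p_su_1 == params.p_su_2

    def test_beats_brute_force_grid(self, synthetic_noisy20, rng):
        records, _ = synthetic_noisy20
        batch = pack_districts(records)
        params, ef = estimate_wastage(batch, form="linear")
        obs = batch.observed_final
        grid = rng.uniform(0.0, 16.0, size=(10_000, 4))
        best_grid = -np.inf
        for x in grid:
            pred = predict_final_biomass(batch, WastageParameters.from_free_vector(x, "linear"))
            best_grid = max(best_grid, modeling_efficiency(obs, pred))
        assert ef >= best_grid - 1e-6

    def test_too_few_districts_rejected(self, synthetic_noisefree):
        records, _ = synthetic_noisefree
        with pytest.raises(ValueError):
            estimate_wastage(records[:1])


class TestLoocv:
    def test_fold_count_and_exclusion(self, synthetic_noisefree):
        records, _ = synthetic_noisefree
        result = loocv(records, form="constant", optimizer_config=FAST_OPT)
        assert len(result.fold_params) == len(records)
        # fold 0 must not depend on district 0's observation
        perturbed = [dataclasses.replace(records[0], z_2008=records[0].z_2008 * 3)]
        perturbed += records[1:]
        res2 = loocv(perturbed, form="constant", optimizer_config=FAST_OPT)
        assert res2.fold_params[0] == result.fold_params[0]
        assert res2.fold_params[1] != result.fold_params[1]

    def test_zero_noise_near_perfect(self, synthetic_noisefree):
        records, _ = synthetic_noisefree
        result = loocv(records, form="linear")
        assert result.ef >= 0.99
        assert result.r_levels > 0.99

    def test_too_few_districts_rejected(self, synthetic_noisefree):
        records, _ = synthetic_noisefree
        with pytest.raises(ValueError):
            loocv(records[:2])


class TestAblation:
    def test_neutral_spec_is_identity(self, synthetic_noisefree):
        records, _ = synthetic_noisefree
        ef = run_ablation(records, AblationSpec(), optimizer_config=FAST_OPT)
        base = loocv(records, form="linear", optimizer_config=FAST_OPT).ef
        assert ef == base

    def test_exclusive_toggles_rejected(self):
        with pytest.raises(ValueError):
            AblationSpec(no_rotation=True, rotation_everywhere=True)

    def test_infra_scale_with_no_infra_rejected(self):
        with pytest.raises(ValueError):
            AblationSpec(no_infra=True, infra_scale=0.5)

    def test_toggles_modify_records(self, synthetic_noisefree):
        records, _ = synthetic_noisefree
        spec = AblationSpec(no_feeding=True, one_growth_rate=True, no_infra=True)
        mod = spec.apply(records)
        assert all(r.feeding == 0 for r in mod)
        assert all(r.growth_rel == 1.0 for r in mod)
        assert all(r.infra_pct == 0.0 for r in mod)
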