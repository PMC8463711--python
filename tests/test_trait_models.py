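"""Mixed-model fitting, frame assembly, and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from citsci_bias import recovery, trait_models as tm
from citsci_bias.errors import ConfigError


def make_frame(rng, n_states=8, n_species=40, sd_state=0.1, noise=0.05,
               betas=(0.05, 0.02, -0.01, 0.03)):
    """Direct draw from the mixed model (state intercepts + trait effects)."""
    species = [f"sp{i}" for i in range(n_species)]
    traits = pd.DataFrame(
        {
            "species": species,
            "log10_body_mass": rng.normal(1.7, 0.6, n_species),
            "log10_flock_size": rng.normal(0.4, 0.3, n_species),
            "color_index": rng.uniform(0, 1, n_species),
            "iucn_score": rng.choice([0.0, 1.0, 2.0], n_species, p=[0.1, 0.1, 0.8]),
        }
    )
    rows = []
    for s in range(n_states):
        a = rng.normal(0, sd_state)
        mu = (
            a
            + betas[0] * traits["log10_body_mass"]
            + betas[1] * traits["log10_flock_size"]
            + betas[2] * traits["color_index"]
            + betas[3] * traits["iucn_score"]
        )
        rows.append(
            pd.DataFrame(
                {
                    "state": f"S{s:02d}",
                    "species": species,
                    "residual": mu + rng.normal(0, noise, n_species),
                    "n_ebird": 100,
                    "n_inat": 10,
                }
            )
        )
    return pd.concat(rows, ignore_index=True), traits


class TestAssembleModelFrame:
    def test_complete_traits_keep_every_row(self, rng):
        residuals, traits = make_frame(rng)
        frame, report = tm.assemble_model_frame(residuals, traits, tm.ModelSpec())
        assert report["n_dropped"] == 0
        assert len(frame) == len(residuals)

    def test_per_model_completeness(self, rng):
        residuals, traits = make_frame(rng)
        traits.loc[traits.index[:10], "color_index"] = np.nan
        global_frame, _ = tm.assemble_model_frame(residuals, traits, tm.ModelSpec())
        body_frame, _ = tm.assemble_model_frame(
            residuals, traits, tm.ModelSpec(predictors=("log10_body_mass",))
        )
        missing_species = set(traits["species"][:10])
        assert not missing_species & set(global_frame["species"])
        assert missing_species <= set(body_frame["species"])
        assert len(body_frame) > len(global_frame)

    def test_planned_missingness_drop_counts(self, rng):
        residuals, traits = make_frame(rng, n_states=3)
        traits.loc[traits.index[:7], "iucn_score"] = np.nan  # e.g. endangered removed
        _, report = tm.assemble_model_frame(residuals, traits, tm.ModelSpec())
        assert report["n_missing_by_predictor"]["iucn_score"] == 7 * 3
        assert report["n_dropped"] == 7 * 3

    def test_empty_frame_raises(self, rng):
        residuals, traits = make_frame(rng, n_states=2)
        traits["color_index"] = np.nan
        with pytest.raises(ValueError, match="empty"):
            tm.assemble_model_frame(residuals, traits, tm.ModelSpec())


class TestFitMixed:
    def test_single_state_equals_ols(self, rng):
        residuals, traits = make_frame(rng, n_states=1)
        frame, _ = tm.assemble_model_frame(residuals, traits, tm.ModelSpec())
        result = tm.fit_mixed(frame, tm.ModelSpec())
        X = sm.add_constant(frame[list(tm.TRAIT_PREDICTORS)].to_numpy())
        ols = sm.OLS(frame["residual"].to_numpy(), X).fit()
        for i, name in enumerate(["intercept", *tm.TRAIT_PREDICTORS]):
            assert result.fixed_effects[name].estimate == pytest.approx(
                ols.params[i], abs=1e-6
            )
        assert result.random_intercept_variance == 0.0
        assert "ols" in result.method

    def test_mixed_estimates_near_truth_with_many_rows(self, rng):
        betas = (0.05, 0.02, -0.01, 0.03)
        residuals, traits = make_frame(rng, n_states=25, n_species=120, betas=betas)
        frame, _ = tm.assemble_model_frame(residuals, traits, tm.ModelSpec())
        result = tm.fit_mixed(frame, tm.ModelSpec())
        assert result.converged
        for beta, name in zip(betas, tm.TRAIT_PREDICTORS):
            fe = result.fixed_effects[name]
            assert abs(fe.estimate - beta) < 4 * fe.std_error
            assert fe.ci_low <= fe.estimate <= fe.ci_high
        assert result.random_intercept_variance > 0
        assert result.residual_variance > 0

    def test_constant_predictor_named_in_error(self, rng):
        residuals, traits = make_frame(rng)
        traits["color_index"] = 0.5
        frame, _ = tm.assemble_model_frame(residuals, traits, tm.ModelSpec())
        with pytest.raises(ValueError, match="color_index"):
            tm.fit_mixed(frame, tm.ModelSpec())

    def test_invariant_to_row_order_and_state_relabeling(self, rng):
        residuals, traits = make_frame(rng, n_states=6)
        frame, _ = tm.assemble_model_frame(residuals, traits, tm.ModelSpec())
        r1 = tm.fit_mixed(frame, tm.ModelSpec())
        shuffled = frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled["state"] = shuffled["state"].map(lambda s: f"relabeled_{s}")
        r2 = tm.fit_mixed(shuffled, tm.ModelSpec())
        for name in ["intercept", *tm.TRAIT_PREDICTORS]:
            assert r1.fixed_effects[name].estimate == pytest.approx(
                r2.fixed_effects[name].estimate, abs=1e-8
            )

    def test_ci_level_configurable(self, rng):
        residuals, traits = make_frame(rng)
        frame, _ = tm.assemble_model_frame(residuals, traits, tm.ModelSpec())
        wide = tm.fit_mixed(frame, tm.ModelSpec(ci_level=0.99))
        narrow = tm.fit_mixed(frame, tm.ModelSpec(ci_level=0.5))
        fe_w = wide.fixed_effects["log10_body_mass"]
        fe_n = narrow.fixed_effects["log10_body_mass"]
        assert fe_w.ci_high - fe_w.ci_low > fe_n.ci_high - fe_n.ci_low

    def test_spec_validation(self):
        with pytest.raises(ConfigError):
            tm.ModelSpec(predictors=())
        with pytest.raises(ConfigError):
            tm.ModelSpec(predictors=("body_size",))
        with pytest.raises(ConfigError):
            tm.ModelSpec(estimation="Bayes")


class TestFitAll:
    def test_orthogonal_design_global_matches_single_trait(self, rng):
        residuals, traits = make_frame(rng, n_states=20, n_species=150,
                                       betas=(0.05, 0.0, 0.0, 0.0))
        out = tm.fit_all(residuals, traits)
        g = out["global"].fixed_effects["log10_body_mass"]
        s = out["per_trait"]["log10_body_mass"].fixed_effects["log10_body_mass"]
        assert abs(g.estimate - s.estimate) < 3 * max(g.std_error, s.std_error)
        # the planted (non-null) effect must agree in sign between routes;
        # null traits may flip sign through chance confounding
        assert out["sign_agreement"]["log10_body_mass"] is True

    def test_missingness_arithmetic(self, rng):
        residuals, traits = make_frame(rng, n_states=4)
        half = traits.index[: len(traits) // 2]
        traits.loc[half, "color_index"] = np.nan
        out = tm.fit_all(residuals, traits)
        assert out["global"].n_rows < out["per_trait"]["log10_body_mass"].n_rows
        assert out["frames"]["global"]["n_rows"] == out["global"].n_rows


class TestRecovery:
    def test_signs_of_planted_effects_recovered(self):
        result, truth, _ = recovery.simulate_replicate(
            seed=12, n_states=20, n_species=100,
            gamma_body=0.05, gamma_flock=0.05, gamma_color=0.0, gamma_iucn=0.03,
        )
        fe = result.fixed_effects
        assert fe["log10_body_mass"].estimate > 0
        assert fe["log10_flock_size"].estimate > 0
        assert fe["iucn_score"].estimate > 0
        assert abs(fe["color_index"].estimate) < 3 * fe["color_index"].std_error

    def test_zero_noise_near_exact_recovery(self):
        result, truth, _ = recovery.simulate_replicate(
            seed=13, n_states=10, n_species=80, noise_sd=0.0,
            gamma_body=0.05, gamma_flock=0.0, gamma_color=0.0, gamma_iucn=0.0,
        )
        assert result.fixed_effects["log10_body_mass"].estimate == pytest.approx(
            0.05, abs=0.005
        )

    def test_recovery_report_structure(self):
        report = recovery.run_recovery_study(range(1, 4), n_states=10, n_species=60)
        assert report["n_replicates"] == 3
        for trait in tm.TRAIT_PREDICTORS:
            entry = report["per_trait"][trait]
            assert set(entry) == {
                "true_value", "mean_estimate", "bias", "rmse",
                "ci_coverage", "rejection_rate", "n_fits",
            }
            assert entry["n_fits"] == 3
            assert entry["rmse"] >= abs(entry["bias"])
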