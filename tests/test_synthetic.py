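"""The synthetic generator: determinism, planted structure, labels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from citsci_bias import representation, synthetic
from citsci_bias.errors import ConfigError

from conftest import make_bundle


class TestTraitGeneration:
    def test_empty_pool_rejected(self):
        with pytest.raises(ConfigError, match="n_species"):
            synthetic.generate_traits(synthetic.TraitGenConfig(n_species=0))

    def test_degenerate_iucn_distribution(self):
        cfg = synthetic.TraitGenConfig(n_species=30, iucn_probs=(1.0, 0.0, 0.0), seed=1)
        traits = synthetic.generate_traits(cfg)
        assert (traits["iucn_category"] == "Least Concern").all()

    def test_determinism_same_seed(self):
        cfg = synthetic.TraitGenConfig(n_species=25, seed=42)
        pd.testing.assert_frame_equal(
            synthetic.generate_traits(cfg), synthetic.generate_traits(cfg)
        )

    def test_probs_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="sum to 1"):
            synthetic.TraitGenConfig(iucn_probs=(0.5, 0.2, 0.2)).validate()

    def test_channels_in_bounds_and_mass_positive(self):
        traits = synthetic.generate_traits(synthetic.TraitGenConfig(n_species=40, seed=2))
        assert (traits["body_mass_g"] > 0).all()
        patch_cols = [c for c in traits.columns if c.startswith(("male_", "female_"))]
        assert len(patch_cols) == 36
        assert traits[patch_cols].to_numpy().min() >= 0
        assert traits[patch_cols].to_numpy().max() <= 255

    def test_iucn_marginals_match_probs(self):
        """Chi-square goodness of fit not rejected at alpha=0.01, n=2000."""
        probs = (0.7, 0.2, 0.1)
        traits = synthetic.generate_traits(
            synthetic.TraitGenConfig(n_species=2000, iucn_probs=probs, seed=99)
        )
        observed = traits["iucn_category"].value_counts()
        obs = [observed.get(level, 0) for level in synthetic.IUCN_LEVELS]
        expected = [p * 2000 for p in probs]
        _, p_value = stats.chisquare(obs, expected)
        assert p_value > 0.01


class TestDirectCounts:
    def _setup(self, seed=0, n_species=30, n_states=3, **truth_kwargs):
        rng = np.random.default_rng(seed)
        states = [f"S{i}" for i in range(n_states)]
        effort = synthetic.default_effort(states, rng)
        truth_kwargs.setdefault("slope_b", 1.0)
        truth = synthetic.PlantedEffects(
            state_intercepts={s: -2.0 for s in states}, **truth_kwargs
        )
        traits = synthetic.generate_traits(
            synthetic.TraitGenConfig(n_species=n_species, seed=seed)
        )
        return traits, states, effort, truth

    def test_deterministic_linear_case(self):
        traits, states, effort, truth = self._setup(noise_sd=0.0)
        counts = synthetic.generate_counts_direct(traits, states, effort, truth, seed=1)
        expected = np.log10(counts["n_ebird"].to_numpy(dtype=float)) - 2.0
        assert np.allclose(counts["log10_inat_latent"].to_numpy(), expected, atol=1e-12)

    def test_rounding_only_residuals_bounded(self):
        """Zero noise, zero gammas: residuals equal the OLS image of the
        rounding perturbation, bounded via leverage and the perturbation."""
        traits, states, effort, truth = self._setup(noise_sd=0.0, n_species=60)
        counts = synthetic.generate_counts_direct(traits, states, effort, truth, seed=2)
        table, fits, _ = representation.build_residual_table(counts)
        merged = table.merge(counts, on=["state", "species"], suffixes=("", "_gen"))
        for state, sub in merged.groupby("state"):
            delta = np.log10(sub["n_inat"].to_numpy(dtype=float)) - sub[
                "log10_inat_latent"
            ].to_numpy()
            x = np.log10(sub["n_ebird"].to_numpy(dtype=float))
            X = np.column_stack([np.ones_like(x), x])
            H = X @ np.linalg.solve(X.T @ X, X.T)
            expected_resid = delta - H @ delta
            assert np.allclose(sub["residual"].to_numpy(), expected_resid, atol=1e-9)
            h_max = np.diag(H).max()
            bound = np.abs(delta).max() + np.sqrt(h_max) * np.linalg.norm(delta)
            assert np.abs(sub["residual"].to_numpy()).max() <= bound + 1e-12

    def test_zero_counts_flagged_not_dropped(self):
        traits, states, _, truth = self._setup(noise_sd=0.0)
        # force tiny unstructured counts via tiny effort
        effort = {s: 10.0 for s in states}
        counts = synthetic.generate_counts_direct(traits, states, effort, truth, seed=3)
        assert counts["inat_zero"].any()
        assert (counts["inat_zero"] == (counts["n_inat"] == 0)).all()
        assert len(counts) == len(traits) * len(states)

    def test_unknown_state_rejected(self):
        traits, states, effort, truth = self._setup()
        with pytest.raises(ConfigError, match="state_intercepts"):
            synthetic.generate_counts_direct(
                traits, states + ["XX"], {**effort, "XX": 10.0}, truth, seed=1
            )

    def test_determinism(self):
        traits, states, effort, truth = self._setup(noise_sd=0.1)
        a = synthetic.generate_counts_direct(traits, states, effort, truth, seed=9)
        b = synthetic.generate_counts_direct(traits, states, effort, truth, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_counts_positively_skewed(self):
        traits, states, effort, truth = self._setup(n_species=300)
        counts = synthetic.generate_counts_direct(traits, states, effort, truth, seed=4)
        assert stats.skew(counts["n_ebird"].to_numpy(dtype=float)) > 1.0


class TestEventLevel:
    def test_zero_contamination_passes_everything(self):
        from citsci_bias.io_filtering import filter_checklists

        bundle = make_bundle(seed=5, contamination={})
        retained, report = filter_checklists(bundle.checklists)
        assert report.n_removed == 0
        assert len(retained) == len(bundle.checklists)

    def test_planted_incomplete_count_is_exact(self):
        bundle = make_bundle(seed=6, n_states=1, checklists_per_state=100,
                             contamination={"incomplete": 0.1})
        n_incomplete = (~bundle.checklists["complete"]).sum()
        labelled = (bundle.checklist_labels["true_fail"] == "incomplete").sum()
        assert n_incomplete == labelled
        from citsci_bias.io_filtering import filter_checklists

        retained, report = filter_checklists(bundle.checklists)
        assert report.n_removed == labelled
        assert report.removals["incomplete"] == labelled

    def test_boundary_durations_present_and_retained(self):
        from citsci_bias.io_filtering import filter_checklists

        bundle = make_bundle(seed=7, checklists_per_state=400, contamination={})
        dur = bundle.checklists["duration_minutes"]
        assert (dur == 5.0).any() and (dur == 240.0).any()
        retained, _ = filter_checklists(bundle.checklists)
        assert (retained["duration_minutes"] == 5.0).any()
        assert (retained["duration_minutes"] == 240.0).any()

    def test_referential_integrity(self, bundle):
        assert set(bundle.ebird_obs["checklist_id"]) <= set(bundle.checklists["checklist_id"])
        assert set(bundle.ebird_obs["species"]) <= set(bundle.traits["species"])
        assert set(bundle.inat_obs["species"]) <= set(bundle.traits["species"])

    def test_x_counts_present_at_configured_rate(self, bundle):
        frac = (bundle.ebird_obs["count"] == "X").mean()
        assert 0.005 < frac < 0.06  # configured 0.02 with sampling noise

    def test_negative_contamination_rejected(self):
        with pytest.raises(ConfigError, match="contamination"):
            synthetic.EventGenConfig(contamination={"incomplete": -0.1}).validate()

    def test_bundle_write_round_trip_deterministic(self, tmp_path):
        b1 = make_bundle(seed=8, n_states=2, n_species=15, checklists_per_state=50)
        b2 = make_bundle(seed=8, n_states=2, n_species=15, checklists_per_state=50)
        p1 = b1.write(tmp_path / "a")
        p2 = b2.write(tmp_path / "b")
        for name in p1:
            bytes1 = open(p1[name], "rb").read()
            bytes2 = open(p2[name], "rb").read()
            assert bytes1 == bytes2, f"{name} differs between identically seeded runs"
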