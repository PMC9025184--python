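"""Generator behaviour: determinism, marginal structure, reliability and
effect-direction regimes, missingness, recipe planting, CSV round trip."""

import numpy as np
import pandas as pd
import pytest

from likertqca import studydesign as sd
from likertqca.config import (ConfigError, ConstructSpec, GeneratorConfig,
                              default_outcome_cutpoints,
                              reference_generator_config)
from likertqca.contrarian import kendall_tau_b
from likertqca.scales import cronbach_alpha
from likertqca.synthetic import SurveyDataset, generate_survey, plant_recipe


def small_config(seed=1, **kw):
    defaults = dict(n_respondents=300, missingness_rate=0.0, use_marginals=False)
    defaults.update(kw)
    return reference_generator_config(seed=seed, **defaults)


class TestGenerate:
    def test_equal_seeds_give_identical_datasets(self):
        a = generate_survey(small_config(seed=5))
        b = generate_survey(small_config(seed=5))
        pd.testing.assert_frame_equal(a.responses, b.responses)

    def test_different_seeds_differ(self):
        a = generate_survey(small_config(seed=5))
        b = generate_survey(small_config(seed=6))
        assert not a.responses.equals(b.responses)

    def test_no_missingness_config_yields_complete_table(self):
        ds = generate_survey(small_config())
        assert not ds.missing_mask.to_numpy().any()

    def test_missingness_rate_produces_gaps(self):
        ds = generate_survey(small_config(missingness_rate=0.05))
        frac = ds.missing_mask.to_numpy().mean()
        assert 0.02 < frac < 0.09

    def test_responses_respect_likert_ranges(self):
        ds = generate_survey(small_config())
        for name, (k, lo, hi) in sd.CONSTRUCT_DESIGN.items():
            vals = ds.responses[ds.construct_map[name]].to_numpy()
            assert vals.min() >= lo and vals.max() <= hi
        assert set(np.unique(ds.outcome)) <= set(sd.OUTCOME_CATEGORIES)
        assert set(np.unique(ds.age)) <= set(sd.AGE_CODES)
        assert set(np.unique(ds.gender)) <= {0.0, 1.0}

    def test_null_effects_reproduce_reference_outcome_marginals(self):
        """With zero coefficients and cutpoints at the logits of the
        reference cumulative frequencies, the share of category 1
        ('never used') must land within one point of 72.52%."""
        cfg = small_config(seed=99, n_respondents=100_000)
        cfg.outcome_coefficients = {c: 0.0 for c in cfg.outcome_coefficients}
        cfg.outcome_cutpoints = default_outcome_cutpoints()
        ds = generate_survey(cfg)
        share = float((ds.outcome == 1).mean()) * 100
        assert abs(share - 72.52) < 1.0

    def test_reference_reliability_regime(self, reference_survey):
        """Constructs generated at inter-item correlation >= 0.35 with >= 5
        items must clear the alpha > 0.7 reliability bar."""
        cfg = reference_generator_config(seed=0)
        for name, spec in cfg.construct_specs.items():
            if spec.inter_item_corr >= 0.35 and spec.n_items >= 5:
                items = reference_survey.responses[
                    reference_survey.construct_map[name]]
                assert cronbach_alpha(items) > 0.7, name

    def test_effect_signs_propagate_to_tau(self, reference_survey):
        """A condition with a known-sign coefficient must correlate with
        the outcome in that direction (large n)."""
        scores = reference_survey.responses[
            reference_survey.construct_map["P_TOLER"]].sum(axis=1)
        tau_pos, _ = kendall_tau_b(scores, reference_survey.outcome)
        assert tau_pos > 0
        scores = reference_survey.responses[
            reference_survey.construct_map["MONITOR"]].sum(axis=1)
        tau_neg, _ = kendall_tau_b(scores, reference_survey.outcome)
        assert tau_neg < 0

    @pytest.mark.parametrize("mutate, message", [
        (lambda c: setattr(c, "seed", None), "seed"),
        (lambda c: setattr(c, "outcome_cutpoints", (0.0,) * 6), "increasing"),
        (lambda c: setattr(c, "age_distribution", (0.5, 0.5, 0.5)), "sum"),
        (lambda c: setattr(c, "missingness_rate", 1.0), "missingness"),
        (lambda c: c.construct_specs.__setitem__(
            "MONITOR", ConstructSpec(11, 1, 5, 0.3)), "Likert"),
    ])
    def test_invalid_configs_rejected(self, mutate, message):
        cfg = small_config()
        mutate(cfg)
        with pytest.raises(ConfigError, match=message):
            generate_survey(cfg)


class TestPlantRecipe:
    def test_full_strength_forces_every_matching_outcome(self):
        ds = generate_survey(small_config(seed=7))
        planted = plant_recipe(ds, {"P_TOLER": "absent"}, outcome_level=1,
                               strength=1.0)
        sums = planted.responses[planted.construct_map["P_TOLER"]].sum(axis=1)
        median = sums.median()
        assert (planted.outcome[sums < median] == 1).all()

    def test_partial_strength_hits_at_least_that_fraction(self):
        ds = generate_survey(small_config(seed=7))
        planted = plant_recipe(ds, {"P_TOLER": "absent"}, outcome_level=1,
                               strength=0.9, seed=3)
        sums = planted.responses[planted.construct_map["P_TOLER"]].sum(axis=1)
        matching = planted.outcome[sums < sums.median()]
        assert (matching == 1).mean() >= 0.9

    def test_empty_recipe_is_identity(self):
        ds = generate_survey(small_config(seed=7))
        planted = plant_recipe(ds, {}, outcome_level=1, strength=1.0)
        pd.testing.assert_frame_equal(planted.responses, ds.responses)

    def test_unknown_condition_rejected(self):
        ds = generate_survey(small_config(seed=7))
        with pytest.raises(ConfigError, match="unknown condition"):
            plant_recipe(ds, {"WEALTH": "present"}, outcome_level=1)

    def test_conjunction_only_touches_joint_matches(self):
        ds = generate_survey(small_config(seed=8))
        planted = plant_recipe(
            ds, {"GENDER": "present", "P_TOLER": "absent"}, outcome_level=1,
            strength=1.0)
        males = planted.responses[sd.GENDER] == 0.0
        # males never match the GENDER=present literal, so their outcomes
        # are untouched
        assert planted.outcome[males].equals(ds.outcome[males])


class TestCsvRoundTrip:
    def test_round_trip_preserves_values_and_missingness(self, tmp_path):
        ds = generate_survey(small_config(seed=9, missingness_rate=0.02))
        path = tmp_path / "survey.csv"
        ds.to_csv(path)
        text = path.read_text()
        assert ",," in text or text.rstrip().endswith(",")  # empty = missing
        back = SurveyDataset.from_csv(path)
        pd.testing.assert_frame_equal(back.responses, ds.responses)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("GENDER,AGE,USE\n0,15,1\n")
        with pytest.raises(ConfigError, match="lacks expected columns"):
            SurveyDataset.from_csv(path)
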