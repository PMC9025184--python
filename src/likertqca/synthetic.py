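"""Synthetic Likert survey generation.

Each multi-item construct follows a single-factor latent model: one standard
normal draw per respondent and construct, with items formed as
``sqrt(r) * latent + sqrt(1 - r) * noise`` so that any two items of the
construct correlate ``r`` on the latent scale.  Items are discretized to
their Likert range either at thresholds matching supplied marginal category
frequencies (Gaussian-copula style) or, absent marginals, at equally spaced
cuts on the latent scale.  The ordinal outcome is drawn from a
proportional-odds model whose linear predictor combines gender and age set
memberships with standardized construct scores.

All randomness flows through one :class:`numpy.random.Generator` seeded from
the configuration, so generation is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from . import studydesign as sd
from .config import ConfigError, GeneratorConfig, PlantedRecipe


@dataclass
class SurveyDataset:
    """A respondent-by-item Likert table plus individual variables.

    ``responses`` holds one row per respondent with item columns (e.g.
    ``MONITOR1``), ``GENDER`` (0 male / 1 female), ``AGE`` (15/16/17) and
    ``USE`` (1..7).  Missing entries are NaN.
    """

    responses: pd.DataFrame
    construct_map: dict[str, list[str]] = field(
        default_factory=sd.default_construct_map
    )

    @property
    def n_respondents(self) -> int:
        return len(self.responses)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.responses.isna()

    @property
    def outcome(self) -> pd.Series:
        return self.responses[sd.OUTCOME]

    @property
    def gender(self) -> pd.Series:
        return self.responses[sd.GENDER]

    @property
    def age(self) -> pd.Series:
        return self.responses[sd.AGE]

    def item_columns(self) -> list[str]:
        cols: list[str] = []
        for items in self.construct_map.values():
            cols.extend(items)
        return cols

    def copy(self) -> "SurveyDataset":
        return SurveyDataset(self.responses.copy(), {k: list(v) for k, v in self.construct_map.items()})

    def to_csv(self, path: str | Path) -> None:
        """Write one respondent per row, header included, missing as empty."""
        out = self.responses.copy()
        # Likert codes are integers; render without a trailing ".0".
        formatted = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
        formatted.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, construct_map: dict[str, list[str]] | None = None
    ) -> "SurveyDataset":
        df = pd.read_csv(path, dtype=float)
        cmap = construct_map or sd.default_construct_map()
        missing = [c for items in cmap.values() for c in items if c not in df.columns]
        missing += [c for c in (sd.GENDER, sd.AGE, sd.OUTCOME) if c not in df.columns]
        if missing:
            raise ConfigError(f"survey CSV lacks expected columns: {missing}")
        return cls(df, cmap)


def _item_thresholds(spec, item_index: int) -> np.ndarray:
    """Latent-scale cut points for one item (n_categories - 1 values)."""
    if spec.marginals is not None:
        probs = np.asarray(spec.marginals[item_index], dtype=float)
        probs = probs / probs.sum()
        cum = np.cumsum(probs)[:-1]
        cum = np.clip(cum, 1e-9, 1 - 1e-9)
        return norm.ppf(cum)
    # No marginals: equally spaced cuts spanning [-1.5, 1.5].
    return np.linspace(-1.5, 1.5, spec.n_categories - 1)


def generate_survey(config: GeneratorConfig) -> SurveyDataset:
    """Draw one synthetic survey according to ``config``.

    Deterministic given ``config.seed``; raises :class:`ConfigError` for
    invalid configurations (including a missing seed).
    """
    config.validate()
    if config.seed is None:
        raise ConfigError("a seed is required for generation; none was given")
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents

    columns: dict[str, np.ndarray] = {}
    construct_map: dict[str, list[str]] = {}
    predictors: dict[str, np.ndarray] = {}

    for name, spec in config.construct_specs.items():
        latent = rng.standard_normal(n)
        load = math.sqrt(spec.inter_item_corr)
        noise_sd = math.sqrt(1.0 - spec.inter_item_corr)
        items = []
        for i in range(spec.n_items):
            v = load * latent + noise_sd * rng.standard_normal(n)
            codes = spec.likert_min + np.digitize(v, _item_thresholds(spec, i))
            col = f"{name}{i + 1}"
            columns[col] = codes.astype(float)
            items.append(col)
        construct_map[name] = items
        sums = np.sum([columns[c] for c in items], axis=0)
        std = sums.std()
        predictors[name] = (sums - sums.mean()) / std if std > 0 else np.zeros(n)

    gender = (rng.random(n) < config.gender_proportion).astype(float)
    age = rng.choice(np.asarray(sd.AGE_CODES, dtype=float), size=n,
                     p=np.asarray(config.age_distribution, dtype=float))
    columns[sd.GENDER] = gender
    columns[sd.AGE] = age
    predictors[sd.GENDER] = gender
    predictors[sd.AGE] = (age - 15.0) / 2.0  # 15/16/17 -> 0/0.5/1

    eta = np.zeros(n)
    for cond, beta in config.outcome_coefficients.items():
        eta += beta * predictors[cond]
    cuts = np.asarray(config.outcome_cutpoints, dtype=float)
    cum_probs = expit(cuts[None, :] - eta[:, None])  # P(y <= j | x), j = 1..6
    u = rng.random(n)
    outcome = 1 + np.sum(u[:, None] > cum_probs, axis=1)
    columns[sd.OUTCOME] = outcome.astype(float)

    ordered = [c for items in construct_map.values() for c in items]
    ordered += [sd.GENDER, sd.AGE, sd.OUTCOME]
    df = pd.DataFrame({c: columns[c] for c in ordered})

    if config.missingness_rate > 0:
        mask = rng.random(df.shape) < config.missingness_rate
        df = df.mask(mask)

    dataset = SurveyDataset(df, construct_map)
    for recipe in config.planted_recipes:
        dataset = plant_recipe(dataset, recipe.states, recipe.outcome_level,
                               recipe.strength, rng=rng)
    return dataset


def _matches_state(dataset: SurveyDataset, cond: str, state: str) -> np.ndarray:
    """Boolean mask of respondents whose dichotomized position on ``cond``
    equals ``state``.

    Constructs are split at the sample median of the item sum (membership
    above 0.5 = present, below = absent; respondents exactly at the median
    are maximally ambiguous and match neither state).  Gender: present =
    female.  Age: present = 17, absent = 15 (16 sits at the crossover).
    """
    df = dataset.responses
    if cond == sd.GENDER:
        vals = df[sd.GENDER]
        return (vals == (1.0 if state == "present" else 0.0)).to_numpy()
    if cond == sd.AGE:
        vals = df[sd.AGE]
        return (vals == (17.0 if state == "present" else 15.0)).to_numpy()
    if cond not in dataset.construct_map:
        raise ConfigError(f"unknown condition {cond!r} in planted recipe")
    items = dataset.construct_map[cond]
    sums = df[items].sum(axis=1, skipna=False)
    median = float(np.nanmedian(sums.to_numpy()))
    if state == "present":
        return (sums > median).to_numpy()
    return (sums < median).to_numpy()


def plant_recipe(
    dataset: SurveyDataset,
    states: Mapping[str, str] | PlantedRecipe,
    outcome_level: int | None = None,
    strength: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SurveyDataset:
    """Force a condition-state conjunction to imply an outcome level.

    For a ``strength`` fraction of respondents matching every state in the
    conjunction, the outcome is overwritten with ``outcome_level``, so a
    downstream sufficiency analysis should recover the conjunction with
    consistency at least ``strength``.  An empty conjunction returns the
    dataset unchanged.  Selection of the affected fraction is seeded.
    """
    if isinstance(states, PlantedRecipe):
        recipe = states
    else:
        if outcome_level is None:
            raise ConfigError("outcome_level required when states given as a mapping")
        recipe = PlantedRecipe(dict(states), outcome_level, strength)
    known = set(dataset.construct_map) | {sd.GENDER, sd.AGE}
    recipe.validate(known)

    result = dataset.copy()
    if not recipe.states:
        return result
    if rng is None:
        if seed is None and recipe.strength < 1.0:
            raise ConfigError("planting at strength < 1 is stochastic and requires a seed")
        rng = np.random.default_rng(seed)

    match = np.ones(dataset.n_respondents, dtype=bool)
    for cond, state in recipe.states.items():
        match &= _matches_state(dataset, cond, state)
    idx = np.flatnonzero(match)
    if idx.size and recipe.strength < 1.0:
        k = math.ceil(recipe.strength * idx.size)
        idx = rng.permutation(idx)[:k]
    result.responses.iloc[idx, result.responses.columns.get_loc(sd.OUTCOME)] = float(
        recipe.outcome_level
    )
    return result
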