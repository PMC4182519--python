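"""Household deprivation indicators and the binary deprivation matrix.

Eleven weighted indicators in three dimensions (education, health, living
standard) classify each household as deprived / non-deprived.  Weights are
exact rationals that sum to one: the two education indicators carry 1/6 each,
health carries 1/6 + 1/12 + 1/12, and the six living-standard indicators 1/18
each.  The deprivation rules:

education
    low_literacy          literacy score < 16 AND numeracy score < 5
    child_not_enrolled    a school-aged child (7-14) in the household is not
                          attending school; households with no school-aged
                          child are non-deprived (the usual convention for
                          non-applicable indicators)
health
    child_acute_illness   fever, diarrhea or difficulty breathing in the last
                          30 days
    low_dietary_diversity household dietary diversity score (HDDS) < 4
    food_lack_episode     an episode of lacking food during the last month
living standard
    no_electricity        household has no electricity
    unimproved_water      water source is a river, OR more than 30 minutes
                          away travelled on foot
    no_latrine            household does not use a latrine
    grass_roof            roof of grass / cane / leaves / straw
    wood_cooking_fuel     household cooks with wood
    low_assets            owns none of radio, television, bicycle

Missing required fields raise :class:`MissingDataError` -- analysis is meant
to run on complete interviews, never on silent imputations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import MissingDataError, ValidationError

__all__ = [
    "IndicatorSpec",
    "DeprivationMatrix",
    "default_indicator_specs",
    "evaluate_indicator",
    "build_deprivation_matrix",
    "DESIGN_COLUMNS",
]

#: household columns carried through to design-based estimation
DESIGN_COLUMNS = ("sampling_probability", "stratum", "ea_id")


@dataclass(frozen=True)
class IndicatorSpec:
    """One deprivation indicator: name, dimension, exact weight, and rule."""

    name: str
    dimension: str  # education | health | living_standard
    weight: Fraction
    requires: tuple[str, ...]
    rule: Callable[[pd.DataFrame], np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValidationError(f"indicator {self.name}: weight must be > 0")


def _col(df: pd.DataFrame, name: str) -> pd.Series:
    if name not in df.columns:
        raise MissingDataError(f"required field '{name}' is missing")
    return df[name]


def _flag(df: pd.DataFrame, name: str) -> np.ndarray:
    s = _col(df, name)
    if s.isna().any():
        bad = df.index[s.isna()][:5].tolist()
        raise MissingDataError(f"field '{name}' has missing values (rows {bad})")
    return s.to_numpy().astype(bool)


def _num(df: pd.DataFrame, name: str) -> np.ndarray:
    s = _col(df, name)
    if s.isna().any():
        bad = df.index[s.isna()][:5].tolist()
        raise MissingDataError(f"field '{name}' has missing values (rows {bad})")
    return s.to_numpy().astype(float)


def _rule_low_literacy(df: pd.DataFrame) -> np.ndarray:
    return (_num(df, "literacy_score") < 16) & (_num(df, "numeracy_score") < 5)


def _rule_child_not_enrolled(df: pd.DataFrame) -> np.ndarray:
    has_child = _flag(df, "has_school_age_child")
    attending = _col(df, "school_age_child_attending")
    if attending[has_child].isna().any():
        raise MissingDataError(
            "field 'school_age_child_attending' is missing for households "
            "with a school-aged child"
        )
    att = np.asarray(
        [1 if pd.isna(v) else int(v) for v in attending], dtype=bool
    ) if attending.dtype == object else attending.fillna(1).to_numpy().astype(bool)
    return has_child & ~att


def _rule_water(df: pd.DataFrame) -> np.ndarray:
    river = _flag(df, "water_source_river")
    far = _flag(df, "water_time_gt30")
    foot = _flag(df, "water_on_foot")
    return river | (far & foot)


def _rule_low_assets(df: pd.DataFrame) -> np.ndarray:
    radio = _flag(df, "owns_radio")
    tv = _flag(df, "owns_tv")
    bike = _flag(df, "owns_bicycle")
    return ~(radio | tv | bike)


def default_indicator_specs() -> tuple[IndicatorSpec, ...]:
    """The eleven indicators in canonical order with exact rational weights."""
    w6, w12, w18 = Fraction(1, 6), Fraction(1, 12), Fraction(1, 18)
    specs = (
        IndicatorSpec(
            "low_literacy", "education", w6,
            ("literacy_score", "numeracy_score"), _rule_low_literacy,
        ),
        IndicatorSpec(
            "child_not_enrolled", "education", w6,
            ("has_school_age_child", "school_age_child_attending"),
            _rule_child_not_enrolled,
        ),
        IndicatorSpec(
            "child_acute_illness", "health", w6,
            ("child_acute_illness",),
            lambda df: _flag(df, "child_acute_illness"),
        ),
        IndicatorSpec(
            "low_dietary_diversity", "health", w12,
            ("hdds",), lambda df: _num(df, "hdds") < 4,
        ),
        IndicatorSpec(
            "food_lack_episode", "health", w12,
            ("lack_food_episode",), lambda df: _flag(df, "lack_food_episode"),
        ),
        IndicatorSpec(
            "no_electricity", "living_standard", w18,
            ("electricity",), lambda df: ~_flag(df, "electricity"),
        ),
        IndicatorSpec(
            "unimproved_water", "living_standard", w18,
            ("water_source_river", "water_time_gt30", "water_on_foot"),
            _rule_water,
        ),
        IndicatorSpec(
            "no_latrine", "living_standard", w18,
            ("uses_latrine",), lambda df: ~_flag(df, "uses_latrine"),
        ),
        IndicatorSpec(
            "grass_roof", "living_standard", w18,
            ("roof_grass",), lambda df: _flag(df, "roof_grass"),
        ),
        IndicatorSpec(
            "wood_cooking_fuel", "living_standard", w18,
            ("cooks_with_wood",), lambda df: _flag(df, "cooks_with_wood"),
        ),
        IndicatorSpec(
            "low_assets", "living_standard", w18,
            ("owns_radio", "owns_tv", "owns_bicycle"), _rule_low_assets,
        ),
    )
    assert sum(s.weight for s in specs) == 1
    return specs


def evaluate_indicator(record, spec: IndicatorSpec) -> int:
    """Apply one indicator rule to a single household record.

    ``record`` may be a mapping or a pandas Series. Returns 1 if deprived.
    """
    if isinstance(record, pd.Series):
        df = record.to_frame().T
    else:
        df = pd.DataFrame([dict(record)])
    out = np.asarray(spec.rule(df))
    return int(out[0])


@dataclass
class DeprivationMatrix:
    """Households x indicators binary matrix with weights and design metadata.

    ``g0[i, j]`` is 1 iff household i is deprived in indicator j; ``weights``
    are exact :class:`~fractions.Fraction` values summing to one; ``design``
    carries sampling_weight (inverse sampling probability), stratum and
    ea_id per row.
    """

    household_ids: np.ndarray
    g0: np.ndarray
    weights: tuple[Fraction, ...]
    design: pd.DataFrame
    indicator_names: tuple[str, ...]
    dimensions: tuple[str, ...]

    def __post_init__(self) -> None:
        self.g0 = np.asarray(self.g0)
        if self.g0.ndim != 2 or self.g0.shape[1] != len(self.weights):
            raise ValidationError("g0 must be n x len(weights)")
        if not np.isin(self.g0, (0, 1)).all():
            raise ValidationError("g0 entries must be 0 or 1")
        if sum(self.weights, Fraction(0)) != 1:
            raise ValidationError("indicator weights must sum to exactly 1")

    @property
    def n(self) -> int:
        return self.g0.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.g0, columns=list(self.indicator_names))
        df.insert(0, "household_id", self.household_ids)
        for c in self.design.columns:
            df[c] = self.design[c].to_numpy()
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, specs=None) -> "DeprivationMatrix":
        specs = default_indicator_specs() if specs is None else tuple(specs)
        names = tuple(s.name for s in specs)
        missing = [n for n in names if n not in df.columns]
        if missing:
            raise MissingDataError(f"indicator columns missing: {missing}")
        design = pd.DataFrame(
            {
                "sampling_weight": df["sampling_weight"].to_numpy(float),
                "stratum": df["stratum"].to_numpy(),
                "ea_id": df["ea_id"].to_numpy(),
            }
        )
        return cls(
            household_ids=df["household_id"].to_numpy(),
            g0=df[list(names)].to_numpy().astype(np.int8),
            weights=tuple(s.weight for s in specs),
            design=design,
            indicator_names=names,
            dimensions=tuple(s.dimension for s in specs),
        )


def serialize_specs(specs: Sequence[IndicatorSpec] | None = None) -> list[dict]:
    """JSON-ready provenance record of the indicator definitions."""
    specs = default_indicator_specs() if specs is None else specs
    return [
        {
            "name": s.name,
            "dimension": s.dimension,
            "weight": str(s.weight),
            "requires": list(s.requires),
        }
        for s in specs
    ]


def build_deprivation_matrix(
    records: pd.DataFrame, specs: Sequence[IndicatorSpec] | None = None
) -> DeprivationMatrix:
    """Evaluate every indicator rule over a household table.

    The sampling weight attached to each row is the inverse of the household
    sampling probability.
    """
    if records is None or len(records) == 0:
        raise ValidationError("records is empty")
    specs = default_indicator_specs() if specs is None else tuple(specs)
    if sum((s.weight for s in specs), Fraction(0)) != 1:
        raise ValidationError("indicator weights must sum to exactly 1")

    for col in ("household_id",) + DESIGN_COLUMNS:
        if col not in records.columns:
            raise MissingDataError(f"required field '{col}' is missing")
    p = records["sampling_probability"].to_numpy(float)
    if not np.all((p > 0) & (p <= 1)):
        raise ValidationError("sampling_probability must lie in (0, 1]")

    cols = [np.asarray(s.rule(records), dtype=np.int8) for s in specs]
    g0 = np.column_stack(cols)
    design = pd.DataFrame(
        {
            "sampling_weight": 1.0 / p,
            "stratum": records["stratum"].to_numpy(),
            "ea_id": records["ea_id"].to_numpy(),
        }
    )
    return DeprivationMatrix(
        household_ids=records["household_id"].to_numpy(),
        g0=g0,
        weights=tuple(s.weight for s in specs),
        design=design,
        indicator_names=tuple(s.name for s in specs),
        dimensions=tuple(s.dimension for s in specs),
    )
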