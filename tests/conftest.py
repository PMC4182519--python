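import logging

import numpy as np
import pandas as pd
import pytest

import mdpoverty as mp
from mdpoverty.deprivation import DeprivationMatrix

# lonely-PSU certainty treatment is expected in the small fixtures
logging.getLogger("mdpoverty.survey_stats").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_survey():
    """A small but structured synthetic survey shared across tests."""
    return mp.generate_survey(mp.SimConfig(n_eas=40, households_per_ea=8, seed=7))


@pytest.fixture(scope="session")
def small_matrix(small_survey):
    return mp.build_deprivation_matrix(small_survey.households)


@pytest.fixture
def make_matrix():
    """Factory: wrap a raw g0 array (+ optional weights/design) in a matrix."""

    def _make(g0, weights=None, s=None, stratum=None, ea=None):
        g0 = np.asarray(g0, dtype=np.int8)
        n, m = g0.shape
        if weights is None:
            specs = mp.default_indicator_specs()
            assert m == len(specs)
            weights = tuple(sp.weight for sp in specs)
            names = tuple(sp.name for sp in specs)
            dims = tuple(sp.dimension for sp in specs)
        else:
            weights = tuple(weights)
            names = tuple(f"ind{j}" for j in range(m))
            dims = tuple("dim0" if j < m // 2 else "dim1" for j in range(m))
        s = np.ones(n) if s is None else np.asarray(s, dtype=float)
        design = pd.DataFrame(
            {
                "sampling_weight": s,
                "stratum": np.repeat("s0", n) if stratum is None else stratum,
                "ea_id": [f"e{i}" for i in range(n)] if ea is None else ea,
            }
        )
        return DeprivationMatrix(
            household_ids=np.array([f"h{i}" for i in range(n)]),
            g0=g0,
            weights=weights,
            design=design,
            indicator_names=names,
            dimensions=dims,
        )

    return _make


@pytest.fixture
def complete_record():
    """A household record deprived in nothing, as a plain dict."""
    rec = {
        "household_id": "h0",
        "ea_id": "e0",
        "district": "D",
        "stratum": "D:rural",
        "urban": 0,
        "language": "Echuabo",
        "sampling_probability": 0.1,
        "literacy_score": 20,
        "numeracy_score": 6,
        "has_school_age_child": 1,
        "school_age_child_attending": 1,
        "child_acute_illness": 0,
        "hdds": 6,
        "lack_food_episode": 0,
        "electricity": 1,
        "water_source_river": 0,
        "water_time_gt30": 0,
        "water_on_foot": 1,
        "uses_latrine": 1,
        "roof_grass": 0,
        "cooks_with_wood": 0,
        "owns_radio": 1,
        "owns_tv": 0,
        "owns_bicycle": 1,
        "monthly_income_mzn": 500.0,
        "household_size": 4,
    }
    return rec
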