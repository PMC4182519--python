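"""Synthetic two-stage household survey generator.

Emulates a provincial cluster survey: enumeration areas (EAs, the primary
sampling units) are scattered over a planar region partitioned into district
strips, a fixed number of households is interviewed per EA, and roughly 96%
of EAs are rural.  Each indicator deprivation is drawn from a probit
threshold model

    deprived_ij  iff  z_e(i) + eps_ij < t_j,     eps_ij ~ N(0, 1) iid,

where z_e is a zero-mean Gaussian EA effect with exponential spatial
covariance sill * exp(-d / range).  The shared EA effect induces within-EA
correlation across households and across indicators, and gives kriging a
real spatial signal to recover.  Thresholds t_j are calibrated so the
deprivation marginals match the 11 target rates (defaults: the observed
provincial deprivation rates, 14.7% low literacy ... 43.2% low assets):

``calibration="population"``
    t_j = sqrt(1 + sill) * Phi^-1(p_j); marginals match in expectation over
    the spatial field, and the superpopulation headcount is analytically
    available (:func:`expected_headcount`).
``calibration="sample"`` (default)
    t_j is solved against the realized EA effects so that the sample
    deprivation rate matches the target up to household-level binomial noise.

Raw survey fields (literacy and numeracy scores, HDDS, water access, asset
flags, ...) are synthesized at the deprivation-rule boundary with jitter
inside the legal range: downstream analysis consumes only the binary
outcome, so within-category detail is cosmetic.  Monetary income is zero
with a calibrated probability (default 49%, tied to the same latent so
no-income households cluster with the deprived) and lognormal otherwise.
A household wealth latent shares the well-being latent (households unlikely
to be deprived are likely to own assets) and drives 37 binary
asset-ownership items through a one-factor probit model.  Urban households
carry a configurable latent advantage, so urban poverty is systematically
lower; the threshold calibration accounts for the rural/urban mixture.

Sampling probabilities follow a two-stage design: EAs drawn proportional to
a synthetic size measure, households (approximately) equal-probability within
EA; strata are district x urban/rural.  All randomness flows from one
``numpy`` Generator, so a fixed seed reproduces the tables bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.linalg import cholesky

from .errors import ConfigError, ValidationError

__all__ = [
    "SimConfig",
    "SurveyTables",
    "generate_survey",
    "spatial_latent_field",
    "calibrate_threshold",
    "expected_headcount",
    "simulate_wealth_items",
    "DEFAULT_TARGET_MARGINALS",
]

#: default deprivation marginals, in canonical indicator order
DEFAULT_TARGET_MARGINALS: tuple[float, ...] = (
    0.147, 0.176, 0.215, 0.154, 0.304, 0.951, 0.297, 0.756, 0.925, 0.959, 0.432,
)

#: district names with EA allocation shares (three focal districts + rest)
DEFAULT_DISTRICTS: tuple[tuple[str, float], ...] = (
    ("Morrumbala", 65 / 259),
    ("Namacurra", 64 / 259),
    ("Alto Molocue", 64 / 259),
    ("Outros", 66 / 259),
)

_LANGUAGES = ("Cisena", "Elomwe", "Echuabo", "Portuguese", "Cinyanja", "Emakhuwa")
_LANGUAGE_P = (0.443, 0.276, 0.256, 0.013, 0.008, 0.004)


@dataclass
class SimConfig:
    """Parameters of the synthetic survey; defaults are the study conditions."""

    n_eas: int = 259
    households_per_ea: int = 15
    rural_fraction: float = 0.96
    district_labels: tuple[tuple[str, float], ...] = DEFAULT_DISTRICTS
    target_marginals: tuple[float, ...] = DEFAULT_TARGET_MARGINALS
    latent_spatial_range: float = 10.0
    latent_sill: float = 0.3
    ea_bbox: tuple[float, float, float, float] = (0.0, 0.0, 100.0, 100.0)
    income_zero_fraction: float = 0.49
    urban_latent_shift: float = 0.75
    calibration: str = "sample"
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n_eas, (int, np.integer)) or self.n_eas < 2:
            raise ConfigError("n_eas must be an integer >= 2")
        if self.households_per_ea < 1:
            raise ConfigError("households_per_ea must be >= 1")
        if not 0 <= self.rural_fraction <= 1:
            raise ConfigError("rural_fraction must lie in [0, 1]")
        if len(self.target_marginals) != 11:
            raise ConfigError("target_marginals must list 11 proportions")
        if any(not 0 <= p <= 1 for p in self.target_marginals):
            raise ConfigError("target_marginals entries must lie in [0, 1]")
        if self.latent_sill < 0:
            raise ConfigError("latent_sill must be >= 0")
        if self.latent_sill > 0 and self.latent_spatial_range <= 0:
            raise ConfigError("latent_spatial_range must be > 0 when latent_sill > 0")
        x0, y0, x1, y1 = self.ea_bbox
        if not (x1 > x0 and y1 > y0):
            raise ConfigError("ea_bbox must satisfy xmax > xmin and ymax > ymin")
        if not 0 <= self.income_zero_fraction <= 1:
            raise ConfigError("income_zero_fraction must lie in [0, 1]")
        if self.urban_latent_shift < 0:
            raise ConfigError("urban_latent_shift must be >= 0")
        if self.calibration not in ("sample", "population"):
            raise ConfigError("calibration must be 'sample' or 'population'")
        if not self.district_labels or any(s <= 0 for _, s in self.district_labels):
            raise ConfigError("district_labels shares must be positive")


@dataclass
class SurveyTables:
    """Generated household and EA tables."""

    households: pd.DataFrame
    eas: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)

    def write(self, out_dir) -> None:
        """Write households.csv, eas.csv, eas.geojson and a config echo."""
        from pathlib import Path
        from .geo import points_to_geojson

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.households.to_csv(out / "households.csv", index=False)
        self.eas.to_csv(out / "eas.csv", index=False)
        gj = points_to_geojson(
            self.eas, props=["ea_id", "district", "stratum", "sampling_probability"]
        )
        (out / "eas.geojson").write_text(json.dumps(gj))
        if self.config is not None:
            (out / "sim_config.json").write_text(
                json.dumps(asdict(self.config), indent=2, default=str)
            )


def calibrate_threshold(target_rate: float, latent_sd: float = 0.0) -> float:
    """Probit threshold t with P(latent + noise < t) = target_rate.

    ``latent_sd`` is the standard deviation of the shared (EA) latent on top
    of unit household noise; t = sqrt(1 + latent_sd^2) * Phi^-1(rate).
    Rates of exactly 0 or 1 return -inf / +inf sentinels.
    """
    if not 0 <= target_rate <= 1:
        raise ConfigError("target_rate must lie in [0, 1]")
    if latent_sd < 0:
        raise ConfigError("latent_sd must be >= 0")
    if target_rate == 0:
        return -np.inf
    if target_rate == 1:
        return np.inf
    return float(math.sqrt(1.0 + latent_sd**2) * ndtri(target_rate))


def _population_threshold(
    target_rate: float, latent_sd: float, urban_shift: float, urban_frac: float
) -> float:
    """Threshold matching the target marginal over the rural/urban mixture."""
    if urban_frac == 0.0 or urban_shift == 0.0:
        return calibrate_threshold(target_rate, latent_sd)
    if target_rate == 0:
        return -np.inf
    if target_rate == 1:
        return np.inf
    s1 = math.sqrt(1.0 + latent_sd**2)

    def f(t: float) -> float:
        return (
            (1.0 - urban_frac) * ndtr(t / s1)
            + urban_frac * ndtr((t - urban_shift) / s1)
            - target_rate
        )

    base = s1 * float(ndtri(target_rate))
    return float(brentq(f, base - 2 - urban_shift, base + 2 + urban_shift, xtol=1e-12))


def _sample_threshold(target_rate: float, z_hh: np.ndarray) -> float:
    """Threshold solved so the realized mean of Phi(t - z) equals the target."""
    if target_rate == 0:
        return -np.inf
    if target_rate == 1:
        return np.inf
    base = float(ndtri(target_rate))
    span = float(np.max(np.abs(z_hh))) + 8.0 if len(z_hh) else 8.0

    def f(t: float) -> float:
        return float(np.mean(ndtr(t - z_hh))) - target_rate

    return float(brentq(f, base - span, base + span, xtol=1e-12))


def spatial_latent_field(ea_coords, range_param: float, sill: float, seed) -> np.ndarray:
    """Draw a zero-mean Gaussian field with covariance sill*exp(-d/range).

    ``seed`` may be an integer or a ``numpy.random.Generator``.  Coincident
    points receive identical values; a zero sill returns exact zeros.
    """
    pts = np.asarray(ea_coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise ValidationError("ea_coords must be an (n, 2) array with n >= 1")
    if not np.isfinite(pts).all():
        raise ValidationError("ea_coords must be finite")
    if sill < 0:
        raise ValidationError("sill must be >= 0")
    if sill == 0:
        return np.zeros(len(pts))
    if range_param <= 0:
        raise ValidationError("range_param must be > 0 when sill > 0")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    uniq, inv = np.unique(pts, axis=0, return_inverse=True)
    d = np.sqrt(
        ((uniq[:, None, :] - uniq[None, :, :]) ** 2).sum(axis=2)
    )
    cov = sill * np.exp(-d / range_param)
    jitter = 1e-10 * sill
    for _ in range(3):
        try:
            chol = cholesky(cov + jitter * np.eye(len(uniq)), lower=True)
            break
        except np.linalg.LinAlgError:
            jitter *= 100
    else:  # pragma: no cover - exponential covariance is positive definite
        raise ValidationError("covariance matrix is not positive definite")
    z_uniq = chol @ rng.standard_normal(len(uniq))
    return z_uniq[inv]


def _largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    shares = shares / shares.sum()
    quotas = shares * total
    base = np.floor(quotas).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:rem]] += 1
    return base


def generate_survey(config: SimConfig) -> SurveyTables:
    """Generate the EA and household tables for one synthetic survey."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_eas = int(config.n_eas)
    m_hh = int(config.households_per_ea)
    n = n_eas * m_hh
    x0, y0, x1, y1 = map(float, config.ea_bbox)

    # --- EA frame: districts occupy vertical strips of the bounding box ---
    names = [d for d, _ in config.district_labels]
    shares = np.array([s for _, s in config.district_labels], dtype=float)
    counts = _largest_remainder(shares, n_eas)
    edges = np.concatenate([[0.0], np.cumsum(shares / shares.sum())])
    district = np.repeat(names, counts)
    strip_lo = np.repeat(x0 + edges[:-1] * (x1 - x0), counts)
    strip_hi = np.repeat(x0 + edges[1:] * (x1 - x0), counts)
    ex = strip_lo + rng.random(n_eas) * (strip_hi - strip_lo)
    ey = y0 + rng.random(n_eas) * (y1 - y0)

    n_urban = int(round((1.0 - config.rural_fraction) * n_eas))
    urban = np.zeros(n_eas, dtype=np.int8)
    if n_urban > 0:
        urban[rng.choice(n_eas, size=n_urban, replace=False)] = 1
    stratum = np.array(
        [f"{d}:{'urban' if u else 'rural'}" for d, u in zip(district, urban)]
    )

    # two-stage selection probabilities: PPS EAs, equal-probability households
    size_measure = rng.integers(60, 401, size=n_eas)
    pi_ea = np.clip(0.3 * size_measure / size_measure.mean(), 0.02, 0.95)
    pi_hh = np.minimum(1.0, m_hh / size_measure)
    p_samp = pi_ea * pi_hh

    coords = np.column_stack([ex, ey])
    z = spatial_latent_field(
        coords, config.latent_spatial_range, config.latent_sill, rng
    )

    eas = pd.DataFrame(
        {
            "ea_id": [f"ea{i:04d}" for i in range(n_eas)],
            "district": district,
            "stratum": stratum,
            "urban": urban,
            "x": ex,
            "y": ey,
            "size_measure": size_measure,
            "sampling_probability": p_samp,
            "latent_effect": z,
        }
    )

    # --- households ---
    ea_idx = np.repeat(np.arange(n_eas), m_hh)
    # urban households carry a latent advantage (systematically less deprived)
    z_hh = z[ea_idx] + config.urban_latent_shift * urban[ea_idx]
    latent_sd = math.sqrt(config.latent_sill)
    urban_frac = float(urban[ea_idx].mean())

    t = np.empty(11)
    for j, p in enumerate(config.target_marginals):
        if config.calibration == "population":
            t[j] = _population_threshold(
                p, latent_sd, config.urban_latent_shift, urban_frac
            )
        else:
            t[j] = _sample_threshold(p, z_hh)
    eps = rng.standard_normal((n, 11))
    with np.errstate(invalid="ignore"):
        dep = (z_hh[:, None] + eps < t[None, :]).astype(np.int8)

    d0, d1, d2, d3, d4, d5, d6, d7, d8, d9, d10 = (dep[:, j] == 1 for j in range(11))

    # literacy/numeracy at the rule boundary (deprived: both low; else break one)
    lit_dep = rng.integers(0, 16, n)
    num_dep = rng.integers(0, 5, n)
    coin = rng.random(n) < 0.5
    lit_a, num_a = rng.integers(16, 31, n), rng.integers(0, 11, n)
    lit_b, num_b = rng.integers(0, 31, n), rng.integers(5, 11, n)
    literacy = np.where(d0, lit_dep, np.where(coin, lit_a, lit_b))
    numeracy = np.where(d0, num_dep, np.where(coin, num_a, num_b))

    # school-aged children: deprived households have one out of school
    has_child_free = rng.random(n) < 0.65
    has_child = np.where(d1, 1, has_child_free.astype(int)).astype(np.int8)
    attending = pd.array(
        np.where(d1, 0, np.where(has_child_free, 1, -1)), dtype="Int64"
    )
    attending[np.asarray(attending == -1)] = pd.NA

    hdds = np.where(d3, rng.integers(0, 4, n), rng.integers(4, 13, n))

    # water access: deprived = river OR (>30 min on foot)
    case_dep = rng.integers(0, 3, n)
    far_any = rng.integers(0, 2, n)
    foot_any = rng.integers(0, 2, n)
    case_ok = rng.integers(0, 3, n)  # (far, foot) in {(0,0),(0,1),(1,0)}
    river = np.where(d6, (case_dep != 1).astype(int), 0).astype(np.int8)
    far = np.where(
        d6, np.where(case_dep == 0, far_any, 1), (case_ok == 2).astype(int)
    ).astype(np.int8)
    foot = np.where(
        d6, np.where(case_dep == 0, foot_any, 1), (case_ok == 1).astype(int)
    ).astype(np.int8)

    pattern = rng.integers(1, 8, n)  # non-empty subset of {radio, tv, bike}
    radio = np.where(d10, 0, pattern & 1).astype(np.int8)
    tv = np.where(d10, 0, (pattern >> 1) & 1).astype(np.int8)
    bike = np.where(d10, 0, (pattern >> 2) & 1).astype(np.int8)

    # monetary income: zero tied to the same latent; lognormal otherwise
    if config.calibration == "population":
        t_inc = _population_threshold(
            config.income_zero_fraction, latent_sd,
            config.urban_latent_shift, urban_frac,
        )
    else:
        t_inc = _sample_threshold(config.income_zero_fraction, z_hh)
    eps_inc = rng.standard_normal(n)
    with np.errstate(invalid="ignore"):
        zero_inc = z_hh + eps_inc < t_inc
    amounts = np.maximum(1, np.round(rng.lognormal(math.log(400.0), 1.25, n)))
    income = np.where(zero_inc, 0.0, amounts)

    household_size = 1 + rng.poisson(3.2, n)
    language = rng.choice(_LANGUAGES, size=n, p=_LANGUAGE_P)

    # wealth latent rises with the same latent that lowers deprivation,
    # so deprived households cluster in the low-wealth tail
    eps_w = rng.standard_normal(n)
    theta = (z_hh + eps_w) / math.sqrt(1.0 + config.latent_sill)
    loadings = rng.uniform(0.6, 1.6, 37)
    intercepts = rng.normal(-0.4, 0.9, 37)
    probs = ndtr(intercepts[None, :] + theta[:, None] * loadings[None, :])
    items = (rng.random((n, 37)) < probs).astype(np.int8)

    households = pd.DataFrame(
        {
            "household_id": [f"hh{i:05d}" for i in range(n)],
            "ea_id": eas["ea_id"].to_numpy()[ea_idx],
            "district": district[ea_idx],
            "stratum": stratum[ea_idx],
            "urban": urban[ea_idx],
            "language": language,
            "sampling_probability": p_samp[ea_idx],
            "literacy_score": literacy,
            "numeracy_score": numeracy,
            "has_school_age_child": has_child,
            "school_age_child_attending": attending,
            "child_acute_illness": d2.astype(np.int8),
            "hdds": hdds,
            "lack_food_episode": d4.astype(np.int8),
            "electricity": (1 - dep[:, 5]).astype(np.int8),
            "water_source_river": river,
            "water_time_gt30": far,
            "water_on_foot": foot,
            "uses_latrine": (1 - dep[:, 7]).astype(np.int8),
            "roof_grass": d8.astype(np.int8),
            "cooks_with_wood": d9.astype(np.int8),
            "owns_radio": radio,
            "owns_tv": tv,
            "owns_bicycle": bike,
            "monthly_income_mzn": income,
            "household_size": household_size,
        }
    )
    for m in range(37):
        households[f"asset_{m + 1:02d}"] = items[:, m]

    return SurveyTables(households=households, eas=eas, config=config)


def simulate_wealth_items(
    n: int,
    n_items: int = 37,
    loadings: np.ndarray | None = None,
    intercepts: np.ndarray | None = None,
    seed: int = 0,
):
    """Binary asset items from a one-factor probit model with known truth.

    Returns ``(items, theta, loadings, intercepts)`` for recovery studies.
    """
    rng = np.random.default_rng(seed)
    if loadings is None:
        loadings = rng.uniform(0.6, 1.6, n_items)
    if intercepts is None:
        intercepts = rng.normal(-0.3, 0.9, n_items)
    loadings = np.asarray(loadings, dtype=float)
    intercepts = np.asarray(intercepts, dtype=float)
    theta = rng.standard_normal(n)
    probs = ndtr(intercepts[None, :] + theta[:, None] * loadings[None, :])
    items = (rng.random((n, len(loadings))) < probs).astype(np.int8)
    return items, theta, loadings, intercepts


def expected_headcount(
    weights: Sequence[Fraction],
    marginals: Sequence[float],
    sill: float,
    k: Fraction = Fraction(1, 3),
    inclusive: bool = True,
    n_quad: int = 96,
) -> float:
    """Exact superpopulation headcount under population-calibrated thresholds.

    Conditional on the EA effect z, the indicators are independent Bernoulli
    with rates Phi(t_j - z); the distribution of the integer score numerator
    follows by dynamic programming, and the marginal headcount integrates
    over z ~ N(0, sill) with Gauss-Hermite quadrature.  Used as the known
    estimand in coverage studies of the design-based variance.  Describes an
    all-rural configuration (``rural_fraction=1``); with urban households the
    urban latent advantage shifts the mixture.
    """
    weights = [Fraction(w) for w in weights]
    if len(weights) != len(marginals):
        raise ValidationError("weights and marginals must align")
    lcd = math.lcm(*(w.denominator for w in weights))
    wnum = [int(w * lcd) for w in weights]
    k = Fraction(k)
    latent_sd = math.sqrt(sill)
    t = np.array([calibrate_threshold(p, latent_sd) for p in marginals])

    if sill == 0:
        zs, wz = np.array([0.0]), np.array([1.0])
    else:
        x, w = np.polynomial.hermite.hermgauss(n_quad)
        zs = math.sqrt(2.0 * sill) * x
        wz = w / math.sqrt(math.pi)

    h = 0.0
    for z, wq in zip(zs, wz):
        with np.errstate(invalid="ignore"):
            pj = ndtr(t - z)
        probs = np.zeros(lcd + 1)
        probs[0] = 1.0
        for p, wn in zip(pj, wnum):
            new = probs * (1.0 - p)
            new[wn:] += probs[: lcd + 1 - wn] * p
            probs = new
        if inclusive:
            cut = math.ceil(k * lcd)
        else:
            cut = math.floor(k * lcd) + 1
        h += wq * float(probs[cut:].sum())
    return h
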