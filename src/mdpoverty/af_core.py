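"""The Alkire-Foster dual-cutoff counting engine.

Identification and aggregation work on the binary deprivation matrix g0 with
exact rational indicator weights w_j (sum 1).  Each household's deprivation
score is c_i = sum_j w_j g0[i,j]; with the default weights every attainable
score is a multiple of 1/36.  A household is poor when c_i >= k (inclusive
rule, default k = 1/3; an exclusive ``>`` variant is available).  Scores of
the non-poor are censored to zero and, with sampling weights s_i,

    H  = sum(s poor) / sum(s)                (headcount ratio)
    A  = sum(s c poor) / sum(s poor)         (intensity among the poor)
    M0 = sum(s c(k)) / sum(s) = H * A        (adjusted headcount)

M0 also equals sum_j w_j CH_j where CH_j is the censored headcount of
indicator j (weighted share both poor and deprived in j); indicator
contributions are w_j CH_j / M0.  Scores and the poverty cut-off are compared
in exact integer arithmetic (numerators over the weight LCD), so households
sitting exactly at c = k never flip with floating-point noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .deprivation import DeprivationMatrix
from .errors import ValidationError
from .survey_stats import SurveyDesign, weighted_ratio_ci

__all__ = [
    "AFParams",
    "AFResult",
    "deprivation_scores",
    "identify_poor",
    "censor_scores",
    "aggregate",
    "subgroup_decomposition",
    "robustness_curve",
    "attainable_scores",
    "default_k_grid",
]


@dataclass(frozen=True)
class AFParams:
    """Poverty cut-off k (exact rational) and identification rule."""

    k: Fraction = Fraction(1, 3)
    inclusive: bool = True

    def __post_init__(self) -> None:
        k = Fraction(self.k)
        object.__setattr__(self, "k", k)
        if not (0 < k <= 1):
            raise ValidationError("poverty cut-off k must lie in (0, 1]")


def _score_numerators(m: DeprivationMatrix) -> tuple[np.ndarray, int]:
    """Integer score numerators over the LCD of the weights."""
    lcd = math.lcm(*(w.denominator for w in m.weights))
    wnum = np.array([int(w * lcd) for w in m.weights], dtype=np.int64)
    return m.g0.astype(np.int64) @ wnum, lcd


def deprivation_scores(m: DeprivationMatrix) -> np.ndarray:
    """Weighted deprivation score c_i in [0, 1] per household."""
    num, lcd = _score_numerators(m)
    return num / lcd


def identify_poor(c, params: AFParams = AFParams()) -> np.ndarray:
    """Binary poor flag per household from scores (floats or Fractions)."""
    carr = np.asarray(c)
    if carr.dtype == object:  # exact scores
        k = params.k
        if params.inclusive:
            return np.array([ci >= k for ci in carr], dtype=np.int8)
        return np.array([ci > k for ci in carr], dtype=np.int8)
    kf = float(params.k)
    if params.inclusive:
        return (carr >= kf - 1e-12).astype(np.int8)
    return (carr > kf + 1e-12).astype(np.int8)


def _identify_exact(m: DeprivationMatrix, params: AFParams) -> np.ndarray:
    num, lcd = _score_numerators(m)
    k = params.k
    lhs = num * k.denominator
    rhs = k.numerator * lcd
    return (lhs >= rhs if params.inclusive else lhs > rhs).astype(np.int8)


def censor_scores(c, poor_flags) -> np.ndarray:
    """Zero the scores of non-poor households."""
    c = np.asarray(c, dtype=float)
    poor = np.asarray(poor_flags)
    if c.shape != poor.shape:
        raise ValidationError("scores and poor flags must align")
    return c * poor


@dataclass
class AFResult:
    """Aggregated poverty measures with design-based confidence intervals."""

    H: float
    A: float
    M0: float
    censored_headcounts: dict[str, float]
    contributions: dict[str, float] | None
    dimension_contributions: dict[str, float] | None
    n_effective: float
    n: int
    ci_H: tuple[float, float] | None = None
    ci_A: tuple[float, float] | None = None
    ci_M0: tuple[float, float] | None = None

    def as_dict(self) -> dict:
        return {
            "H": self.H,
            "A": self.A,
            "M0": self.M0,
            "ci_H": self.ci_H,
            "ci_A": self.ci_A,
            "ci_M0": self.ci_M0,
            "censored_headcounts": self.censored_headcounts,
            "indicator_contributions": self.contributions,
            "dimension_contributions": self.dimension_contributions,
            "n": self.n,
            "n_effective": self.n_effective,
        }


def aggregate(
    m: DeprivationMatrix,
    params: AFParams = AFParams(),
    confidence: float = 0.95,
    compute_ci: bool = True,
) -> AFResult:
    """Compute H, A, M0, censored headcounts, contributions and CIs."""
    if m.n == 0:
        raise ValidationError("deprivation matrix is empty")
    num, lcd = _score_numerators(m)
    c = num / lcd
    poor = _identify_exact(m, params).astype(float)
    ck = c * poor
    s = m.design["sampling_weight"].to_numpy(float)
    if not np.all(s > 0):
        raise ValidationError("design weights must be positive")
    stot = float(s.sum())

    H = float(np.sum(s * poor)) / stot
    M0 = float(np.sum(s * ck)) / stot
    A = M0 / H if H > 0 else 0.0

    ch = {
        name: float(np.sum(s * poor * m.g0[:, j])) / stot
        for j, name in enumerate(m.indicator_names)
    }
    if M0 > 0:
        contrib = {
            name: float(m.weights[j]) * ch[name] / M0
            for j, name in enumerate(m.indicator_names)
        }
        dims: dict[str, float] = {}
        for j, name in enumerate(m.indicator_names):
            dims[m.dimensions[j]] = dims.get(m.dimensions[j], 0.0) + contrib[name]
    else:
        contrib = None
        dims = None

    ci_H = ci_A = ci_M0 = None
    if compute_ci:
        design = SurveyDesign.from_frame(m.design)
        _, ci_H, _ = weighted_ratio_ci(poor, np.ones_like(poor), design, confidence)
        _, ci_M0, _ = weighted_ratio_ci(ck, np.ones_like(ck), design, confidence)
        if H > 0:
            _, ci_A, _ = weighted_ratio_ci(ck, poor, design, confidence)

    return AFResult(
        H=H, A=A, M0=M0,
        censored_headcounts=ch,
        contributions=contrib,
        dimension_contributions=dims,
        n_effective=stot,
        n=m.n,
        ci_H=ci_H, ci_A=ci_A, ci_M0=ci_M0,
    )


def subgroup_decomposition(
    m: DeprivationMatrix,
    group_labels,
    params: AFParams = AFParams(),
    confidence: float = 0.95,
    compute_ci: bool = True,
) -> dict:
    """Per-group AF results with population shares.

    The adjusted headcount is additively decomposable: the population-share
    weighted subgroup M0 values recombine exactly to the pooled M0.
    Returns ``{group: {"result": AFResult, "share": float}}``.
    """
    labels = np.asarray(group_labels)
    if len(labels) != m.n:
        raise ValidationError("every household must carry a group label")
    if pd.isna(labels).any():
        raise ValidationError("group labels must not be missing")
    s = m.design["sampling_weight"].to_numpy(float)
    stot = float(s.sum())
    out = {}
    for g in pd.unique(labels):
        mask = labels == g
        if not mask.any():
            warnings.warn(f"group {g!r} is empty; excluded", stacklevel=2)
            continue
        sub = DeprivationMatrix(
            household_ids=m.household_ids[mask],
            g0=m.g0[mask],
            weights=m.weights,
            design=m.design.loc[mask].reset_index(drop=True),
            indicator_names=m.indicator_names,
            dimensions=m.dimensions,
        )
        res = aggregate(sub, params, confidence, compute_ci=compute_ci)
        out[g] = {"result": res, "share": float(s[mask].sum()) / stot}
    return out


def attainable_scores(weights: Sequence[Fraction]) -> list[Fraction]:
    """All subset sums of the weight vector (the attainable scores), sorted."""
    lcd = math.lcm(*(Fraction(w).denominator for w in weights))
    sums = {0}
    for w in weights:
        wn = int(Fraction(w) * lcd)
        sums |= {t + wn for t in sums}
    return [Fraction(t, lcd) for t in sorted(sums)]


def default_k_grid(weights: Sequence[Fraction]) -> list[Fraction]:
    """The robustness grid of poverty cut-offs, spanning 1/9 to 2/3.

    With the default weights (score LCD 36) the grid steps by 2/36 below one
    quarter and by 1/36 from one quarter to two thirds, yielding 19 cut-offs
    {4/36, 6/36, 8/36, 9/36, ..., 24/36} -- the grid conventionally tabulated
    for this indicator set.  For weight vectors whose LCD does not admit that
    construction the grid falls back to every attainable score in [1/9, 2/3].
    """
    lcd = math.lcm(*(Fraction(w).denominator for w in weights))
    if lcd % 36 == 0:
        coarse = range(lcd // 9, lcd // 4, lcd // 18)
        fine = range(lcd // 4, 2 * lcd // 3 + 1, lcd // 36)
        return [Fraction(t, lcd) for t in list(coarse) + list(fine)]
    lo, hi = Fraction(1, 9), Fraction(2, 3)
    return [a for a in attainable_scores(weights) if lo <= a <= hi]


def robustness_curve(
    m: DeprivationMatrix,
    k_grid: Sequence[Fraction] | None = None,
    inclusive: bool = True,
    confidence: float = 0.95,
    compute_ci: bool = True,
) -> pd.DataFrame:
    """Headcount H (with CIs) over a grid of poverty cut-offs.

    H is non-increasing in k: raising the bar for identification can only
    shrink the set of poor households.
    """
    if k_grid is None:
        k_grid = default_k_grid(m.weights)
    k_grid = [Fraction(k) for k in k_grid]
    if len(k_grid) == 0:
        raise ValidationError("k_grid is empty")
    if any(k_grid[i] > k_grid[i + 1] for i in range(len(k_grid) - 1)):
        raise ValidationError("k_grid must be sorted ascending")
    rows = []
    for k in k_grid:
        res = aggregate(
            m, AFParams(k=k, inclusive=inclusive),
            confidence, compute_ci=compute_ci,
        )
        lo, hi = res.ci_H if res.ci_H is not None else (float("nan"),) * 2
        rows.append(
            {"k": float(k), "k_exact": str(k), "H": res.H, "ci_lo": lo, "ci_hi": hi}
        )
    return pd.DataFrame(rows)
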