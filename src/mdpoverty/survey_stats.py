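"""Design-based estimation for stratified, clustered household surveys.

Point estimates are inverse-probability-weighted ratios; variances use Taylor
linearization with the with-replacement PSU approximation: within each
stratum the weighted residual totals of the primary sampling units
(enumeration areas) are contrasted around their stratum mean, and no
finite-population correction is applied.  Confidence intervals use the normal
reference, which is adequate at the PSU counts these surveys run at
(hundreds of enumeration areas).

A stratum containing a single PSU cannot contribute a between-PSU contrast;
by default it is treated as a certainty unit (zero variance contribution,
with a warning).  ``lonely="collapse"`` instead pools all single-PSU strata
into one synthetic stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "SurveyDesign",
    "weighted_mean_ci",
    "weighted_proportion_ci",
    "weighted_ratio_ci",
    "weighted_quantile",
]


@dataclass
class SurveyDesign:
    """Per-household sampling weight, stratum label and PSU (EA) label."""

    weights: np.ndarray
    strata: np.ndarray
    psus: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.strata = np.asarray(self.strata)
        self.psus = np.asarray(self.psus)
        n = len(self.weights)
        if len(self.strata) != n or len(self.psus) != n:
            raise ValidationError("design arrays must have equal length")
        if n == 0:
            raise ValidationError("design is empty")
        if not np.all(self.weights > 0):
            raise ValidationError("sampling weights must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurveyDesign":
        return cls(
            weights=df["sampling_weight"].to_numpy(float),
            strata=df["stratum"].to_numpy(),
            psus=df["ea_id"].to_numpy(),
        )


def _as_design(design) -> SurveyDesign:
    if isinstance(design, SurveyDesign):
        return design
    if isinstance(design, pd.DataFrame):
        return SurveyDesign.from_frame(design)
    raise ValidationError("design must be a SurveyDesign or a design frame")


def weighted_ratio_ci(
    numerator,
    denominator,
    design,
    confidence: float = 0.95,
    lonely: str = "certainty",
):
    """Weighted ratio R = sum(s*y) / sum(s*x) with a linearized CI.

    The linearized residual u_i = s_i (y_i - R x_i) / X_hat is totalled per
    PSU and contrasted within strata.  Means and proportions are the special
    case x == 1.

    Returns ``(estimate, (lo, hi), se)``.
    """
    y = np.asarray(numerator, dtype=float)
    x = np.asarray(denominator, dtype=float)
    d = _as_design(design)
    if len(y) != len(d.weights) or len(x) != len(d.weights):
        raise ValidationError("value arrays must match the design length")
    s = d.weights
    xhat = float(np.sum(s * x))
    if xhat == 0:
        raise ValidationError("zero total weight in the ratio denominator")
    r = float(np.sum(s * y)) / xhat
    u = s * (y - r * x) / xhat

    strata = d.strata
    psus = d.psus
    if lonely == "collapse":
        # pool single-PSU strata into one synthetic stratum
        counts = (
            pd.DataFrame({"h": strata, "c": psus})
            .groupby("h")["c"]
            .nunique()
        )
        lonely_set = set(counts.index[counts < 2])
        if lonely_set:
            strata = np.asarray(
                ["__collapsed__" if h in lonely_set else h for h in strata],
                dtype=object,
            )
    elif lonely != "certainty":
        raise ValidationError("lonely must be 'certainty' or 'collapse'")

    var = 0.0
    frame = pd.DataFrame({"h": strata, "c": psus, "u": u})
    psu_totals = frame.groupby(["h", "c"], sort=True)["u"].sum()
    for h, tot in psu_totals.groupby(level=0, sort=True):
        vals = tot.to_numpy()
        n_h = len(vals)
        if n_h < 2:
            log.warning(
                "stratum %r has a single PSU; treated as a certainty unit "
                "(zero variance contribution)", h,
            )
            continue
        mean_h = vals.mean()
        var += n_h / (n_h - 1) * float(np.sum((vals - mean_h) ** 2))
    se = float(np.sqrt(max(var, 0.0)))
    z = float(ndtri(0.5 + confidence / 2.0))
    return r, (r - z * se, r + z * se), se


def weighted_mean_ci(values, design, confidence: float = 0.95, **kw):
    """Design-weighted mean with Taylor-linearized confidence interval."""
    values = np.asarray(values, dtype=float)
    return weighted_ratio_ci(values, np.ones_like(values), design, confidence, **kw)


def weighted_proportion_ci(flags, design, confidence: float = 0.95, **kw):
    """Design-weighted proportion; flags must be binary."""
    f = np.asarray(flags, dtype=float)
    if not np.isin(f, (0.0, 1.0)).all():
        raise ValidationError("flags must be binary")
    return weighted_mean_ci(f, design, confidence, **kw)


def weighted_quantile(values, weights, q: float) -> float:
    """Smallest value whose cumulative normalized weight reaches ``q``."""
    if not 0 <= q <= 1:
        raise ValidationError("q must lie in [0, 1]")
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValidationError("empty input to weighted_quantile")
    if v.shape != w.shape:
        raise ValidationError("values and weights must align")
    if not np.all(w >= 0) or w.sum() == 0:
        raise ValidationError("weights must be non-negative with positive sum")
    order = np.argsort(v, kind="stable")
    cw = np.cumsum(w[order]) / w.sum()
    idx = int(np.searchsorted(cw, q, side="left"))
    idx = min(idx, v.size - 1)
    return float(v[order][idx])
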