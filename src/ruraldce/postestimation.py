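"""Post-estimation statistics: willingness to accept, relative importance
and marginal uptake-rate change, with delta-method or Krinsky-Robb
uncertainty intervals.

Willingness to accept (WTA) converts an attribute coefficient to monthly
salary (ETB) by dividing it by the salary coefficient: the compensation a
respondent requires to forgo the better level.  Relative importance is the
within-class utility range of each attribute, normalised so the most
influential attribute scores 1; pooled scores weight the per-class scores
by class shares.  The uptake-rate change for a single attribute move is
the paired-choice probability of the improved job against an otherwise
identical base job, expressed as relative change from the 50% base:
Delta% = 100 * (logistic(beta'dx) - 0.5) / 0.5, evaluated at the mixed
logit coefficient means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import AttributeSchema
from .estimation import MIXLResult

#: Smallest |salary coefficient| for which coefficient ratios are reported.
SALARY_COEF_TOL = 1e-12


@dataclass
class WTAEstimate:
    """Willingness to accept for one attribute, in ETB per month."""

    attribute: str
    point: float
    lower: float | None = None
    upper: float | None = None
    method: str | None = None

    def __post_init__(self):
        if self.lower is not None and not (self.lower <= self.point <= self.upper):
            raise ValueError("WTA interval must contain the point estimate")


@dataclass
class UptakeChange:
    """Marginal uptake-rate change for one attribute-level move."""

    base_level: str
    policy_level: str
    delta_pct: float  # percentage points relative to the 50% base
    lower: float | None = None
    upper: float | None = None
    method: str | None = None


@dataclass
class RelativeImportanceTable:
    """Per-class utility ranges and normalised importance scores."""

    ranges: pd.DataFrame  # attributes x classes
    scores: pd.DataFrame  # attributes x classes, max per class = 1
    pooled: pd.Series  # class-share-weighted scores
    shares: np.ndarray


def _mean_and_cov(result, attribute):
    beta_a = float(result.means[attribute])
    beta_s = float(result.means["salary"])
    cov = result.cov.loc[[attribute, "salary"], [attribute, "salary"]].to_numpy()
    return beta_a, beta_s, cov


def wta(result: MIXLResult, attribute: str) -> WTAEstimate:
    """Point willingness to accept: beta_attribute / beta_salary (ETB/month).

    Positive values are the monthly compensation required to forgo the
    better level of the attribute (equivalently, what respondents would
    give up to obtain it).
    """
    beta_s = float(result.means["salary"])
    if abs(beta_s) < SALARY_COEF_TOL:
        raise ValueError("salary coefficient too close to zero for a stable ratio")
    point = float(result.means[attribute]) / beta_s
    return WTAEstimate(attribute=attribute, point=point)


def wta_interval(
    result: MIXLResult,
    attribute: str,
    method: str = "krinsky_robb",
    n_draws: int = 10000,
    seed: int = 0,
    level: float = 0.95,
) -> WTAEstimate:
    """WTA with a confidence interval.

    ``delta``: first-order variance of the ratio r = a/s,
    var(r) = r^2 (var(a)/a^2 + var(s)/s^2 - 2 cov(a,s)/(a s)).
    ``krinsky_robb``: percentile interval over multivariate-normal
    parameter draws (seeded).
    """
    point = wta(result, attribute).point
    beta_a, beta_s, cov = _mean_and_cov(result, attribute)
    _check_psd(cov)
    alpha = 1.0 - level
    if method == "delta":
        grad = np.array([1.0 / beta_s, -beta_a / beta_s**2])
        var = float(grad @ cov @ grad)
        from scipy.stats import norm

        halfwidth = norm.ppf(1 - alpha / 2) * np.sqrt(max(var, 0.0))
        lo, hi = point - halfwidth, point + halfwidth
    elif method == "krinsky_robb":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal([beta_a, beta_s], cov, size=n_draws)
        ratios = draws[:, 0] / draws[:, 1]
        lo, hi = np.quantile(ratios, [alpha / 2, 1 - alpha / 2])
        lo, hi = float(min(lo, point)), float(max(hi, point))
    else:
        raise ValueError(f"unknown interval method {method!r}")
    return WTAEstimate(attribute=attribute, point=point, lower=lo, upper=hi, method=method)


def wta_table(
    result: MIXLResult,
    attributes=None,
    method: str = "krinsky_robb",
    n_draws: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """WTA for every non-salary coefficient, as a tidy table."""
    attributes = attributes or [c for c in result.means.index if c != "salary"]
    rows = []
    for a in attributes:
        est = wta_interval(result, a, method=method, n_draws=n_draws, seed=seed)
        rows.append(
            {"attribute": a, "wta_etb": est.point, "lower": est.lower, "upper": est.upper}
        )
    return pd.DataFrame(rows)


def _check_psd(cov):
    if np.any(np.linalg.eigvalsh(0.5 * (cov + cov.T)) < -1e-8):
        raise ValueError("covariance matrix is not positive semi-definite")


# ---------------------------------------------------------------------------
# Relative importance


def relative_importance(result, schema: AttributeSchema) -> RelativeImportanceTable:
    """Attribute importance per latent class and share-weighted pooled.

    Each attribute's range is the utility difference between its best and
    worst level: |beta_salary| * (max - min salary) for the linear salary
    attribute and |beta_level| for binary attributes.  Ranges are
    normalised by the class maximum (most important attribute scores 1);
    pooled scores are sum_c share_c * score_c.
    """
    coefs = result.class_coefs
    shares = np.asarray(result.shares, dtype=float)
    rows = {}
    for attr in schema.attributes:
        if attr.coding == "linear":
            span = max(attr.numeric_values.values()) - min(attr.numeric_values.values())
            rows[attr.name] = np.abs(coefs.loc[attr.name]) * span
        else:
            cols = list(attr.encoded_columns)
            rows[attr.name] = np.abs(coefs.loc[cols]).max(axis=0)
    ranges = pd.DataFrame(rows).T  # attributes x classes
    scores = ranges / ranges.max(axis=0)
    pooled = scores @ shares
    return RelativeImportanceTable(
        ranges=ranges, scores=scores, pooled=pooled, shares=shares
    )


# ---------------------------------------------------------------------------
# Uptake-rate change


def _delta_x(result, schema: AttributeSchema, base_level: str, policy_level: str):
    """Encoded difference (policy job - base job), one attribute moved."""
    attr = None
    for a in schema.attributes:
        if base_level in a.levels and policy_level in a.levels:
            attr = a
            break
    if attr is None:
        raise ValueError(
            f"levels {base_level!r} and {policy_level!r} do not belong to one attribute"
        )
    dx = pd.Series(0.0, index=result.means.index)
    enc_base = dict(zip(attr.encoded_columns, attr.encode_level(base_level)))
    enc_pol = dict(zip(attr.encoded_columns, attr.encode_level(policy_level)))
    for c in attr.encoded_columns:
        dx[c] = enc_pol[c] - enc_base[c]
    return dx


def uptake_change(
    result: MIXLResult, schema: AttributeSchema, base_level: str, policy_level: str
) -> UptakeChange:
    """Marginal uptake-rate change for one attribute-level move.

    The policy job is pitted against an otherwise identical base job, so
    P(policy) = logistic(beta'dx) with dx the single-attribute encoded
    difference; the change is reported relative to the 50% base:
    Delta% = 100 * (P - 0.5) / 0.5 percentage points.  Point prediction
    uses the mixed logit coefficient means.
    """
    dx = _delta_x(result, schema, base_level, policy_level)
    p = float(expit(result.means @ dx))
    return UptakeChange(
        base_level=base_level,
        policy_level=policy_level,
        delta_pct=100.0 * (p - 0.5) / 0.5,
    )


def uptake_interval(
    result: MIXLResult,
    schema: AttributeSchema,
    base_level: str,
    policy_level: str,
    method: str = "krinsky_robb",
    n_draws: int = 10000,
    seed: int = 0,
    level: float = 0.95,
) -> UptakeChange:
    """Uptake-rate change with a Krinsky-Robb (default) or delta interval."""
    point = uptake_change(result, schema, base_level, policy_level)
    dx = _delta_x(result, schema, base_level, policy_level)
    idx = list(result.means.index)
    cov = result.cov.loc[idx, idx].to_numpy()
    _check_psd(cov)
    alpha = 1.0 - level
    if method == "delta":
        from scipy.stats import norm

        v = float(result.means @ dx)
        # dDelta%/dbeta = 200 * sigma'(v) * dx
        grad = 200.0 * expit(v) * (1 - expit(v)) * dx.to_numpy()
        var = float(grad @ cov @ grad)
        hw = norm.ppf(1 - alpha / 2) * np.sqrt(max(var, 0.0))
        lo, hi = point.delta_pct - hw, point.delta_pct + hw
    elif method == "krinsky_robb":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(result.means.to_numpy(), cov, size=n_draws)
        deltas = 100.0 * (expit(draws @ dx.to_numpy()) - 0.5) / 0.5
        lo, hi = np.quantile(deltas, [alpha / 2, 1 - alpha / 2])
        lo, hi = float(min(lo, point.delta_pct)), float(max(hi, point.delta_pct))
    else:
        raise ValueError(f"unknown interval method {method!r}")
    return UptakeChange(
        base_level=point.base_level,
        policy_level=point.policy_level,
        delta_pct=point.delta_pct,
        lower=lo,
        upper=hi,
        method=method,
    )


def uptake_table(
    result: MIXLResult,
    schema: AttributeSchema,
    moves=None,
    method: str = "krinsky_robb",
    n_draws: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Uptake-rate changes for a set of policy moves (default: every
    improvement from each attribute's first level)."""
    if moves is None:
        moves = []
        for a in schema.attributes:
            base = a.levels[0]
            moves += [(base, lv) for lv in a.levels[1:]]
    rows = []
    for base, policy in moves:
        est = uptake_interval(
            result, schema, base, policy, method=method, n_draws=n_draws, seed=seed
        )
        rows.append(
            {
                "base": base,
                "policy": policy,
                "delta_pct": est.delta_pct,
                "lower": est.lower,
                "upper": est.upper,
            }
        )
    return pd.DataFrame(rows)
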