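"""Panel linear models for repeated measurements per woman.

The model throughout is a simple linear regression ``y = alpha + beta*x``
observed repeatedly within women, where the woman-level intercept may be
treated as fixed (one dummy per woman; the within/LSDV estimator) or
random (a shared intercept plus a woman-level random effect, inducing
compound-symmetric within-woman covariance; fitted by GLS).  A pooled
OLS fit ignores the grouping entirely and supplies the residuals from
which the variance components are estimated by the method of moments:

* ``sigma2_total``  — mean squared pooled residual,
* ``sigma2_between`` — mean within-woman cross-product of residuals
  (the covariance induced by the shared woman effect),
* ``sigma2_within`` = ``sigma2_total - sigma2_between`` (clamped at 0).

GLS then uses the per-woman covariance block
``Omega_i = sigma2_within * I + sigma2_between * J`` through its closed
form inverse, which is algebraically equivalent to quasi-demeaning.

A Hausman-style statistic ``H = (beta_gls - beta_lsdv)**2`` referred to
a chi-square(1) distribution decides between the fixed- and random-
effect views.  As used by the source analysis the decision rule is
inverted relative to standard practice (the random-effect model is
*rejected when p > .05*); both that rule and the conventional one are
selectable — see :func:`hausman_test`.

All estimators accept unbalanced panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError, EstimationError

logger = logging.getLogger(__name__)

_P_PARAMS = 2  # intercept + slope


@dataclass(frozen=True)
class PanelDataset:
    """Observations (woman, x, y) with women encoded as 0..N-1 codes."""

    woman: np.ndarray  # int codes, shape (n_obs,)
    x: np.ndarray
    y: np.ndarray
    ids: np.ndarray  # original labels indexed by code

    def __post_init__(self) -> None:
        n = len(self.x)
        if not (len(self.woman) == len(self.y) == n):
            raise DataError("woman, x, y must have equal length")
        if n == 0:
            raise DataError("empty panel")

    @property
    def n_obs(self) -> int:
        return len(self.x)

    @property
    def n_women(self) -> int:
        return len(self.ids)

    @property
    def counts(self) -> np.ndarray:
        """Observations per woman, indexed by code."""
        return np.bincount(self.woman, minlength=self.n_women)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        id_col: str = "woman_id",
        x_col: str = "x",
        y_col: str = "y",
    ) -> "PanelDataset":
        sub = df[[id_col, x_col, y_col]].dropna()
        if sub.empty:
            raise DataError("no complete (woman, x, y) observations")
        codes, ids = pd.factorize(sub[id_col], sort=True)
        return cls(
            woman=np.asarray(codes, dtype=np.int64),
            x=np.asarray(sub[x_col], dtype=float),
            y=np.asarray(sub[y_col], dtype=float),
            ids=np.asarray(ids),
        )

    @classmethod
    def from_observations(cls, obs: Iterable[tuple]) -> "PanelDataset":
        df = pd.DataFrame(list(obs), columns=["woman_id", "x", "y"])
        return cls.from_frame(df)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"woman_id": self.ids[self.woman], "x": self.x, "y": self.y}
        )


@dataclass(frozen=True)
class LinearFitResult:
    estimator: str  # pooled_ols | lsdv | gls_re
    alpha: float
    beta: float
    resid: np.ndarray
    per_woman_alpha: Mapping | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.alpha + self.beta * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class VarianceComponents:
    """Moment-based residual variance decomposition (days^2)."""

    sigma2_total: float
    sigma2_between: float
    sigma2_within: float


@dataclass(frozen=True)
class HausmanResult:
    statistic: float
    p_value: float
    favored_model: str  # "fixed" | "random"
    rule: str


def _group_sums(panel: PanelDataset, values: np.ndarray) -> np.ndarray:
    return np.bincount(panel.woman, weights=values, minlength=panel.n_women)


def pooled_ols(panel: PanelDataset) -> LinearFitResult:
    """Ordinary least squares ignoring the woman grouping."""
    x, y = panel.x, panel.y
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx <= 0:
        raise EstimationError("pooled OLS: x has no variation (singular design)")
    beta = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    alpha = float(y.mean() - beta * x.mean())
    resid = y - alpha - beta * x
    return LinearFitResult("pooled_ols", alpha, beta, resid)


def lsdv_fit(panel: PanelDataset) -> LinearFitResult:
    """Fixed-effect (within / least-squares-dummy-variable) fit.

    The slope comes solely from within-woman variation; each woman gets
    her own intercept ``alpha_i = ybar_i - xbar_i * beta``.  The
    ``alpha`` field of the result is the observation-weighted mean of
    the per-woman intercepts (a convenience for prediction; the slope
    is the estimand of interest).
    """
    counts = panel.counts
    xbar = _group_sums(panel, panel.x) / counts
    ybar = _group_sums(panel, panel.y) / counts
    xd = panel.x - xbar[panel.woman]
    yd = panel.y - ybar[panel.woman]
    denom = float(np.sum(xd * xd))
    if denom <= 0:
        raise EstimationError("LSDV: no within-woman x variation (singular design)")
    beta = float(np.sum(xd * yd) / denom)
    alpha_i = ybar - xbar * beta
    resid = panel.y - alpha_i[panel.woman] - beta * panel.x
    alpha = float(np.average(alpha_i, weights=counts))
    per_woman = dict(zip(panel.ids.tolist(), alpha_i.tolist()))
    return LinearFitResult("lsdv", alpha, beta, resid, per_woman_alpha=per_woman)


def variance_components(
    panel: PanelDataset, pooled_resid: np.ndarray, p: int = _P_PARAMS
) -> VarianceComponents:
    """Method-of-moments variance components from pooled residuals.

    With ``mu_it`` the pooled residuals, ``T_i`` the per-woman counts
    and ``p`` the number of regression parameters:

        sigma2_total   = sum(mu_it^2) / (sum T_i - p)
        sigma2_between = sum_{i} sum_{t<s} mu_it mu_is
                         / (sum T_i (T_i - 1)/2 - p)
        sigma2_within  = max(sigma2_total - sigma2_between, 0)

    A negative between-woman estimate (possible in small samples) is
    clamped to zero with a warning.
    """
    resid = np.asarray(pooled_resid, dtype=float)
    if len(resid) != panel.n_obs:
        raise DataError("residual vector does not match panel size")
    counts = panel.counts
    n_obs = panel.n_obs
    denom_total = n_obs - p
    if denom_total <= 0:
        raise EstimationError("variance components: too few observations")
    sigma2_total = float(np.sum(resid**2) / denom_total)
    n_pairs = float(np.sum(counts * (counts - 1) / 2))
    denom_between = n_pairs - p
    if denom_between <= 0:
        raise EstimationError(
            "variance components: need more within-woman pairs than parameters"
        )
    group_sum = _group_sums(panel, resid)
    group_sq = _group_sums(panel, resid**2)
    pair_sum = float(np.sum((group_sum**2 - group_sq) / 2.0))
    sigma2_between = pair_sum / denom_between
    if sigma2_between < 0:
        logger.warning(
            "between-woman variance estimate %.4g < 0; clamped to 0", sigma2_between
        )
        sigma2_between = 0.0
    sigma2_within = max(sigma2_total - sigma2_between, 0.0)
    return VarianceComponents(sigma2_total, sigma2_between, sigma2_within)


def gls_random_effects(
    panel: PanelDataset, components: VarianceComponents | None = None
) -> LinearFitResult:
    """Random-effect GLS under per-woman compound-symmetric covariance.

    ``Omega_i = sigma2_within * I + sigma2_between * J`` per woman,
    block-diagonal across women.  Uses the closed-form block inverse
    ``Omega_i^{-1} = (I - g_i J)/sigma2_within`` with
    ``g_i = sigma2_between / (sigma2_within + T_i * sigma2_between)``
    in the 2x2 normal equations, so the fit is exact and O(n).

    When the between component is zero, Omega is proportional to the
    identity and the result coincides with pooled OLS.
    """
    if components is None:
        pooled = pooled_ols(panel)
        components = variance_components(panel, pooled.resid)
    w, b = components.sigma2_within, components.sigma2_between
    counts = panel.counts
    if b == 0.0:
        fit = pooled_ols(panel)
        return LinearFitResult("gls_re", fit.alpha, fit.beta, fit.resid)
    if w <= 0.0 and np.any(counts >= 2):
        raise EstimationError(
            "degenerate covariance: within-woman variance is zero with repeated observations"
        )
    g = b / (w + counts * b)  # per-woman shrinkage factor
    sx = _group_sums(panel, panel.x)
    sy = _group_sums(panel, panel.y)
    sxx = _group_sums(panel, panel.x**2)
    sxy = _group_sums(panel, panel.x * panel.y)
    t = counts.astype(float)
    a11 = np.sum(t - g * t**2) / w
    a12 = np.sum(sx - g * t * sx) / w
    a22 = np.sum(sxx - g * sx**2) / w
    b1 = np.sum(sy - g * t * sy) / w
    b2 = np.sum(sxy - g * sx * sy) / w
    A = np.array([[a11, a12], [a12, a22]])
    rhs = np.array([b1, b2])
    try:
        alpha, beta = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise EstimationError(f"GLS normal equations singular: {exc}") from exc
    resid = panel.y - alpha - beta * panel.x
    return LinearFitResult("gls_re", float(alpha), float(beta), resid)


HAUSMAN_RULES = ("reject_random_if_p_large", "standard")


def hausman_test(
    lsdv: LinearFitResult,
    gls: LinearFitResult,
    rule: str = "reject_random_if_p_large",
) -> HausmanResult:
    """Compare the fixed- and random-effect slopes.

    ``H = (beta_gls - beta_lsdv)**2`` is referred to chi-square(1),
    exactly as used by the source analysis (no variance normalisation;
    the statistic therefore carries units of squared slope and the
    p-value should be read comparatively, not inferentially).

    Rules for ``favored_model``:

    * ``"reject_random_if_p_large"`` (default, mirroring the source
      analysis): the random-effect model is rejected when p > .05.
    * ``"standard"``: conventional reading — a small p (large
      discrepancy) rejects the random-effect model.
    """
    if rule not in HAUSMAN_RULES:
        raise ConfigError(f"unknown Hausman rule {rule!r}; choose from {HAUSMAN_RULES}")
    if lsdv.estimator != "lsdv" or gls.estimator != "gls_re":
        raise DataError("hausman_test expects an LSDV fit and a GLS fit")
    h = float((gls.beta - lsdv.beta) ** 2)
    p = float(stats.chi2.sf(h, df=1))
    if rule == "reject_random_if_p_large":
        favored = "fixed" if p > 0.05 else "random"
    else:
        favored = "fixed" if p < 0.05 else "random"
    return HausmanResult(statistic=h, p_value=p, favored_model=favored, rule=rule)


_ESTIMATORS = {
    "pooled_ols": pooled_ols,
    "ols": pooled_ols,
    "lsdv": lsdv_fit,
    "gls_re": gls_random_effects,
    "gls": gls_random_effects,
}


def fit_panel(panel: PanelDataset, estimator: str = "gls_re") -> LinearFitResult:
    """Dispatch to one of the three estimators by name."""
    try:
        fn = _ESTIMATORS[estimator]
    except KeyError:
        raise ConfigError(
            f"unknown estimator {estimator!r}; choose from {sorted(set(_ESTIMATORS))}"
        ) from None
    return fn(panel)
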