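"""Calendar-based ovulation-date predictors.

All three methods predict the next follicular phase length — and hence
the ovulation date, counted from the last menstruation onset — as a
function of the trailing mean cycle length ``c*`` alone:

* **Ogino**: assumes a fixed 14-day luteal phase, so ovulation falls
  ``floor(c*) - 15`` days after onset.
* **Half cycle length (HCL)**: ovulation at the cycle midpoint,
  ``floor(c* / 2)`` days after onset.
* **Optimized**: ``floor(alpha + beta * c*)`` with (alpha, beta) fitted
  by panel least squares of observed follicular lengths on ``c*``.

The bracket is floor throughout ("rounded down to the nearest
integer"); predictions are therefore integers and monotone
non-decreasing in ``c*`` whenever the slope is non-negative.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

from .errors import ConfigError, PredictionError
from .panel import PanelDataset, fit_panel
from .records import Cycle, trailing_mean_frame

METHODS = ("ogino", "hcl", "opt")


@dataclass(frozen=True)
class OptimizedFit:
    """Fitted linear predictor of follicular length for a given k."""

    k: int
    alpha: float
    beta: float
    estimator: str

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OptimizedFit":
        return cls(k=int(d["k"]), alpha=float(d["alpha"]), beta=float(d["beta"]), estimator=str(d["estimator"]))


def ogino_predict(c_star: float) -> int:
    """Ogino follicular-length prediction: floor(c*) - 15 days."""
    pred = math.floor(c_star) - 15
    if pred < 1:
        raise PredictionError(
            f"Ogino prediction {pred} < 1 day for mean cycle length {c_star}"
        )
    return pred


def hcl_predict(c_star: float) -> int:
    """Half-cycle-length prediction: floor(c*/2) days."""
    if c_star < 2:
        raise PredictionError(f"mean cycle length {c_star} too short for HCL")
    return math.floor(c_star / 2)


def fit_optimized(
    cycles: Sequence[Cycle], k: int, estimator: str = "gls_re"
) -> OptimizedFit:
    """Fit the Optimized predictor for one k.

    Builds the panel x = trailing mean cycle length c*(k), y = observed
    follicular length, over all ovulation-dated cycles whose k past
    cycles exist, and fits the chosen panel estimator.  One fit is
    produced per k; coefficients are not shared across k.
    """
    frame = trailing_mean_frame(cycles, k)
    frame = frame.dropna(subset=["f"])
    panel = PanelDataset.from_frame(frame, x_col="c_star", y_col="f")
    fit = fit_panel(panel, estimator)
    return OptimizedFit(k=k, alpha=fit.alpha, beta=fit.beta, estimator=fit.estimator)


def opt_predict(fit: OptimizedFit, c_star: float) -> int:
    """Optimized prediction: floor(alpha + beta * c*)."""
    pred = math.floor(fit.alpha + fit.beta * c_star)
    if pred < 1:
        raise PredictionError(
            f"optimized prediction {pred} < 1 day for mean cycle length {c_star}"
        )
    return pred


def predict_follicular(
    method: str, c_star: float, fit: OptimizedFit | None = None
) -> int:
    """Dispatch a follicular-length prediction by method name."""
    if method == "ogino":
        return ogino_predict(c_star)
    if method == "hcl":
        return hcl_predict(c_star)
    if method == "opt":
        if fit is None:
            raise ConfigError("the optimized method requires a fitted OptimizedFit")
        return opt_predict(fit, c_star)
    raise ConfigError(f"unknown method {method!r}; choose from {METHODS}")


def predict_ovulation_date(
    onset: dt.date, method: str, c_star: float, fit: OptimizedFit | None = None
) -> dt.date:
    """Predicted ovulation date: onset plus the predicted follicular length."""
    return onset + dt.timedelta(days=predict_follicular(method, c_star, fit))


def write_fits_json(fits: Sequence[OptimizedFit], path) -> None:
    with open(path, "w") as fh:
        json.dump([f.to_dict() for f in fits], fh, indent=2)
        fh.write("\n")


def read_fits_json(path) -> list[OptimizedFit]:
    with open(path) as fh:
        return [OptimizedFit.from_dict(d) for d in json.load(fh)]
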