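"""Summary tables, correlations, per-k panel fits, and predictor accuracy.

This module reproduces the shape of the published analyses on any
derived-cycle set (real or synthetic): phase-length summaries by
integer cycle length, counts of cycles with k past cycles on record,
Pearson correlations between the trailing mean cycle length and
next-cycle quantities, per-k panel fits with the Hausman comparison,
and the head-to-head accuracy of the three calendar predictors at
allowable errors of 0, 1, and 2 days.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .panel import PanelDataset, gls_random_effects, hausman_test, lsdv_fit
from .predictors import METHODS, OptimizedFit, fit_optimized
from .records import Cycle, trailing_mean_frame

_TARGET_COLS = {"next_cycle": "c", "follicular": "f", "luteal": "l"}


def _round_half_up(values: np.ndarray) -> np.ndarray:
    """Nearest-integer bin with deterministic half-up ties."""
    return np.floor(np.asarray(values, dtype=float) + 0.5).astype(int)


def summarize_by_cycle_length(cycles: Sequence[Cycle]) -> pd.DataFrame:
    """Phase-length summary: one row per integer cycle length.

    Only ovulation-dated cycles contribute.  The (lo, hi) range columns
    are the central 95% range of *individual* phase lengths (2.5th to
    97.5th percentile, rounded to integer days), spanning between-woman
    variation rather than a standard error of the mean.
    """
    rows = []
    dated = [cy for cy in cycles if cy.f is not None]
    by_c: dict[int, list[Cycle]] = {}
    for cy in dated:
        by_c.setdefault(cy.c, []).append(cy)
    for c in sorted(by_c):
        grp = by_c[c]
        f = np.array([cy.f for cy in grp], dtype=float)
        l = np.array([cy.l for cy in grp], dtype=float)
        rows.append(
            {
                "cycle_length": c,
                "n": len(grp),
                "mean_f": float(f.mean()),
                "f_lo": int(round(np.percentile(f, 2.5))),
                "f_hi": int(round(np.percentile(f, 97.5))),
                "mean_l": float(l.mean()),
                "l_lo": int(round(np.percentile(l, 2.5))),
                "l_hi": int(round(np.percentile(l, 97.5))),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cycle_length", "n", "mean_f", "f_lo", "f_hi", "mean_l", "l_lo", "l_hi"],
    )


def past_record_counts(cycles: Sequence[Cycle], k_max: int = 8) -> pd.DataFrame:
    """Ovulation-dated cycles with k screened past cycles, by mean-length bin.

    Long format (bin, k, n): for each k = 1..k_max, counts the
    ovulation-dated cycles whose k immediately preceding cycles all
    survived screening, binned by the nearest integer of the trailing
    mean c*(k).  Since a cycle eligible at k is eligible at every
    smaller k, total counts are non-increasing in k.
    """
    if k_max < 1:
        raise ConfigError(f"k_max must be >= 1, got {k_max}")
    rows = []
    for k in range(1, k_max + 1):
        frame = trailing_mean_frame(cycles, k)
        frame = frame.dropna(subset=["f"])
        if frame.empty:
            continue
        bins = _round_half_up(frame["c_star"].to_numpy())
        for b, n in pd.Series(bins).value_counts().sort_index().items():
            rows.append({"bin": int(b), "k": k, "n": int(n)})
    return pd.DataFrame(rows, columns=["bin", "k", "n"])


def depth_totals(counts: pd.DataFrame) -> dict[int, int]:
    """Total eligible ovulation-dated cycles per k, summed over bins."""
    return {int(k): int(v) for k, v in counts.groupby("k")["n"].sum().items()}


def correlation_with_mean(
    cycles: Sequence[Cycle], k: int, target: str = "follicular"
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between c*(k) and a next-cycle quantity.

    ``target`` is ``"next_cycle"`` (the cycle length itself),
    ``"follicular"``, or ``"luteal"``; the latter two restrict to
    ovulation-dated cycles.  p comes from the exact t transform with
    n - 2 degrees of freedom.
    """
    if target not in _TARGET_COLS:
        raise ConfigError(f"unknown target {target!r}; choose from {sorted(_TARGET_COLS)}")
    frame = trailing_mean_frame(cycles, k).dropna(subset=[_TARGET_COLS[target]])
    x = frame["c_star"].to_numpy(dtype=float)
    y = frame[_TARGET_COLS[target]].to_numpy(dtype=float)
    if len(x) < 3:
        raise DataError(f"need >= 3 pairs for a correlation, have {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("correlation undefined: zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def per_k_fits(
    cycles: Sequence[Cycle],
    k_range: Iterable[int] = range(1, 9),
    hausman_rule: str = "reject_random_if_p_large",
) -> pd.DataFrame:
    """GLS coefficients and Hausman comparison per k and phase target.

    For each k and each target (follicular, luteal), builds the panel
    x = c*(k), y = phase length, fits LSDV and random-effect GLS, and
    reports the GLS (alpha, beta) with the Hausman statistic and
    p-value.
    """
    rows = []
    for k in k_range:
        frame = trailing_mean_frame(cycles, k)
        for target in ("follicular", "luteal"):
            sub = frame.dropna(subset=[_TARGET_COLS[target]])
            panel = PanelDataset.from_frame(sub, x_col="c_star", y_col=_TARGET_COLS[target])
            gls = gls_random_effects(panel)
            lsdv = lsdv_fit(panel)
            hm = hausman_test(lsdv, gls, rule=hausman_rule)
            rows.append(
                {
                    "k": k,
                    "target": target,
                    "alpha": gls.alpha,
                    "beta": gls.beta,
                    "beta_lsdv": lsdv.beta,
                    "hausman_H": hm.statistic,
                    "hausman_p": hm.p_value,
                    "favored_model": hm.favored_model,
                    "n_obs": panel.n_obs,
                    "n_women": panel.n_women,
                }
            )
    return pd.DataFrame(rows)


def accuracy_by_mean_cycle(
    cycles: Sequence[Cycle],
    method: str,
    e: int,
    k: int,
    fit: OptimizedFit | None = None,
) -> pd.DataFrame:
    """Fraction of correctly predicted ovulation days per mean-length bin.

    A prediction is correct when |predicted - observed follicular
    length| <= e days.  Cycles are binned by the nearest integer of
    c*(k); empty bins are omitted.  Returns columns
    (method, k, e, bin, n, accuracy).
    """
    if method not in METHODS:
        raise ConfigError(f"unknown method {method!r}; choose from {METHODS}")
    if e < 0:
        raise ConfigError("allowable error e must be >= 0")
    if method == "opt":
        if fit is None:
            raise ConfigError("the optimized method requires a fitted OptimizedFit")
        if fit.k != k:
            raise ConfigError(f"fit was produced for k={fit.k}, evaluation requested k={k}")
    frame = trailing_mean_frame(cycles, k).dropna(subset=["f"])
    if frame.empty:
        return pd.DataFrame(columns=["method", "k", "e", "bin", "n", "accuracy"])
    c_star = frame["c_star"].to_numpy(dtype=float)
    f_obs = frame["f"].to_numpy(dtype=float)
    if method == "ogino":
        pred = np.floor(c_star) - 15
    elif method == "hcl":
        pred = np.floor(c_star / 2)
    else:
        pred = np.floor(fit.alpha + fit.beta * c_star)
    correct = np.abs(pred - f_obs) <= e
    bins = _round_half_up(c_star)
    df = pd.DataFrame({"bin": bins, "correct": correct})
    grouped = df.groupby("bin")["correct"].agg(["size", "mean"]).reset_index()
    out = pd.DataFrame(
        {
            "method": method,
            "k": k,
            "e": e,
            "bin": grouped["bin"].astype(int),
            "n": grouped["size"].astype(int),
            "accuracy": grouped["mean"].astype(float),
        }
    )
    return out


def mean_accuracy(cells: pd.DataFrame, pooled: bool = False) -> float:
    """Mean accuracy across mean-cycle-length bins for one (method, e, k).

    Default is the unweighted mean over bins, so sparse extreme bins
    count as much as the crowded centre; ``pooled=True`` weights bins
    by cycle count (the overall fraction correct).
    """
    if cells.empty:
        raise DataError("no accuracy cells to average")
    if pooled:
        return float(np.average(cells["accuracy"], weights=cells["n"]))
    return float(cells["accuracy"].mean())


def accuracy_report(
    cycles: Sequence[Cycle],
    methods: Sequence[str] = METHODS,
    errors: Sequence[int] = (0, 1, 2),
    k_range: Iterable[int] = range(1, 9),
    estimator: str = "gls_re",
    fits: dict[int, OptimizedFit] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full accuracy grid over (method, e, k) plus per-combination means.

    Fits the optimized predictor per k (unless pre-fitted ``fits`` are
    supplied), evaluates every requested combination, and returns
    (cells, means) where ``means`` has one row per method x e x k with
    the unweighted and pooled mean accuracies.
    """
    k_list = list(k_range)
    if fits is None and "opt" in methods:
        fits = {k: fit_optimized(cycles, k, estimator) for k in k_list}
    cell_frames = []
    mean_rows = []
    for k in k_list:
        for method in methods:
            fit = fits.get(k) if (fits and method == "opt") else None
            for e in errors:
                cells = accuracy_by_mean_cycle(cycles, method, e, k, fit)
                if cells.empty:
                    continue
                cell_frames.append(cells)
                mean_rows.append(
                    {
                        "method": method,
                        "k": k,
                        "e": e,
                        "mean_accuracy": mean_accuracy(cells),
                        "pooled_accuracy": mean_accuracy(cells, pooled=True),
                        "n": int(cells["n"].sum()),
                    }
                )
    cells_df = (
        pd.concat(cell_frames, ignore_index=True)
        if cell_frames
        else pd.DataFrame(columns=["method", "k", "e", "bin", "n", "accuracy"])
    )
    return cells_df, pd.DataFrame(mean_rows)
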