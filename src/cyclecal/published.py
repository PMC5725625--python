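"""Published summary statistics for the original app-tracked cohort.

The analyses this package re-implements were originally run on a
proprietary dataset from a Japanese cycle-tracking app: 7043 women who
wanted to conceive and had recorded at least one cycle with an
ovulation date.  The raw records are not public; what is public is a
set of aggregate tables — phase lengths by cycle length, counts of
cycles with k past cycles on record, and fitted panel-model
coefficients.  Those aggregates are reproduced here as plain data so
they can serve two purposes:

* calibrating the synthetic generator (:mod:`cyclecal.synth`) so that
  simulated cohorts have the reported marginal structure, and
* internal-consistency checks (the per-row counts, means, and totals
  must cohere with the reported overall means and fractions).
"""

from __future__ import annotations

import pandas as pd

#: Cohort size after screening to women with >= 1 ovulation-dated cycle.
N_WOMEN = 7043

#: All recorded cycles, before the 20-45 day screen.
TOTAL_CYCLES = 135_666

#: Cycles carrying a usable ovulation date.
OVULATION_DATED_CYCLES = 12_731

#: Ovulation-dated cycles with at least 8 screened past cycles.
CYCLES_WITH_8_PAST = 7285

#: Reported overall means (days) over ovulation-dated cycles.
OVERALL_MEAN = {"cycle": 29.76, "follicular": 14.84, "luteal": 13.91}

#: Share of ovulation records by basis label.
BASIS_SHARES = {"clinical": 0.31, "test_kit": 0.54, "other": 0.15}

#: Reported GLS random-effect coefficients (intercept, slope) for phase
#: length regressed on cycle length.  NOTE: as printed, the follicular
#: pair (0.501, -0.088) implies a near-flat/negative dependence of
#: follicular length on cycle length, which contradicts the strongly
#: increasing per-cycle-length summary rows below; the labels were most
#: likely swapped or rescaled in the source.  The pairs are kept exactly
#: as printed and used as generative truths in recovery simulations,
#: never as a calibration of the synthetic cohort.
GLS_COEFFICIENTS = {
    "follicular": (0.501, -0.088),
    "luteal": (0.466, 0.088),
}

# Per-cycle-length phase summary: cycle length (days), number of
# ovulation-dated cycles, mean follicular length with central 95% range,
# mean luteal length with central 95% range.
_PHASE_SUMMARY_ROWS = [
    # c,    n, mean_f, f_lo, f_hi, mean_l, l_lo, l_hi
    (23, 120, 10.5, 7, 15, 11.5, 7, 15),
    (24, 324, 11.1, 7, 15, 11.9, 8, 16),
    (25, 657, 11.5, 8, 16, 12.5, 8, 16),
    (26, 1065, 12.1, 9, 16, 12.9, 9, 16),
    (27, 1407, 12.7, 10, 16, 13.3, 10, 16),
    (28, 1637, 13.4, 10, 17, 13.6, 10, 17),
    (29, 1516, 14.1, 11, 17, 13.9, 11, 17),
    (30, 1392, 15.0, 11, 19, 14.0, 10, 18),
    (31, 1144, 15.7, 12, 20, 14.3, 10, 18),
    (32, 875, 16.4, 12, 20, 14.6, 11, 19),
    (33, 707, 17.4, 13, 21, 14.6, 11, 19),
    (34, 557, 18.1, 12, 23, 14.9, 10, 21),
    (35, 395, 18.8, 11, 26, 15.2, 8, 23),
    (36, 300, 19.6, 12, 25, 15.4, 10, 23),
    (37, 204, 20.1, 12, 25, 15.9, 11, 24),
    (38, 162, 21.5, 14, 28, 15.5, 9, 23),
    (39, 145, 21.6, 12, 29, 16.4, 9, 26),
    (40, 124, 22.3, 12, 29, 16.7, 10, 27),
]

#: Ovulation-dated cycles having k screened past cycles, k = 1..8 (totals).
RECORD_DEPTH_TOTALS = {
    1: 11_640,
    2: 11_093,
    3: 10_421,
    4: 9_804,
    5: 9_154,
    6: 8_529,
    7: 7_898,
    8: 7_285,
}

#: Reported Pearson correlations between the k=1 trailing mean cycle
#: length and next-cycle quantities (kept for qualitative comparison).
CORRELATION_K1 = {"next_cycle": 0.543, "follicular": 0.506, "luteal": 0.109}


def phase_summary_table() -> pd.DataFrame:
    """Published phase-length summary, one row per integer cycle length."""
    return pd.DataFrame(
        _PHASE_SUMMARY_ROWS,
        columns=[
            "cycle_length",
            "n",
            "mean_f",
            "f_lo",
            "f_hi",
            "mean_l",
            "l_lo",
            "l_hi",
        ],
    )
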