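"""Voltage- and time-dependence of stimulation effects.

Ordinary least squares trends of per-recording effect series against days
since device implant (slopes in units/day, with Pearson r and 95% CIs),
per-voltage-group trends with a CI-overlap report, one-way ANOVA with
Tukey-Kramer post-hoc comparisons across voltage settings, and mean
electrographic-seizure frequency per voltage epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ConfigError, InsufficientDataError

__all__ = [
    "TrendResult",
    "VoltageGroupResult",
    "ols_trend",
    "grouped_trends",
    "anova_tukey",
    "seizure_frequency_by_voltage",
]


@dataclass(frozen=True)
class TrendResult:
    series_name: str
    n: int
    slope_per_day: float
    intercept: float
    p_value: float
    r: float
    slope_ci_95: tuple[float, float]

    @property
    def ci_includes_zero(self) -> bool:
        return self.slope_ci_95[0] <= 0.0 <= self.slope_ci_95[1]


@dataclass(frozen=True)
class VoltageGroupResult:
    groups: dict  # voltage -> (n, mean, sd)
    anova_F: float
    anova_p: float
    tukey_pairs: list  # (v_i, v_j, mean_diff, adjusted_p, significant)
    alpha: float = 0.05


def ols_trend(
    days: np.ndarray, values: np.ndarray, series_name: str = ""
) -> TrendResult:
    """OLS regression of values on days: slope/day, two-sided p, Pearson r,
    and a 95% CI on the slope."""
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.shape != values.shape:
        raise ConfigError("days and values must have equal length")
    n = len(days)
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 for a trend, got {n}")
    if len(np.unique(days)) < 2:
        raise ConfigError("need at least 2 distinct days for a trend")
    fit = stats.linregress(days, values)
    tcrit = stats.t.ppf(0.975, n - 2)
    half = tcrit * fit.stderr
    return TrendResult(
        series_name=series_name,
        n=n,
        slope_per_day=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        r=float(fit.rvalue),
        slope_ci_95=(float(fit.slope - half), float(fit.slope + half)),
    )


def grouped_trends(
    frame: pd.DataFrame,
    value_col: str,
    day_col: str = "days_since_implant",
    voltage_col: str = "dbs_voltage",
    pooled_groups: Sequence[Sequence[float]] = (),
    min_n: int = 3,
) -> tuple[dict, pd.DataFrame]:
    """Per-voltage (and pooled-group) trends plus a CI-overlap table.

    Returns ``(trends, overlap)``: trends maps a group label (single voltage
    like ``"3.0V"`` or a pooled set like ``"2.0+3.0V"``) to its TrendResult;
    the overlap frame reports, for every pair of groups, whether the 95%
    slope CIs overlap and whether each CI includes zero. Groups smaller than
    ``min_n`` are skipped with a warning.
    """
    groups: dict[str, pd.DataFrame] = {}
    for v, sub in frame.groupby(voltage_col):
        groups[f"{float(v):g}V"] = sub
    for pool in pooled_groups:
        sel = frame[frame[voltage_col].isin(list(pool))]
        groups["+".join(f"{float(v):g}" for v in pool) + "V"] = sel

    trends: dict[str, TrendResult] = {}
    for label, sub in groups.items():
        if len(sub) < min_n:
            warnings.warn(
                f"group {label}: n={len(sub)} < {min_n}, skipped", stacklevel=2
            )
            continue
        trends[label] = ols_trend(
            sub[day_col].to_numpy(), sub[value_col].to_numpy(), series_name=label
        )

    rows = []
    labels = list(trends)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            lo_a, hi_a = trends[a].slope_ci_95
            lo_b, hi_b = trends[b].slope_ci_95
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "slope_a": trends[a].slope_per_day,
                    "slope_b": trends[b].slope_per_day,
                    "ci_overlap": (lo_a <= hi_b) and (lo_b <= hi_a),
                    "a_includes_zero": trends[a].ci_includes_zero,
                    "b_includes_zero": trends[b].ci_includes_zero,
                }
            )
    return trends, pd.DataFrame(
        rows,
        columns=[
            "group_a",
            "group_b",
            "slope_a",
            "slope_b",
            "ci_overlap",
            "a_includes_zero",
            "b_includes_zero",
        ],
    )


def anova_tukey(
    values_by_voltage: Mapping[float, Sequence[float]], alpha: float = 0.05
) -> VoltageGroupResult:
    """One-way ANOVA across voltage groups with Tukey-Kramer post-hoc pairs.

    The Tukey-Kramer procedure (studentized-range critical values with the
    unequal-n harmonic correction) is applied at ``alpha``; each pairwise
    row carries the adjusted p-value.
    """
    voltages = sorted(values_by_voltage)
    if len(voltages) < 2:
        raise InsufficientDataError("need at least 2 voltage groups for ANOVA")
    arrays = {v: np.asarray(values_by_voltage[v], dtype=float) for v in voltages}
    for v, arr in arrays.items():
        if len(arr) < 2:
            raise InsufficientDataError(f"voltage group {v} has n < 2")
    f_stat, p = stats.f_oneway(*arrays.values())

    flat = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[v] * len(arrays[v]) for v in voltages])
    tk = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    from itertools import combinations

    pair_order = list(combinations(tk.groupsunique, 2))
    pairs = [
        (float(g1), float(g2), float(md), float(pv), bool(rej))
        for (g1, g2), md, pv, rej in zip(
            pair_order, tk.meandiffs, tk.pvalues, tk.reject
        )
    ]
    return VoltageGroupResult(
        groups={
            float(v): (len(arr), float(arr.mean()), float(arr.std(ddof=1)))
            for v, arr in arrays.items()
        },
        anova_F=float(f_stat),
        anova_p=float(p),
        tukey_pairs=pairs,
        alpha=alpha,
    )


def seizure_frequency_by_voltage(
    daily_counts: pd.DataFrame,
    voltage_epochs: Sequence[tuple[float, float, float]],
    per: str = "day",
) -> pd.DataFrame:
    """Mean electrographic-seizure count per voltage epoch.

    ``daily_counts`` needs columns ``day`` and ``count``; epochs are
    half-open ``(start_day, end_day, voltage)``. ``per`` is ``"day"`` or
    ``"month"`` (30-day months). Epochs with no covered days are flagged.
    """
    if per not in ("day", "month"):
        raise ConfigError("per must be 'day' or 'month'")
    factor = 1.0 if per == "day" else 30.0
    rows = []
    for start, end, voltage in voltage_epochs:
        sel = daily_counts[(daily_counts["day"] >= start) & (daily_counts["day"] < end)]
        n_days = len(sel)
        if n_days == 0:
            warnings.warn(
                f"voltage epoch [{start}, {end}) has no daily counts", stacklevel=2
            )
            mean_rate = float("nan")
        else:
            mean_rate = float(sel["count"].mean()) * factor
        rows.append(
            {
                "start_day": start,
                "end_day": end,
                "voltage_V": voltage,
                "n_days": n_days,
                f"mean_per_{per}": mean_rate,
            }
        )
    return pd.DataFrame(rows)
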