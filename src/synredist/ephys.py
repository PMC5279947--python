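"""Fiber-volley-normalized analysis of evoked synaptic responses.

The pipeline mirrors the analysis conventions of simultaneous field /
whole-cell recordings from dentate granule cells: repeated stimuli at each
intensity are averaged; responses that have saturated axonal recruitment
are dropped; averaged responses are binned by fiber-volley (FV) amplitude,
which normalizes for between-slice differences in stimulation efficacy and
removes stimulus intensity as a variable; per-response EPSC/FV (or
fEPSP-slope/FV) ratios summarize synaptic strength per unit of axonal
recruitment; and group comparisons across FV bins with unequal per-cell
counts use a two-factor unweighted-means ANOVA.

Tabular data are pandas DataFrames with the sweep-table schema
(``slice_id, group, cell_id, stimulus_v, fv_uv, fepsp_slope, epsc_pa,
saturated``); amplitudes are stored as magnitudes (inward currents
positive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SWEEP_COLUMNS",
    "MEASURES",
    "EventTrain",
    "UnweightedMeansResult",
    "average_by_intensity",
    "flag_saturation",
    "exclude_saturated",
    "bin_by_fiber_volley",
    "complete_bins",
    "response_fv_ratio",
    "paired_pulse_ratio",
    "event_summary",
    "percent_change",
    "unweighted_means_test",
]

SWEEP_COLUMNS = (
    "slice_id",
    "group",
    "cell_id",
    "stimulus_v",
    "fv_uv",
    "fepsp_slope",
    "epsc_pa",
    "saturated",
)

#: response measure name -> sweep-table column
MEASURES = {"epsc": "epsc_pa", "fepsp_slope": "fepsp_slope"}

_KEYS = ["slice_id", "group", "cell_id", "stimulus_v"]


def _check_sweeps(sweeps: pd.DataFrame) -> None:
    missing = set(SWEEP_COLUMNS) - set(sweeps.columns)
    if missing:
        raise ValueError(f"sweep table missing column(s): {', '.join(sorted(missing))}")


def _measure_column(measure: str) -> str:
    try:
        return MEASURES[measure]
    except KeyError:
        raise ValueError(
            f"unknown measure {measure!r}; expected one of {sorted(MEASURES)}"
        ) from None


@dataclass(frozen=True)
class EventTrain:
    """Detected synaptic events (spontaneous or desynchronized) in one cell."""

    cell_id: str
    duration: float  # seconds
    times: np.ndarray  # seconds, sorted, in [0, duration)
    amplitudes: np.ndarray  # pA, same length as times

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if self.duration <= 0:
            raise ValueError("duration must be strictly positive")
        if t.shape != a.shape:
            raise ValueError("times and amplitudes must have equal length")
        if t.size and (np.any(np.diff(t) < 0) or t[0] < 0 or t[-1] >= self.duration):
            raise ValueError("event times must be sorted and within [0, duration)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)

    def __len__(self) -> int:
        return int(self.times.size)


def average_by_intensity(sweeps: pd.DataFrame) -> pd.DataFrame:
    """Average repeated sweeps into one response per (cell, intensity).

    FV amplitude, fEPSP slope and EPSC amplitude are arithmetic means over
    the sweeps at each stimulus intensity (the recording protocol delivers
    10 stimuli per intensity); the saturated flag is a majority vote.
    """
    _check_sweeps(sweeps)
    if sweeps.empty:
        raise ValueError("empty sweep table")
    out = (
        sweeps.groupby(_KEYS, sort=True, as_index=False)
        .agg(
            fv_uv=("fv_uv", "mean"),
            fepsp_slope=("fepsp_slope", "mean"),
            epsc_pa=("epsc_pa", "mean"),
            saturated=("saturated", lambda s: bool(s.mean() > 0.5)),
        )
    )
    return out[list(SWEEP_COLUMNS)]


def flag_saturation(
    responses: pd.DataFrame, plateau_tol: float = 0.05
) -> pd.DataFrame:
    """Flag plateaued responses when no explicit saturation flag exists.

    A (cell, intensity) response is marked saturated when its FV is within
    ``plateau_tol`` of the cell's maximum FV and the response at the
    next-lower intensity is also within that margin — i.e. raising the
    stimulus no longer recruits more axons.  This is a reproducible
    stand-in for the operator's on-line judgment.
    """
    _check_sweeps(responses)
    out = responses.copy()
    flags = np.zeros(len(out), dtype=bool)
    pos = {idx: i for i, idx in enumerate(out.index)}
    for _, cell in out.groupby(["slice_id", "cell_id"], sort=False):
        cell = cell.sort_values("stimulus_v")
        fv = cell["fv_uv"].to_numpy(dtype=float)
        top = fv.max()
        if top <= 0:
            continue
        near = fv >= (1.0 - plateau_tol) * top
        for i in range(1, len(fv)):
            if near[i] and near[i - 1]:
                flags[pos[cell.index[i]]] = True
    out["saturated"] = out["saturated"].astype(bool) | flags
    return out


def exclude_saturated(responses: pd.DataFrame) -> pd.DataFrame:
    """Drop saturated responses, preserving row order.

    Saturated responses carry no extra information about synaptic gain and
    would flatten the input-output relation at high intensities.
    """
    _check_sweeps(responses)
    kept = responses.loc[~responses["saturated"].astype(bool)]
    if kept.empty and not responses.empty:
        warnings.warn("all responses are saturated; returning an empty table")
    return kept


def bin_by_fiber_volley(
    responses: pd.DataFrame, bin_width: float = 100.0, measure: str = "epsc"
) -> pd.DataFrame:
    """Per-group mean +/- SEM of a response measure in uniform FV bins.

    Bins are half-open ``[k*w, (k+1)*w)`` anchored at 0 uV; empty bins are
    omitted.  SEM uses the n-1 variance and is NaN for singleton bins.
    Returns columns ``group, bin_low, bin_high, mean_response, sem, n``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be strictly positive")
    _check_sweeps(responses)
    if responses.empty:
        raise ValueError("no responses to bin (all saturated?)")
    col = _measure_column(measure)
    df = responses.copy()
    df["_bin"] = np.floor(df["fv_uv"].to_numpy(dtype=float) / bin_width).astype(int)
    summary = (
        df.groupby(["group", "_bin"], sort=True)[col]
        .agg(mean_response="mean", sem=lambda s: s.sem(ddof=1), n="size")
        .reset_index()
    )
    summary["bin_low"] = summary["_bin"] * bin_width
    summary["bin_high"] = (summary["_bin"] + 1) * bin_width
    summary["n"] = summary["n"].astype(int)
    return summary[["group", "bin_low", "bin_high", "mean_response", "sem", "n"]]


def complete_bins(binned: pd.DataFrame, min_n: int = 2) -> pd.DataFrame:
    """Restrict a binned summary to bins present in every group with n >= min_n.

    The unweighted-means ANOVA needs a complete factorial crossing; bins
    sampled in only one group (typical at the extremes of the FV range)
    are excluded before testing.
    """
    groups = binned["group"].unique()
    ok = binned[binned["n"] >= min_n]
    counts = ok.groupby("bin_low")["group"].nunique()
    keep = counts[counts == len(groups)].index
    return ok[ok["bin_low"].isin(keep)].reset_index(drop=True)


def response_fv_ratio(
    responses: pd.DataFrame, measure: str = "epsc"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-response measure/FV ratios and their per-group mean +/- SEM.

    For the EPSC this is the overall EPSC/FV ratio in pA/uV: synaptic
    current per microvolt of fiber volley, i.e. per unit of axonal
    recruitment.  The group mean averages the per-response ratios (each
    averaged response is one observation, matching the per-response n of
    the summary statistic).  Rows with zero FV are excluded with a warning.
    """
    _check_sweeps(responses)
    col = _measure_column(measure)
    fv = responses["fv_uv"].to_numpy(dtype=float)
    zero = fv <= 0
    if np.any(zero):
        warnings.warn(f"excluding {int(zero.sum())} response(s) with zero fiber volley")
    per = responses.loc[~zero].copy()
    per["ratio"] = per[col].to_numpy(dtype=float) / per["fv_uv"].to_numpy(dtype=float)
    summary = (
        per.groupby("group", sort=True)["ratio"]
        .agg(mean_ratio="mean", sem=lambda s: s.sem(ddof=1), n="size")
        .reset_index()
    )
    summary["n"] = summary["n"].astype(int)
    return per, summary


def paired_pulse_ratio(amp1, amp2):
    """Paired-pulse ratio: second response amplitude over the first.

    A proxy for presynaptic release probability; values below 1 indicate
    paired-pulse depression.  Accepts scalars or arrays; the first
    amplitude must be strictly positive.
    """
    a1 = np.asarray(amp1, dtype=float)
    a2 = np.asarray(amp2, dtype=float)
    if np.any(a1 <= 0):
        raise ValueError("first-pulse amplitude must be strictly positive")
    out = a2 / a1
    return out if out.ndim else float(out)


def event_summary(train: EventTrain) -> tuple[float, float]:
    """Event frequency (Hz) and mean amplitude (pA) of one event train.

    An empty train has frequency 0 and an undefined (NaN) amplitude.
    """
    freq = len(train) / train.duration
    amp = float(np.mean(train.amplitudes)) if len(train) else float("nan")
    return freq, amp


def percent_change(reference_mean: float, test_mean: float) -> int:
    """Percent change of a test mean relative to a reference mean.

    Rounded to the nearest integer, the reporting convention for
    stereological cell counts (e.g. a 16,881 -> 23,756 increase in newborn
    cells is reported as +41%).
    """
    if reference_mean <= 0:
        raise ValueError("reference_mean must be strictly positive")
    return int(round(100.0 * (test_mean - reference_mean) / reference_mean))


@dataclass(frozen=True)
class UnweightedMeansResult:
    """Two-factor unweighted-means ANOVA outcome (group and bin effects)."""

    F_group: float
    p_group: float
    F_bin: float
    p_bin: float
    df_group: int
    df_bin: int
    df_error: int
    n_harmonic: float


def unweighted_means_test(binned: pd.DataFrame) -> UnweightedMeansResult:
    """Two-factor unweighted-means ANOVA on a group x FV-bin summary.

    When responses are binned by FV amplitude the number of observations
    differs between cells of the design, so main effects are computed on
    the unweighted cell means with the harmonic mean of the cell sizes,
    n_h = (a*b) / sum(1/n_ij), replacing n in the sums of squares:

        SS_group = n_h * b * sum_i (rowmean_i - grand)^2
        SS_bin   = n_h * a * sum_j (colmean_j - grand)^2

    where the grand mean and marginal means are unweighted means of the
    cell means.  The error term pools the within-cell variance,
    SS_err = sum_ij (n_ij - 1) * s_ij^2 with df = sum_ij (n_ij - 1), which
    the binned summary carries through its SEMs (s^2 = sem^2 * n).  In a
    balanced design this reduces exactly to the standard two-way ANOVA.

    Requires >= 2 groups, >= 2 bins, a complete crossing, and n >= 2 in
    every cell (see :func:`complete_bins` for pre-filtering).
    """
    required = {"group", "bin_low", "mean_response", "sem", "n"}
    missing = required - set(binned.columns)
    if missing:
        raise ValueError(f"binned summary missing column(s): {', '.join(sorted(missing))}")
    if (binned["n"] < 2).any():
        bad = binned.loc[binned["n"] < 2, ["group", "bin_low"]].iloc[0]
        raise ValueError(
            f"cell (group={bad['group']!r}, bin_low={bad['bin_low']}) has n < 2"
        )
    cells = binned.pivot(index="group", columns="bin_low", values="mean_response")
    ns = binned.pivot(index="group", columns="bin_low", values="n")
    sems = binned.pivot(index="group", columns="bin_low", values="sem")
    if cells.isna().any().any():
        raise ValueError("incomplete factorial design: some (group, bin) cells are missing")
    a, b = cells.shape
    if a < 2 or b < 2:
        raise ValueError(f"need >= 2 levels per factor, got {a} group(s) x {b} bin(s)")

    m = cells.to_numpy(dtype=float)
    n = ns.to_numpy(dtype=float)
    s2 = sems.to_numpy(dtype=float) ** 2 * n  # per-cell sample variance (ddof=1)

    n_h = (a * b) / np.sum(1.0 / n)
    grand = m.mean()
    ss_group = n_h * b * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_bin = n_h * a * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_err = np.sum((n - 1.0) * s2)
    df_group, df_bin = a - 1, b - 1
    df_err = int(np.sum(n - 1.0))
    ms_err = ss_err / df_err
    if ms_err == 0.0:
        # degenerate noiseless input: any effect is infinitely significant
        F_g = np.inf if ss_group > 0 else 0.0
        F_b = np.inf if ss_bin > 0 else 0.0
    else:
        F_g = (ss_group / df_group) / ms_err
        F_b = (ss_bin / df_bin) / ms_err
    return UnweightedMeansResult(
        F_group=float(F_g),
        p_group=float(stats.f.sf(F_g, df_group, df_err)),
        F_bin=float(F_b),
        p_bin=float(stats.f.sf(F_b, df_bin, df_err)),
        df_group=df_group,
        df_bin=df_bin,
        df_error=df_err,
        n_harmonic=float(n_h),
    )
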