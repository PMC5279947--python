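"""Deterministic day-stepped model of synapse redistribution.

A fixed pool of perforant-path synapses is shared between the resident
mature granule-cell population and successive daily cohorts of adult-born
immature granule cells.  The total pool

    S_total = S_M + S_I(0)

is set once from the initial census and held static: every synapse an
immature cohort acquires is a synapse the mature population no longer
holds.  Each day t (integers, t=0 is the manipulation day) a cohort of

    I(t) = P(t) * survival_rate

new cells incorporates, where P(t) is the declining progenitor
proliferation curve.  A cohort incorporated on day k has, on day t, the
per-cell synaptic strength Y(t-k+1), the logarithmic integration curve in
percent of the mature complement.  The immature synapse load is the
convolution

    S_I(t) = sum_{k<=t} I(k) * m_k * Y(t-k+1) / 100 * synapses_per_cell,

with m_k a per-cohort strength multiplier (1.35 for Bax-deleted cohorts,
whose synapses escape pruning; 1 otherwise).  The immature share of the
pool is %im = S_I(t) / S_total * 100 and %mat = 100 - %im.

The model is an expected-value (deterministic) computation: cohort sizes
are real-valued, there is no sampling anywhere, and immature cohorts never
convert to mature status within the simulated window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import BAX_KO, CONDITIONS, CONTROL, ModelParams

__all__ = [
    "CohortLedger",
    "Trajectory",
    "synaptic_strength",
    "proliferation",
    "initial_pools",
    "incorporation_schedule",
    "immature_synapse_load",
    "run_simulation",
    "predicted_mature_ratio",
]


@dataclass(frozen=True)
class CohortLedger:
    """Per-day record of incorporated immature-cell cohorts.

    ``incorporation_day`` is strictly increasing; ``cells`` are
    expected-value (fractional) cohort sizes; ``strength_multiplier`` is
    1.0 for control-era cohorts and the Bax-deletion factor for cohorts
    incorporating after the deletion takes effect.
    """

    incorporation_day: np.ndarray  # int days, strictly increasing
    cells: np.ndarray              # cells >= 0
    strength_multiplier: np.ndarray  # >= 1
    condition: str

    def __post_init__(self) -> None:
        day = np.asarray(self.incorporation_day)
        if day.size and np.any(np.diff(day) <= 0):
            raise ValueError("incorporation_day must be strictly increasing")
        if np.any(np.asarray(self.cells) < 0):
            raise ValueError("cohort cells must be non-negative")
        if np.any(np.asarray(self.strength_multiplier) < 1):
            raise ValueError("strength_multiplier must be >= 1")

    def __len__(self) -> int:
        return int(np.asarray(self.incorporation_day).size)


@dataclass(frozen=True)
class Trajectory:
    """Day-indexed immature/mature synapse shares for one condition."""

    day: np.ndarray
    immature_synapses: np.ndarray
    pct_immature: np.ndarray
    pct_mature: np.ndarray
    condition: str
    total_synapses: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.day,
                "condition": self.condition,
                "immature_synapses": self.immature_synapses,
                "pct_immature": self.pct_immature,
                "pct_mature": self.pct_mature,
            }
        )


def synaptic_strength(
    days_since_incorporation, params: ModelParams = ModelParams()
):
    """Integration curve Y(d): per-cell synaptic strength in percent.

    Y(d) = slope * ln(age_offset + d) - intercept, clamped to [0, 100].
    At the defaults a cell one day after integration onset holds ~5% of the
    mature synapse complement, ~65% at d=21 and ~100% at d=43.

    Accepts a scalar or array of non-negative integer days.
    """
    d = np.asarray(days_since_incorporation, dtype=float)
    if np.any(d < 0):
        raise ValueError("days_since_incorporation must be >= 0")
    raw = (
        params.strength_slope * np.log(params.strength_age_offset + d)
        - params.strength_intercept
    )
    out = np.clip(raw, 0.0, 100.0)
    return out if out.ndim else float(out)


def proliferation(t, params: ModelParams = ModelParams()):
    """Progenitor proliferation P(t) = scale * (age_offset + t)**exponent.

    Cells available per day; strictly decreasing in t for the default
    negative exponent.  Accepts a scalar or array of non-negative days.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be >= 0")
    out = params.prolif_scale * (params.prolif_age_offset + tt) ** params.prolif_exponent
    return out if out.ndim else float(out)


def initial_pools(params: ModelParams = ModelParams()) -> tuple[float, float, float]:
    """Initial mature, baseline-immature and total synapse counts.

    The mature pool is synapses_per_cell * mature cell count.  The
    pre-existing immature pool spreads the immature census uniformly over
    the maturation span, one cohort per strength value:

        S_I(0) = N_im / span * sum_{d=1..span} Y(d) / 100 * synapses_per_cell

    The returned total (S_M + S_I(0), ~19.6 million at the defaults) is the
    static pool conserved for the whole simulation.
    """
    mature_cells = params.total_cells * params.mature_fraction
    immature_cells = params.total_cells * (1.0 - params.mature_fraction)
    mature_synapses = params.synapses_per_mature_cell * mature_cells

    ages = np.arange(1, params.maturation_span + 1)
    strength_sum = float(np.sum(synaptic_strength(ages, params)))
    baseline_immature = (
        immature_cells
        / params.maturation_span
        * strength_sum
        / 100.0
        * params.synapses_per_mature_cell
    )
    return mature_synapses, baseline_immature, mature_synapses + baseline_immature


def _survival(day: np.ndarray, params: ModelParams, condition: str) -> np.ndarray:
    if condition == CONTROL:
        return np.full(day.shape, params.survival_wt)
    if condition == BAX_KO:
        return np.where(day >= params.ko_onset_day, params.survival_ko, params.survival_wt)
    raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


def incorporation_schedule(
    params: ModelParams = ModelParams(), condition: str = CONTROL
) -> CohortLedger:
    """Daily cohorts incorporating over t=1..horizon.

    Cohort size is proliferation times the survival rate in effect on the
    incorporation day.  In the Bax-deleted condition, cohorts incorporating
    on or after ko_onset_day survive at the knockout rate and carry the
    knockout strength multiplier (un-pruned synapses); earlier cohorts are
    indistinguishable from control.
    """
    days = np.arange(1, params.horizon + 1)
    cells = proliferation(days, params) * _survival(days, params, condition)
    mult = np.ones_like(cells)
    if condition == BAX_KO:
        mult[days >= params.ko_onset_day] = params.ko_strength_factor
    return CohortLedger(days, cells, mult, condition)


def immature_synapse_load(
    t: int, ledger: CohortLedger, params: ModelParams = ModelParams()
) -> float:
    """Synapses held by post-manipulation immature cohorts on day t.

    S_I(t) = sum over cohorts incorporated on day k <= t of
    cells_k * m_k * Y(t-k+1)/100 * synapses_per_cell.  Zero at t=0 (no
    cohort has incorporated) and non-decreasing in t, because Y is
    non-decreasing and cohorts never lose cells or synapses.
    """
    if t > params.horizon:
        raise ValueError(f"t={t} beyond horizon {params.horizon}")
    k = np.asarray(ledger.incorporation_day)
    active = k <= t
    if not np.any(active):
        return 0.0
    ages = t - k[active] + 1
    strengths = synaptic_strength(ages, params)
    cells = np.asarray(ledger.cells)[active]
    mult = np.asarray(ledger.strength_multiplier)[active]
    return float(
        np.sum(cells * mult * strengths / 100.0 * params.synapses_per_mature_cell)
    )


def run_simulation(
    params: ModelParams = ModelParams(), condition: str = CONTROL
) -> Trajectory:
    """Simulate the immature/mature synapse shares over t=0..horizon.

    The denominator of the percentage is fixed at the initial total pool;
    the numerator is the newly appropriated load S_I(t), plus the baseline
    immature pool when include_baseline_in_numerator is set.  %im and %mat
    sum to 100 by construction (conservation of the static pool).
    """
    ledger = incorporation_schedule(params, condition)
    _, baseline, total = initial_pools(params)
    days = np.arange(0, params.horizon + 1)
    load = np.array([immature_synapse_load(t, ledger, params) for t in days])
    numerator = load + (baseline if params.include_baseline_in_numerator else 0.0)
    pct_im = numerator / total * 100.0
    return Trajectory(
        day=days,
        immature_synapses=numerator,
        pct_immature=pct_im,
        pct_mature=100.0 - pct_im,
        condition=condition,
        total_synapses=total,
    )


def predicted_mature_ratio(
    ko: Trajectory,
    ctrl: Trajectory,
    window: tuple[int, int] = (36, 43),
) -> pd.DataFrame:
    """Knockout-to-control ratio of the mature synapse share, in percent.

    100 * %mat_ko(t) / %mat_ctrl(t) for each day in the inclusive window
    (default the final week, t=36..43).  Values are <= 100 whenever the
    knockout appropriates at least as many synapses as control.
    """
    if ko.day.shape != ctrl.day.shape or np.any(ko.day != ctrl.day):
        raise ValueError("trajectories have mismatched day grids")
    lo, hi = window
    if lo > hi:
        raise ValueError(f"empty window {window}")
    if lo < ko.day[0] or hi > ko.day[-1]:
        raise ValueError(f"window {window} outside simulated horizon")
    sel = (ko.day >= lo) & (ko.day <= hi)
    ratio = 100.0 * ko.pct_mature[sel] / ctrl.pct_mature[sel]
    return pd.DataFrame({"day": ko.day[sel], "ratio_pct": ratio})
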