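"""Poisson experiment-planning and activity bookkeeping.

Closed-form arithmetic used to design and sanity-check a low-activity
tracking scan: expected coincidence rates from per-cell activity and
scanner sensitivity, zero-event probabilities that set the frame step,
radioactive-decay timelines, per-cell activity from bulk measurements,
dilution counting statistics, and background-corrected count-rate
assessment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "F18_HALF_LIFE_S",
    "LabelingMeasurement",
    "RatePlan",
    "expected_cl_rate",
    "prob_zero_events",
    "choose_time_step",
    "make_rate_plan",
    "per_cell_activity",
    "decay_activity",
    "decay_time",
    "cells_from_activity",
    "dilution_count",
    "count_rate_assessment",
    "signal_to_noise",
    "experiment_design_report",
]

# Printed isotope constant (109.8 min); configurable everywhere it is used.
F18_HALF_LIFE_S = 109.8 * 60.0


@dataclass(frozen=True)
class LabelingMeasurement:
    """Bulk activity of a labeled cell sample plus its cell count."""

    total_activity_bq: float
    n_cells: float
    n_cells_sigma: float = 0.0
    total_activity_sigma_bq: float = 0.0

    def __post_init__(self):
        if self.total_activity_bq < 0 or self.n_cells < 0:
            raise ValueError("activity and cell count must be >= 0")


@dataclass(frozen=True)
class RatePlan:
    """Window-design summary for one per-cell detection rate."""

    per_cell_rate_per_s: float
    step_s: int
    window_s: float
    p_zero_at_step: float
    events_per_window: float


def expected_cl_rate(activity_bq: float, sensitivity: float) -> float:
    """Expected coincidence-detection rate: activity times sensitivity."""
    if activity_bq < 0:
        raise ValueError("activity must be >= 0")
    if not (0 < sensitivity <= 1):
        raise ValueError("sensitivity must be in (0, 1]")
    return activity_bq * sensitivity


def prob_zero_events(rate_per_s: float, dt_s: float) -> float:
    """P(no events in dt) for a Poisson process: exp(-rate*dt)."""
    if rate_per_s < 0 or dt_s < 0:
        raise ValueError("rate and dt must be >= 0")
    return math.exp(-rate_per_s * dt_s)


def choose_time_step(rate_per_s: float, p_threshold: float = 0.01) -> int:
    """Smallest integer step (s) at which the zero-event probability drops
    below ``p_threshold``."""
    if rate_per_s <= 0:
        raise ValueError("rate must be positive to choose a step")
    if not (0 < p_threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    dt = 1
    while prob_zero_events(rate_per_s, dt) >= p_threshold:
        dt += 1
    return dt


def make_rate_plan(
    activity_bq: float,
    sensitivity: float,
    p_threshold: float = 0.01,
    window_s: float = 60.0,
) -> RatePlan:
    """Assemble the window-design numbers for one cell."""
    rate = expected_cl_rate(activity_bq, sensitivity)
    step = choose_time_step(rate, p_threshold)
    return RatePlan(
        per_cell_rate_per_s=rate,
        step_s=step,
        window_s=window_s,
        p_zero_at_step=prob_zero_events(rate, step),
        events_per_window=rate * window_s,
    )


def per_cell_activity(m: LabelingMeasurement) -> tuple[float, float]:
    """Average activity per cell with first-order error propagation."""
    if m.n_cells <= 0:
        raise ValueError("cell count must be positive")
    a = m.total_activity_bq / m.n_cells
    rel2 = (m.n_cells_sigma / m.n_cells) ** 2
    if m.total_activity_bq > 0:
        rel2 += (m.total_activity_sigma_bq / m.total_activity_bq) ** 2
    return a, a * math.sqrt(rel2)


def decay_activity(a0_bq: float, t_s: float, half_life_s: float = F18_HALF_LIFE_S) -> float:
    """Activity after time t: a0 * 2^(-t / half_life)."""
    if a0_bq < 0 or half_life_s <= 0:
        raise ValueError("need a0 >= 0 and half_life > 0")
    return a0_bq * 2.0 ** (-t_s / half_life_s)


def decay_time(a0_bq: float, a1_bq: float, half_life_s: float = F18_HALF_LIFE_S) -> float:
    """Time for activity to fall from a0 to a1: half_life * log2(a0/a1).

    A target activity above the start returns a negative time (future
    extrapolation) with a warning.
    """
    if a0_bq <= 0 or a1_bq <= 0 or half_life_s <= 0:
        raise ValueError("activities and half-life must be positive")
    if a1_bq > a0_bq:
        warnings.warn("target activity exceeds start; returning negative time")
    return half_life_s * math.log2(a0_bq / a1_bq)


def cells_from_activity(total_bq: float, per_cell_bq: float) -> float:
    """Cell count inferred from bulk and per-cell activity (unrounded)."""
    if per_cell_bq <= 0:
        raise ValueError("per-cell activity must be positive")
    if total_bq < 0:
        raise ValueError("total activity must be >= 0")
    return total_bq / per_cell_bq


def dilution_count(conc_per_ul: float, volume_ul: float) -> tuple[float, float]:
    """Expected cells pipetted and the Poisson counting sigma sqrt(N)."""
    if conc_per_ul < 0 or volume_ul < 0:
        raise ValueError("concentration and volume must be >= 0")
    expected = conc_per_ul * volume_ul
    return expected, math.sqrt(expected)


def count_rate_assessment(
    total_rate_per_min: float, background_rate_per_min: float, n_cells: int
) -> float:
    """Background-corrected per-cell count rate (events/cell/min)."""
    if n_cells <= 0:
        raise ValueError("cell count must be positive")
    corrected = total_rate_per_min - background_rate_per_min
    if corrected < 0:
        raise ValueError("corrected rate is negative: background exceeds total")
    return corrected / n_cells


def signal_to_noise(peak_signal_density: float, peak_background_density: float) -> float:
    """Ratio of peak smoothed signal density to peak background density."""
    if peak_background_density <= 0:
        raise ValueError("background density must be positive")
    return peak_signal_density / peak_background_density


def experiment_design_report(
    activity_bq: float = 32.0,
    sensitivity: float = 0.052,
    p_threshold: float = 0.01,
    window_s: float = 60.0,
    background_rate_per_min: float = 170.0,
) -> str:
    """Plain-text window-design rationale for given activity/sensitivity."""
    plan = make_rate_plan(activity_bq, sensitivity, p_threshold, window_s)
    lines = [
        "PEPT experiment design",
        "----------------------",
        f"per-cell activity:        {activity_bq:g} Bq",
        f"scanner sensitivity:      {100 * sensitivity:g} %",
        f"expected CL rate:         {plan.per_cell_rate_per_s:.3f} events/s/cell"
        f" ({60 * plan.per_cell_rate_per_s:.0f} per min)",
        f"chosen time step:         {plan.step_s} s "
        f"(P(0 events) = {100 * plan.p_zero_at_step:.2f} % < {100 * p_threshold:g} %)",
        f"window length:            {plan.window_s:g} s "
        f"-> {plan.events_per_window:.0f} events expected per cell per window",
        f"background rate:          {background_rate_per_min:g} counts/min",
    ]
    return "\n".join(lines)
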