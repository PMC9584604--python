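"""Very slow rate constants from 1 Hz movies: sneak-through and washout.

Under saturating inhibitor (plus cycloheximide), molecules stalled in
the mid-FRET GA-like state convert to the high-FRET accommodated state
on the minutes-to-hours timescale, either by drug-bound "sneak-through"
or, after drug washout, at the drug dissociation rate.  Both scenarios
reduce to the same estimation problem: an irreversible exponential
conversion observed with right censoring (photobleaching or movie end).
The censored maximum-likelihood rate is

    k = (number of conversion events) / (summed observed time),

where each trace contributes its time up to conversion or censoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExponentialFit",
    "first_accommodation_times",
    "fit_exponential_accumulation",
    "rate_fold_change",
]


@dataclass
class ExponentialFit:
    """Censored-MLE exponential rate with trace-bootstrap SE."""

    rate: float
    amplitude: float
    se_rate: float
    n_events: int
    n_total: int
    window_s: float
    rate_upper_bound: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "rate_per_s": float(self.rate),
            "se_rate_per_s": float(self.se_rate),
            "amplitude": float(self.amplitude),
            "n_events": int(self.n_events),
            "n_total": int(self.n_total),
            "window_s": float(self.window_s),
        }


def first_accommodation_times(
    ideals,
    min_dwell: float | None = None,
    high_state: int | None = None,
) -> pd.DataFrame:
    """Per-trace time of first qualifying high-FRET dwell, or censoring.

    ``min_dwell`` defaults to one frame: at 1 s resolution the 300 ms
    accommodation criterion is sub-frame, so a single high-FRET frame
    qualifies.  Traces without a qualifying dwell are right-censored at
    their end (photobleach or movie end).

    Returns a DataFrame with columns ``trace_id, time_s, event``.
    """
    rows = []
    for ideal in ideals:
        dt = ideal.frame_period
        thresh = dt if min_dwell is None else min_dwell
        hs = high_state
        if hs is None:
            hs = int(np.argmax(ideal.model.emission_means))
        t_event = None
        for st, s, e in ideal.dwell_segments():
            if st == hs and (e - s) * dt >= thresh - 1e-9:
                t_event = s * dt
                break
        if t_event is not None:
            rows.append({"trace_id": ideal.trace_id, "time_s": t_event, "event": True})
        else:
            rows.append(
                {"trace_id": ideal.trace_id, "time_s": ideal.n_frames * dt, "event": False}
            )
    if not rows:
        raise ValueError("no traces given")
    return pd.DataFrame(rows, columns=["trace_id", "time_s", "event"])


def fit_exponential_accumulation(
    times,
    events,
    n_boot: int = 1000,
    seed=None,
) -> ExponentialFit:
    """Censored maximum-likelihood exponential rate.

    ``times`` are per-trace observed times (conversion time for event
    traces, censoring time otherwise); ``events`` the matching booleans.
    With zero events the rate is undefined and only
    ``rate_upper_bound = 1 / (total observed time)`` is reported (the
    rate at which one event would have been expected).
    """
    t = np.asarray(times, dtype=float)
    ev = np.asarray(events, dtype=bool)
    if t.shape != ev.shape or t.ndim != 1:
        raise ValueError("times and events must be matched 1-D arrays")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    total = float(t.sum())
    if total <= 0:
        raise ValueError("zero total observation time")
    n_events = int(ev.sum())
    window = float(t.max())
    if n_events == 0:
        return ExponentialFit(
            rate=float("nan"), amplitude=0.0, se_rate=float("nan"),
            n_events=0, n_total=len(t), window_s=window,
            rate_upper_bound=1.0 / total,
        )
    rate = n_events / total
    se = float("nan")
    if n_boot > 0 and len(t) >= 2:
        rng = np.random.default_rng(seed)
        vals = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, len(t), len(t))
            tot_b = t[idx].sum()
            vals[b] = ev[idx].sum() / tot_b if tot_b > 0 else np.nan
        se = float(np.nanstd(vals))
    return ExponentialFit(
        rate=float(rate), amplitude=n_events / len(t), se_rate=se,
        n_events=n_events, n_total=len(t), window_s=window,
    )


def rate_fold_change(fit_a: ExponentialFit, fit_b: ExponentialFit):
    """Ratio of two fitted rates (a / b) with delta-method SE."""
    if not (fit_a.rate > 0) or not (fit_b.rate > 0):
        raise ZeroDivisionError("both rates must be positive and defined")
    ratio = fit_a.rate / fit_b.rate
    rel = 0.0
    for fit in (fit_a, fit_b):
        if np.isfinite(fit.se_rate):
            rel += (fit.se_rate / fit.rate) ** 2
    return ratio, ratio * float(np.sqrt(rel))
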