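"""Parameter-recovery experiments at the published experimental scale.

Each function regenerates synthetic data at the published conditions
(2000 selection traces at 15 ms frames; 8-dose titrations with 500
traces per dose; 1000 one-hertz movies of 3000 s) and runs the full
analysis pipeline on it, returning the recovered quantity.  These are
the end-to-end checks that the estimator chain — simulation, SKM
idealization, truncation, count/occupancy rates, Hill and censored
exponential fits — reproduces its own generating parameters.

Known limitation, quantified in docs/methods.md: mid-to-high transition
rates are recovered with a systematic deficit of roughly 20-40% because
high-FRET excursions average only 3-4 frames at 15 ms resolution and a
fifth of them are shorter than one camera frame, hence invisible to any
frame-level idealization.  The truth-path estimates returned alongside
isolate this idealization loss from estimator bias.
"""

from __future__ import annotations

import numpy as np

from .dose import accommodated_fraction, fit_hill_bootstrap
from .idealize import default_model
from .kinetics import (
    dwell_table,
    estimate_rate_matrix,
    truncate_before_first_long_high,
    truth_dwell_table,
)
from .pipeline import idealize_traces
from .slow import first_accommodation_times, fit_exponential_accumulation
from .synthetic import PhotophysicsModel, build_scheme, simulate_dose_series, simulate_slow_process, simulate_traces

__all__ = ["table1_recovery", "ic50_recovery", "slow_rate_recovery", "slow_analysis_model"]

DOSE_CONCENTRATIONS = tuple(np.geomspace(0.1, 1000.0, 8))


def slow_analysis_model():
    """Two-state (GA, AC) HMM for 1 Hz movies (sigma 0.01, see synthetic)."""
    return default_model(means=(0.45, 0.7), sigma=0.01, state_labels=("GA", "AC"))


def table1_recovery(
    condition: str,
    n_traces: int = 2000,
    t_max: float = 10.0,
    seed: int = 1,
    n_boot: int = 1000,
):
    """Full-pipeline and truth-path rate recovery for one preset.

    Simulates ``n_traces`` selection traces (dark arrival, 15 ms frames,
    sigma 0.06), idealizes them with SKM (fixed means 0/0.2/0.45/0.7),
    truncates before the first >= 150 ms high-FRET dwell and estimates
    the apparent rate matrix.  Also estimates rates from the exact
    generating paths (censored at the rendered trace length, no
    truncation), for which the count/occupancy estimator is the unbiased
    continuous-time Markov MLE.

    Returns ``(pipeline_estimate, oracle_estimate)``.
    """
    scheme = build_scheme(condition, include_dark_arrival=True)
    model = PhotophysicsModel()
    traces = simulate_traces(
        scheme, model, n_traces, t_max, seed=seed, condition=condition
    )
    traces = [t for t in traces if t.n_frames > 0]
    hmm = default_model()
    ideals = idealize_traces(traces, model=hmm)
    truncated = [
        t
        for t in (truncate_before_first_long_high(i) for i in ideals)
        if t.n_frames > 0
    ]
    est = estimate_rate_matrix(
        dwell_table(truncated), hmm.state_labels,
        n_boot=n_boot, seed=np.random.SeedSequence([seed, 91]),
    )
    paths = [t.truth_path for t in traces]
    t_obs = [t.n_frames * t.frame_period for t in traces]
    oracle = estimate_rate_matrix(
        truth_dwell_table(paths, t_obs), hmm.state_labels,
        n_boot=n_boot, seed=np.random.SeedSequence([seed, 92]),
    )
    return est, oracle


def ic50_recovery(
    ic50_true: float,
    hill: float = 1.0,
    n_traces: int = 500,
    concentrations=DOSE_CONCENTRATIONS,
    bound_condition: str = "didemnin",
    t_max: float = 10.0,
    seed: int = 11,
    n_boot: int = 1000,
):
    """Simulate a titration at a known IC50 and refit it.

    Drug-free molecules follow the control scheme, drug-bound ones the
    stalled scheme; both with the high-FRET state absorbing (true
    accommodation retains high FRET).  Accommodated fractions (>= 300 ms
    high FRET) per dose are Hill-fitted with a trace-bootstrap SE.
    """
    free = build_scheme("control", include_dark_arrival=True, absorb_high=True)
    bound = build_scheme(bound_condition, include_dark_arrival=True, absorb_high=True)
    series = simulate_dose_series(
        free, bound, ic50=ic50_true, hill=hill,
        concentrations=concentrations, n_traces=n_traces,
        model=PhotophysicsModel(), t_max=t_max, seed=seed,
    )
    hmm = default_model()
    flags = []
    for c in concentrations:
        ideals = idealize_traces(series[c], model=hmm)
        flags.append(accommodated_fraction(ideals, n_boot=0).flags)
    return fit_hill_bootstrap(
        np.asarray(concentrations, dtype=float), flags,
        n_boot=n_boot, seed=np.random.SeedSequence([seed, 93]),
    )


def slow_rate_recovery(
    k_true: float,
    n_traces: int = 1000,
    t_max: float = 3000.0,
    seed: int = 21,
    n_boot: int = 1000,
):
    """Simulate a 1 Hz sneak-through/washout movie set and refit the rate."""
    traces = simulate_slow_process(k_true, n_traces, t_max, seed=seed)
    ideals = idealize_traces(traces, model=slow_analysis_model())
    ev = first_accommodation_times(ideals)
    return fit_exponential_accumulation(
        ev["time_s"].to_numpy(), ev["event"].to_numpy(),
        n_boot=n_boot, seed=np.random.SeedSequence([seed, 94]),
    )
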