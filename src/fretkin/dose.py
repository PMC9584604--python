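"""Accommodated fraction and Hill dose-response fitting.

A molecule counts as accommodated when its trace contains at least one
high-FRET dwell lasting 300 ms or more.  Plotting that fraction against
inhibitor concentration and fitting the Hill equation

    f(c) = floor + (ceiling - floor) / (1 + (c / IC50)^h)

yields the half-maximal inhibitory concentration.  Floor and ceiling are
fitted, not pinned, since escape from inhibition is below 100% even
without drug (bleaching and non-productive events) and above 0% at
saturation (sneak-through).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinetics import bootstrap_statistic

__all__ = [
    "AccommodatedFraction",
    "DoseResponseFit",
    "accommodated_fraction",
    "hill_curve",
    "fit_hill",
    "fit_hill_bootstrap",
]


@dataclass
class AccommodatedFraction:
    fraction: float
    se: float
    flags: np.ndarray  # per-trace accommodated booleans
    n_traces: int


@dataclass
class DoseResponseFit:
    ic50: float
    hill_slope: float
    floor: float
    ceiling: float
    se_ic50: float = float("nan")
    concentrations: np.ndarray | None = None
    fractions: np.ndarray | None = None
    n_traces: object = None
    converged: bool = True
    sse: float = float("nan")

    def predict(self, c):
        return hill_curve(np.asarray(c, dtype=float), self.ic50,
                          self.hill_slope, self.floor, self.ceiling)

    def to_dict(self) -> dict:
        d = {
            "ic50_nM": float(self.ic50),
            "hill_slope": float(self.hill_slope),
            "floor": float(self.floor),
            "ceiling": float(self.ceiling),
            "se_ic50_nM": float(self.se_ic50),
            "converged": bool(self.converged),
            "sse": float(self.sse),
        }
        if self.concentrations is not None:
            d["concentrations_nM"] = np.asarray(self.concentrations).tolist()
            d["fractions"] = np.asarray(self.fractions).tolist()
        return d


def accommodated_fraction(
    ideals,
    min_dwell: float = 0.300,
    high_state: int | None = None,
    n_boot: int = 1000,
    seed=None,
) -> AccommodatedFraction:
    """Fraction of traces with >= 1 high-FRET dwell of >= ``min_dwell`` s.

    The threshold is inclusive (20 frames at 15 ms).  SE by trace-level
    bootstrap.
    """
    ideals = list(ideals)
    if not ideals:
        raise ValueError("no traces given")
    flags = np.zeros(len(ideals), dtype=bool)
    for i, ideal in enumerate(ideals):
        hs = high_state
        if hs is None:
            hs = int(np.argmax(ideal.model.emission_means))
        dt = ideal.frame_period
        flags[i] = any(
            st == hs and (e - s) * dt >= min_dwell - 1e-9
            for st, s, e in ideal.dwell_segments()
        )
    if len(flags) >= 2 and n_boot > 0:
        res = bootstrap_statistic(flags.tolist(), np.mean, n_boot=n_boot, seed=seed)
        se = res.se
    else:
        se = float("nan")
    return AccommodatedFraction(
        fraction=float(flags.mean()), se=se, flags=flags, n_traces=len(flags)
    )


def hill_curve(c, ic50, hill, floor, ceiling):
    """Decreasing Hill function; f(0) = ceiling, f(inf) = floor."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        r = np.where(c > 0, (c / ic50) ** hill, 0.0)
    return floor + (ceiling - floor) / (1.0 + r)


def fit_hill(concentrations, fractions, weights=None) -> DoseResponseFit:
    """Least-squares Hill fit of accommodated fraction vs concentration.

    Multi-start over a log-spaced IC50 grid spanning the sampled
    concentration range crossed with Hill slopes {0.5, 1, 2}; the best
    start by residual sum of squares wins.  All starts and bounds are
    derived from the data, so rescaling every concentration by a factor
    rescales the fitted IC50 by exactly that factor.

    Raises ``ValueError`` for flat (IC50-unidentifiable) responses or
    when no start converges.
    """
    c = np.asarray(concentrations, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if c.ndim != 1 or c.shape != f.shape:
        raise ValueError("concentrations and fractions must be 1-D and matched")
    if len(np.unique(c)) < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    w = np.ones_like(f) if weights is None else np.asarray(weights, dtype=float)
    if f.max() - f.min() < 0.05:
        raise ValueError("flat response: IC50 is unidentifiable")

    pos = c[c > 0]
    if pos.size < 2:
        raise ValueError("need >= 2 positive concentrations")
    lo, hi = np.log10(pos.min()), np.log10(pos.max())

    def residuals(theta):
        log_ic50, h, fl, ce = theta
        return w * (hill_curve(c, 10.0 ** log_ic50, h, fl, ce) - f)

    bounds = ([lo - 3.0, 0.05, 0.0, 0.0], [hi + 3.0, 10.0, 1.0, 1.0])
    f_lo, f_hi = float(np.clip(f.min(), 0, 1)), float(np.clip(f.max(), 0, 1))
    best = None
    for log_start in np.linspace(lo, hi, 5):
        for h0 in (0.5, 1.0, 2.0):
            try:
                sol = least_squares(
                    residuals, x0=[log_start, h0, f_lo, f_hi], bounds=bounds
                )
            except Exception:
                continue
            if not sol.success:
                continue
            sse = float(2.0 * sol.cost)
            if best is None or sse < best[0] - 1e-12:
                best = (sse, sol.x)
    if best is None:
        raise ValueError("Hill fit failed to converge from every start")
    sse, (log_ic50, h, fl, ce) = best
    if ce - fl < 0.02:
        raise ValueError("degenerate fit: floor ~= ceiling, IC50 unidentifiable")
    return DoseResponseFit(
        ic50=float(10.0 ** log_ic50), hill_slope=float(h),
        floor=float(fl), ceiling=float(ce),
        concentrations=c, fractions=f, converged=True, sse=sse,
    )


def fit_hill_bootstrap(
    concentrations,
    flags_per_dose,
    n_boot: int = 1000,
    seed=None,
) -> DoseResponseFit:
    """Hill fit with a trace-bootstrap SE on the IC50.

    ``flags_per_dose`` holds, for each concentration, the per-trace
    accommodated booleans; each bootstrap replicate resamples traces
    within each dose, recomputes the fractions and refits.  Replicates
    on which the fit fails are dropped (error if more than half fail).
    """
    c = np.asarray(concentrations, dtype=float)
    flags = [np.asarray(fl, dtype=bool) for fl in flags_per_dose]
    if len(flags) != len(c):
        raise ValueError("one flag array per concentration required")
    fractions = np.array([fl.mean() for fl in flags])
    fit = fit_hill(c, fractions)

    rng = np.random.default_rng(seed)
    vals = []
    n_failed = 0
    for _ in range(n_boot):
        fb = np.array(
            [fl[rng.integers(0, len(fl), len(fl))].mean() for fl in flags]
        )
        try:
            vals.append(fit_hill(c, fb).ic50)
        except ValueError:
            n_failed += 1
    if n_failed > n_boot / 2:
        raise RuntimeError(f"Hill fit failed on {n_failed}/{n_boot} resamples")
    fit.se_ic50 = float(np.std(vals)) if len(vals) >= 2 else float("nan")
    fit.n_traces = [int(len(fl)) for fl in flags]
    return fit
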