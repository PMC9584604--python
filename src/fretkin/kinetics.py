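"""Dwell-time and transition-rate estimation for idealized traces.

Implements the analysis applied to aa-tRNA selection traces: each trace
is restricted to the interval before its first dwell in high FRET
lasting >= 150 ms, apparent rates k_i->j are estimated as transition
counts over state occupancy times, and standard errors come from
resampling whole traces with replacement (1000 bootstrap samples by
default, matching the published protocol).

Censoring convention: dwells that touch a trace boundary contribute
occupancy time but no exit event.  A truncated trace is an exception —
its final dwell ends in an *observed* entry into the long high-FRET
dwell, recorded via ``IdealizedTrace.terminal_state``, so that mid->high
transition is counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .idealize import IdealizedTrace, extract_dwells

__all__ = [
    "RateMatrixEstimate",
    "SurvivalCurve",
    "BootstrapResult",
    "truncate_before_first_long_high",
    "dwell_table",
    "truth_dwell_table",
    "estimate_rate_matrix",
    "state_lifetimes",
    "transition_ratio",
    "survival_curve",
    "bootstrap_statistic",
]

KINETIC_STATES = ("CR", "GA", "AC")


@dataclass
class RateMatrixEstimate:
    """Apparent transition rates k_i->j with bootstrap standard errors.

    ``k[i, j] = counts[i, j] / occupancy[i]`` for i != j; ``k_total`` is
    the row sum (the per-state decay rate k_i).  Entries for states with
    zero occupancy are NaN (missing), never zero.  ``boot_k`` holds the
    bootstrap replicate matrices used for derived-quantity errors.
    """

    state_labels: tuple
    k: np.ndarray
    k_total: np.ndarray
    se: np.ndarray
    se_total: np.ndarray
    counts: np.ndarray
    occupancy: np.ndarray
    n_traces: int
    boot_k: np.ndarray | None = None

    def rate(self, src: str, dst: str) -> float:
        i, j = self.state_labels.index(src), self.state_labels.index(dst)
        return float(self.k[i, j])

    def to_dict(self) -> dict:
        return {
            "state_labels": list(self.state_labels),
            "k": _nan_to_none(self.k),
            "k_total": _nan_to_none(self.k_total),
            "se": _nan_to_none(self.se),
            "se_total": _nan_to_none(self.se_total),
            "counts": self.counts.tolist(),
            "occupancy_s": self.occupancy.tolist(),
            "n_traces": int(self.n_traces),
        }


@dataclass
class SurvivalCurve:
    """Empirical dwell-time survival S(t) with a bootstrap s.e.m. band."""

    time: np.ndarray
    survival: np.ndarray
    se: np.ndarray
    n_dwells: int


@dataclass
class BootstrapResult:
    point: float
    se: float
    n_boot: int
    n_failed: int = 0


def _nan_to_none(a):
    return [
        [None if not np.isfinite(v) else float(v) for v in row]
        if np.ndim(row) else (None if not np.isfinite(row) else float(row))
        for row in np.atleast_1d(a)
    ]


def truncate_before_first_long_high(
    ideal: IdealizedTrace,
    min_high_dwell: float = 0.150,
    high_state: int | None = None,
) -> IdealizedTrace:
    """Restrict a trace to before its first long high-FRET dwell.

    Returns the prefix ending at the first frame of the first high-FRET
    dwell whose duration is >= ``min_high_dwell`` (inclusive; 10 frames
    at 15 ms).  Shorter high-FRET excursions are retained.  If no such
    dwell exists the trace is returned unchanged.  The returned trace
    carries ``terminal_state = high`` so the final observed transition
    into the long dwell is counted, not censored.
    """
    if high_state is None:
        high_state = int(np.argmax(ideal.model.emission_means))
    dt = ideal.frame_period
    for state, s, e in ideal.dwell_segments():
        if state == high_state and (e - s) * dt >= min_high_dwell - 1e-9:
            return IdealizedTrace(
                state_seq=ideal.state_seq[:s],
                frame_period=dt,
                fret=ideal.fret[:s],
                model=ideal.model,
                trace_id=ideal.trace_id,
                converged=ideal.converged,
                logp_history=ideal.logp_history,
                terminal_state=high_state,
            )
    return ideal


def dwell_table(ideals, min_frames: int = 1) -> pd.DataFrame:
    """Pooled dwell table over a list of idealized traces.

    Traces lacking a ``trace_id`` get their position in the list.
    """
    frames = []
    for i, ideal in enumerate(ideals):
        df = extract_dwells(ideal, min_frames=min_frames)
        if len(df):
            if ideal.trace_id is None:
                df["trace_id"] = i
            frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["trace_id", "state", "start_s", "duration_s", "next_state", "censored"]
        )
    return pd.concat(frames, ignore_index=True)


def truth_dwell_table(paths, t_obs=None) -> pd.DataFrame:
    """Exact dwell table from simulated state paths (idealization bypass).

    Serves as the truth-path oracle: rate estimation on these continuous
    dwells isolates the count/occupancy estimator from idealization and
    frame-discretization effects.  ``t_obs`` optionally right-censors
    each path at an observation end (e.g. the rendered trace length);
    scalar or one value per path.

    The first dwell and the dwell running into the observation end are
    flagged censored, matching :func:`~fretkin.idealize.extract_dwells`.
    """
    paths = list(paths)
    if np.ndim(t_obs) == 0:
        t_obs = [t_obs] * len(paths)
    rows = []
    for i, (path, tend) in enumerate(zip(paths, t_obs)):
        tend = path.t_end if tend is None else min(float(tend), path.t_end)
        keep = path.t_entry < tend
        sts = path.states[keep]
        t0 = path.t_entry[keep]
        t1 = np.minimum(path.t_exit[keep], tend)
        for j, (s, a, b) in enumerate(zip(sts, t0, t1)):
            last = j == len(sts) - 1
            cut = last and (b >= tend or path.t_exit[keep][j] > b)
            rows.append(
                {
                    "trace_id": i,
                    "state": int(s),
                    "start_s": float(a),
                    "duration_s": float(b - a),
                    "next_state": float(sts[j + 1]) if not last else float("nan"),
                    "censored": bool(j == 0 or cut or last),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["trace_id", "state", "start_s", "duration_s", "next_state", "censored"],
    )
    return df.astype({"state": int, "next_state": float, "censored": bool})


def _per_trace_arrays(dwells, labels, state_index, exclude_censored_exits):
    """Per-trace transition count matrices and occupancy vectors."""
    m = len(labels)
    groups = dwells.groupby("trace_id", sort=False, dropna=False)
    counts = np.zeros((groups.ngroups, m, m))
    occ = np.zeros((groups.ngroups, m))
    for g, (_, df) in enumerate(groups):
        st = df["state"].map(state_index)
        keep = st.notna().to_numpy()
        si = st.to_numpy(dtype=float)
        occ_idx = si[keep].astype(int)
        np.add.at(occ[g], occ_idx, df["duration_s"].to_numpy()[keep])
        nx = df["next_state"].map(state_index)
        ok = keep & nx.notna().to_numpy()
        if exclude_censored_exits:
            ok &= ~df["censored"].to_numpy(dtype=bool)
        if ok.any():
            np.add.at(
                counts[g],
                (si[ok].astype(int), nx.to_numpy(dtype=float)[ok].astype(int)),
                1.0,
            )
    return counts, occ


def estimate_rate_matrix(
    dwells: pd.DataFrame,
    state_labels,
    exclude_states=("dark",),
    exclude_censored_exits: bool = True,
    n_boot: int = 1000,
    seed=None,
) -> RateMatrixEstimate:
    """Count/occupancy estimator of apparent transition rates.

    ``state_labels`` names every state index appearing in ``dwells``
    (i.e. the idealization model's labels); states in ``exclude_states``
    (the dark, pre-arrival state by default) are dropped entirely.
    k_i->j = N_i->j / T_i with T_i the total occupancy of state i
    including censored dwells; censored dwells contribute no exit events
    when ``exclude_censored_exits``.  Bootstrap SEs resample whole
    traces with replacement.
    """
    if len(dwells) == 0:
        raise ValueError("empty dwell table")
    state_labels = tuple(state_labels)
    kept = [s for s in state_labels if s not in set(exclude_states)]
    state_index = {state_labels.index(s): i for i, s in enumerate(kept)}
    counts, occ = _per_trace_arrays(dwells, kept, state_index, exclude_censored_exits)
    if counts.sum() == 0:
        raise ValueError("no uncensored transitions among the kept states")
    N, T = counts.sum(axis=0), occ.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(T[:, None] > 0, N / np.where(T[:, None] > 0, T[:, None], 1.0), np.nan)
    np.fill_diagonal(k, 0.0)
    k_total = k.sum(axis=1)
    k_total[T == 0] = np.nan

    n_traces = counts.shape[0]
    boot_k = None
    se = np.full_like(k, np.nan)
    se_total = np.full_like(k_total, np.nan)
    if n_boot > 0 and n_traces >= 2:
        rng = np.random.default_rng(seed)
        m = len(kept)
        boot_k = np.empty((n_boot, m, m))
        for b in range(n_boot):
            idx = rng.integers(0, n_traces, n_traces)
            Nb = counts[idx].sum(axis=0)
            Tb = occ[idx].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                kb = np.where(Tb[:, None] > 0, Nb / np.where(Tb[:, None] > 0, Tb[:, None], 1.0), np.nan)
            np.fill_diagonal(kb, 0.0)
            boot_k[b] = kb
        with np.errstate(invalid="ignore"):
            se = np.nanstd(boot_k, axis=0)
            se_total = np.nanstd(boot_k.sum(axis=2), axis=0)
        np.fill_diagonal(se, 0.0)
    return RateMatrixEstimate(
        state_labels=tuple(kept),
        k=k,
        k_total=k_total,
        se=se,
        se_total=se_total,
        counts=N,
        occupancy=T,
        n_traces=n_traces,
        boot_k=boot_k,
    )


def state_lifetimes(est: RateMatrixEstimate) -> np.ndarray:
    """Mean state lifetime 1 / k_i; infinite where k_i = 0."""
    with np.errstate(divide="ignore"):
        return np.where(est.k_total > 0, 1.0 / est.k_total, np.inf)


def transition_ratio(
    est: RateMatrixEstimate,
    state: str = "GA",
    to_high: str = "AC",
    to_low: str = "CR",
):
    """Ratio of mid-to-high over mid-to-low transition rates, with SE.

    k_GA->AC / k_GA->CR compares proofreading attempts against initial
    selection reversals.  SE from the stored bootstrap replicates.
    """
    lo = est.rate(state, to_low)
    hi = est.rate(state, to_high)
    if not lo > 0:
        raise ZeroDivisionError(f"k_{state}->{to_low} is zero or missing")
    ratio = hi / lo
    se = float("nan")
    if est.boot_k is not None:
        i = est.state_labels.index(state)
        jh = est.state_labels.index(to_high)
        jl = est.state_labels.index(to_low)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = est.boot_k[:, i, jh] / est.boot_k[:, i, jl]
        r = r[np.isfinite(r)]
        if r.size >= 2:
            se = float(r.std())
    return ratio, se


def survival_curve(
    dwells: pd.DataFrame,
    state: int,
    grid: np.ndarray | None = None,
    n_boot: int = 1000,
    seed=None,
) -> SurvivalCurve:
    """Empirical survival of uncensored dwell durations in one state.

    S(t) is the fraction of dwells longer than t; the band is the s.e.m.
    from resampling traces with replacement.
    """
    sel = (dwells["state"] == state) & ~dwells["censored"].astype(bool)
    sub = dwells[sel]
    if len(sub) == 0:
        raise ValueError(f"no uncensored dwells in state {state}")
    durations = sub["duration_s"].to_numpy(dtype=float)
    if grid is None:
        grid = np.linspace(0.0, float(durations.max()), 101)
    grid = np.asarray(grid, dtype=float)
    surv = (durations[None, :] > grid[:, None]).mean(axis=1)

    se = np.full_like(grid, np.nan)
    ids = sub["trace_id"].to_numpy()
    uniq = pd.unique(ids)
    if n_boot > 0 and len(uniq) >= 2:
        rng = np.random.default_rng(seed)
        by_trace = [durations[ids == u] for u in uniq]
        boots = np.empty((n_boot, len(grid)))
        for b in range(n_boot):
            idx = rng.integers(0, len(by_trace), len(by_trace))
            d = np.concatenate([by_trace[i] for i in idx])
            boots[b] = (
                (d[None, :] > grid[:, None]).mean(axis=1) if d.size else np.nan
            )
        se = np.nanstd(boots, axis=0)
    return SurvivalCurve(time=grid, survival=surv, se=se, n_dwells=len(durations))


def bootstrap_statistic(
    units,
    statistic,
    n_boot: int = 1000,
    seed=None,
) -> BootstrapResult:
    """Trace-level bootstrap of an arbitrary statistic.

    ``units`` is a sequence of resampling units (whole traces or
    per-trace dwell groups); ``statistic`` maps a list of units to a
    number.  Resamples on which the statistic raises or is non-finite
    are dropped and counted; more than 50% failures is an error.
    """
    units = list(units)
    if len(units) < 2:
        raise ValueError("need at least 2 resampling units")
    point = float(statistic(units))
    rng = np.random.default_rng(seed)
    vals = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(units), len(units))
        try:
            v = float(statistic([units[i] for i in idx]))
        except Exception:
            n_failed += 1
            continue
        if not np.isfinite(v):
            n_failed += 1
            continue
        vals.append(v)
    if n_failed > n_boot / 2:
        raise RuntimeError(
            f"statistic undefined on {n_failed}/{n_boot} bootstrap resamples"
        )
    se = float(np.std(vals)) if len(vals) >= 2 else float("nan")
    return BootstrapResult(point=point, se=se, n_boot=n_boot, n_failed=n_failed)
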