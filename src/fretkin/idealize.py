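"""Trace idealization by segmental k-means (SKM) over a Gaussian HMM.

Each frame of a noisy FRET trace is assigned to a discrete state by
Viterbi decoding under a hidden Markov model with Gaussian emissions;
SKM alternates decoding with re-estimation of the transition matrix
(and, optionally, the emission parameters) from the decoded path until
the path is stable.  The default model has four states — a zero-FRET
dark state absorbing pre-arrival and post-bleach frames, plus the CR
(0.2), GA (0.45) and AC (0.7) selection states — with emission means
held fixed at those nominal values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "HmmModel",
    "IdealizedTrace",
    "default_model",
    "viterbi_path",
    "path_log_probability",
    "skm_idealize",
    "run_length_segments",
    "extract_dwells",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class HmmModel:
    """Gaussian-emission HMM over discrete FRET states."""

    emission_means: np.ndarray
    emission_sigmas: np.ndarray
    transition_probs: np.ndarray
    initial_probs: np.ndarray
    state_labels: tuple
    fixed_means: bool = True

    def __post_init__(self):
        mu = np.asarray(self.emission_means, dtype=float)
        sig = np.asarray(self.emission_sigmas, dtype=float)
        A = np.asarray(self.transition_probs, dtype=float)
        pi = np.asarray(self.initial_probs, dtype=float)
        object.__setattr__(self, "emission_means", mu)
        object.__setattr__(self, "emission_sigmas", sig)
        object.__setattr__(self, "transition_probs", A)
        object.__setattr__(self, "initial_probs", pi)
        object.__setattr__(self, "state_labels", tuple(self.state_labels))
        n = len(mu)
        if not (len(sig) == n == len(pi) == len(self.state_labels)):
            raise ValueError("inconsistent state dimensions")
        if A.shape != (n, n):
            raise ValueError("transition matrix shape mismatch")
        if np.any(sig <= 0):
            raise ValueError("emission sigmas must be > 0")
        if np.max(np.abs(A.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("transition matrix rows must sum to 1")
        if abs(pi.sum() - 1.0) > 1e-10:
            raise ValueError("initial probabilities must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.emission_means)

    @property
    def dark_state(self) -> int | None:
        """Index of the dark (zero-FRET) state, if the model has one."""
        try:
            return self.state_labels.index("dark")
        except ValueError:
            return None

    def index(self, label: str) -> int:
        return self.state_labels.index(label)


def default_model(
    means=(0.0, 0.2, 0.45, 0.7),
    sigma: float = 0.06,
    state_labels=None,
    self_prob: float = 0.95,
    fixed_means: bool = True,
) -> HmmModel:
    """Weakly informative starting model for SKM.

    Uniform self-transition probability 0.95 with the remainder split
    evenly; uniform initial distribution.  ``sigma`` may be a scalar or a
    per-state sequence.  The 4-state default carries labels
    ``("dark", "CR", "GA", "AC")``; other sizes label the non-dark states
    by their means unless ``state_labels`` is given.
    """
    means = np.asarray(means, dtype=float)
    n = len(means)
    sigmas = np.broadcast_to(np.asarray(sigma, dtype=float), (n,)).copy()
    if state_labels is None:
        if n == 4 and means[0] == 0.0:
            state_labels = ("dark", "CR", "GA", "AC")
        else:
            state_labels = tuple(f"S{m:g}" for m in means)
    A = np.full((n, n), (1.0 - self_prob) / max(n - 1, 1))
    np.fill_diagonal(A, self_prob if n > 1 else 1.0)
    pi = np.full(n, 1.0 / n)
    return HmmModel(means, sigmas, A, pi, state_labels, fixed_means=fixed_means)


@dataclass
class IdealizedTrace:
    """Per-frame state assignment of one trace, with dwell segmentation.

    ``terminal_state`` records a state known to be entered at the frame
    immediately after the last one (set by truncation at the first long
    high-FRET dwell) so that the final dwell's exit is an observed
    transition rather than a censoring event.
    """

    state_seq: np.ndarray
    frame_period: float
    fret: np.ndarray
    model: HmmModel
    trace_id: object = None
    converged: bool = True
    logp_history: list = field(default_factory=list)
    terminal_state: int | None = None

    @property
    def n_frames(self) -> int:
        return len(self.state_seq)

    def dwell_segments(self):
        """(state, start_frame, end_frame) runs; frames half-open [start, end)."""
        return run_length_segments(self.state_seq)


def _emission_loglik(fret: np.ndarray, model: HmmModel) -> np.ndarray:
    z = (fret[:, None] - model.emission_means[None, :]) / model.emission_sigmas
    return -0.5 * (z * z + _LOG2PI) - np.log(model.emission_sigmas)[None, :]


def viterbi_path(trace, model: HmmModel) -> np.ndarray:
    """Most probable state sequence under the model (MAP path).

    Ties are broken toward the lower state index.  ``trace`` may be a
    :class:`~fretkin.synthetic.Trace` or a bare FRET array.  Non-finite
    FRET values are an error: mask or trim before decoding.
    """
    fret = np.asarray(getattr(trace, "fret", trace), dtype=float)
    if fret.size == 0:
        raise ValueError("cannot decode an empty trace")
    if not np.all(np.isfinite(fret)):
        raise ValueError("non-finite FRET frames; mask or trim before decoding")
    n = model.n_states
    loglik = _emission_loglik(fret, model)
    logA = np.log(np.maximum(model.transition_probs, _PROB_FLOOR))
    delta = np.log(np.maximum(model.initial_probs, _PROB_FLOOR)) + loglik[0]
    T = len(fret)
    psi = np.empty((T, n), dtype=np.intp)
    idx = np.arange(n)
    for t in range(1, T):
        cand = delta[:, None] + logA
        best = np.argmax(cand, axis=0)  # first max -> lowest predecessor index
        psi[t] = best
        delta = cand[best, idx] + loglik[t]
    path = np.empty(T, dtype=np.intp)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path


def path_log_probability(fret: np.ndarray, path: np.ndarray, model: HmmModel) -> float:
    """Joint log-probability of a given state path and the emissions."""
    loglik = _emission_loglik(np.asarray(fret, dtype=float), model)
    logA = np.log(np.maximum(model.transition_probs, _PROB_FLOOR))
    logpi = np.log(np.maximum(model.initial_probs, _PROB_FLOOR))
    lp = logpi[path[0]] + loglik[np.arange(len(path)), path].sum()
    if len(path) > 1:
        lp += logA[path[:-1], path[1:]].sum()
    return float(lp)


def _reestimate(model: HmmModel, fret: np.ndarray, path: np.ndarray) -> HmmModel:
    n = model.n_states
    counts = np.zeros((n, n))
    if len(path) > 1:
        np.add.at(counts, (path[:-1], path[1:]), 1.0)
    A = model.transition_probs.copy()
    visited = counts.sum(axis=1) > 0
    A[visited] = counts[visited] / counts[visited].sum(axis=1, keepdims=True)
    A = np.maximum(A, _PROB_FLOOR)
    A /= A.sum(axis=1, keepdims=True)
    pi = np.full(n, _PROB_FLOOR)
    pi[path[0]] = 1.0
    pi /= pi.sum()
    mu, sig = model.emission_means, model.emission_sigmas
    if not model.fixed_means:
        mu = mu.copy()
        sig = sig.copy()
        for s in range(n):
            sel = path == s
            if sel.sum() >= 2:
                mu[s] = fret[sel].mean()
                sig[s] = max(fret[sel].std(), 1e-3)
    return replace(
        model, transition_probs=A, initial_probs=pi,
        emission_means=mu, emission_sigmas=sig,
    )


def skm_idealize(
    trace,
    model: HmmModel | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> IdealizedTrace:
    """Segmental k-means idealization of one trace.

    Alternates Viterbi decoding with maximum-likelihood re-estimation of
    the transition matrix (and emission parameters when
    ``model.fixed_means`` is false) from the decoded path, until the path
    is unchanged, the relative joint log-probability change falls below
    ``tol``, or ``max_iter`` is reached (then ``converged`` is False).
    The joint log-probability is non-decreasing across iterations.
    """
    if model is None:
        model = default_model()
    fret = np.asarray(getattr(trace, "fret", trace), dtype=float)
    donor = getattr(trace, "donor", None)
    if donor is not None:
        total = np.asarray(donor) + np.asarray(trace.acceptor)
        valid = np.isfinite(fret) & (total > 0)
    else:
        valid = np.isfinite(fret)
    # trailing invalid frames (post-bleach) are trimmed; interior ones are an error
    n_valid = int(np.max(np.nonzero(valid)[0])) + 1 if valid.any() else 0
    if not valid[:n_valid].all():
        raise ValueError("interior masked frames are not supported")
    fret = fret[:n_valid]
    frame_period = getattr(trace, "frame_period", 1.0)
    trace_id = None
    if hasattr(trace, "metadata"):
        trace_id = trace.metadata.get("trace_id")
    if n_valid == 0:
        return IdealizedTrace(
            np.empty(0, dtype=np.intp), frame_period, fret, model,
            trace_id=trace_id, converged=True,
        )

    path = None
    history: list = []
    converged = False
    for _ in range(max_iter):
        new_path = viterbi_path(fret, model)
        lp = path_log_probability(fret, new_path, model)
        history.append(lp)
        if path is not None and np.array_equal(new_path, path):
            path = new_path
            converged = True
            break
        if len(history) >= 2 and abs(lp - history[-2]) <= tol * abs(history[-2]):
            path = new_path
            converged = True
            break
        path = new_path
        model = _reestimate(model, fret, path)
    return IdealizedTrace(
        state_seq=path,
        frame_period=frame_period,
        fret=fret,
        model=model,
        trace_id=trace_id,
        converged=converged,
        logp_history=history,
    )


def run_length_segments(seq: np.ndarray):
    """Run-length encode a state sequence into (state, start, end) tuples."""
    seq = np.asarray(seq)
    if seq.size == 0:
        return []
    change = np.flatnonzero(np.diff(seq)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(seq)]])
    return [(int(seq[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def _merge_short_runs(seq: np.ndarray, min_frames: int) -> np.ndarray:
    seq = seq.copy()
    while True:
        segs = run_length_segments(seq)
        if len(segs) <= 1:
            return seq
        short = [i for i, (_, s, e) in enumerate(segs) if e - s < min_frames]
        if not short:
            return seq
        i = short[0]
        state, s, e = segs[i]
        # absorb into the previous run (or the following one if first)
        target = segs[i - 1][0] if i > 0 else segs[i + 1][0]
        seq[s:e] = target


def extract_dwells(ideal: IdealizedTrace, min_frames: int = 1) -> pd.DataFrame:
    """Dwell table of one idealized trace.

    Runs shorter than ``min_frames`` are merged into their neighbors
    first (default: no merging).  The first and last dwells are flagged
    censored (entry/exit unobserved), except that a truncated trace's
    final dwell exits into ``terminal_state`` and is uncensored.

    Returns a DataFrame with columns ``trace_id, state, start_s,
    duration_s, next_state, censored``.
    """
    seq = ideal.state_seq
    if min_frames > 1 and seq.size:
        seq = _merge_short_runs(seq, min_frames)
    segs = run_length_segments(seq)
    dt = ideal.frame_period
    rows = []
    for i, (state, s, e) in enumerate(segs):
        last = i == len(segs) - 1
        if not last:
            nxt = float(segs[i + 1][0])
            censored = i == 0
        elif ideal.terminal_state is not None:
            nxt = float(ideal.terminal_state)
            censored = i == 0  # exit observed via truncation
        else:
            nxt = float("nan")
            censored = True
        rows.append(
            {
                "trace_id": ideal.trace_id,
                "state": state,
                "start_s": s * dt,
                "duration_s": (e - s) * dt,
                "next_state": nxt,
                "censored": bool(censored or i == 0),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["trace_id", "state", "start_s", "duration_s", "next_state", "censored"],
    )
    return df.astype({"state": int, "next_state": float, "censored": bool})
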