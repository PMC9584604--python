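"""Ensemble summaries: post-synchronized FRET contours and transition
density plots (TDPs).

Post-synchronization aligns every trace to the first appearance of FRET
signal (the first non-dark idealized frame) so that non-equilibrium
selection kinetics can be averaged across molecules arriving at
different times.  The TDP histograms the (FRET before, FRET after) pair
of every idealized transition, using the dwell-mean *raw* FRET so the
emission noise structure stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .idealize import IdealizedTrace

__all__ = [
    "Histogram2D",
    "DEFAULT_FRET_EDGES",
    "postsynchronize",
    "contour_histogram",
    "transition_density",
]

DEFAULT_FRET_EDGES = np.linspace(-0.1, 1.0, 46)  # 45 bins


@dataclass
class Histogram2D:
    """2-D histogram with bin edges; optionally column-normalized."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    normalized: bool
    n_traces: int

    def column_normalized(self) -> "Histogram2D":
        """Normalize each x-column to sum to 1 (empty columns left at 0)."""
        col = self.counts.sum(axis=1, keepdims=True)
        out = np.divide(
            self.counts, col, out=np.zeros_like(self.counts, dtype=float),
            where=col > 0,
        )
        return _dc_replace(self, counts=out, normalized=True)


def _first_signal_frame(ideal: IdealizedTrace, fret_threshold: float):
    dark = ideal.model.dark_state
    if dark is not None:
        hits = np.flatnonzero(ideal.state_seq != dark)
    else:
        hits = np.flatnonzero(ideal.fret > fret_threshold)
    return int(hits[0]) if hits.size else None


def postsynchronize(ideals, fret_threshold: float = 0.12):
    """Align traces to the first appearance of FRET.

    Each trace is shifted so frame 0 is its first non-dark idealized
    frame (or, for models without a dark state, the first frame with raw
    FRET above ``fret_threshold``).  Traces with no detected event are
    dropped.

    Returns ``(aligned, n_dropped)``.
    """
    ideals = list(ideals)
    if not ideals:
        raise ValueError("no traces to post-synchronize")
    aligned = []
    n_dropped = 0
    for ideal in ideals:
        f0 = _first_signal_frame(ideal, fret_threshold)
        if f0 is None:
            n_dropped += 1
            continue
        aligned.append(
            IdealizedTrace(
                state_seq=ideal.state_seq[f0:],
                frame_period=ideal.frame_period,
                fret=ideal.fret[f0:],
                model=ideal.model,
                trace_id=ideal.trace_id,
                converged=ideal.converged,
                terminal_state=ideal.terminal_state,
            )
        )
    return aligned, n_dropped


def contour_histogram(
    aligned,
    time_window: float = 10.0,
    fret_edges: np.ndarray | None = None,
    normalize: bool = True,
) -> Histogram2D:
    """2-D occupancy histogram of raw FRET vs time since synchronization.

    Each column (time slice, one frame wide) is normalized to unit sum
    when ``normalize`` so the plot shows the FRET distribution of the
    surviving population at each time.
    """
    aligned = list(aligned)
    if not aligned:
        raise ValueError("empty aligned trace set")
    if fret_edges is None:
        fret_edges = DEFAULT_FRET_EDGES
    dt = aligned[0].frame_period
    n_cols = int(round(time_window / dt))
    t_edges = np.arange(n_cols + 1) * dt
    counts = np.zeros((n_cols, len(fret_edges) - 1))
    for ideal in aligned:
        n = min(ideal.n_frames, n_cols)
        if n == 0:
            continue
        cols = np.arange(n)
        rows = np.searchsorted(fret_edges, ideal.fret[:n], side="right") - 1
        ok = (rows >= 0) & (rows < counts.shape[1])
        np.add.at(counts, (cols[ok], rows[ok]), 1.0)
    hist = Histogram2D(
        x_edges=t_edges, y_edges=np.asarray(fret_edges, dtype=float),
        counts=counts, normalized=False, n_traces=len(aligned),
    )
    return hist.column_normalized() if normalize else hist


def transition_density(
    ideals,
    fret_edges: np.ndarray | None = None,
) -> Histogram2D:
    """Transition density plot over all idealized transitions.

    For every transition between two non-dark dwells, one point at
    (mean raw FRET of the dwell before, mean raw FRET of the dwell
    after), binned on a FRET x FRET grid.  Transitions into or out of
    the dark state are excluded.
    """
    if fret_edges is None:
        fret_edges = DEFAULT_FRET_EDGES
    before, after = [], []
    n_traces = 0
    for ideal in ideals:
        n_traces += 1
        dark = ideal.model.dark_state
        segs = ideal.dwell_segments()
        means = [float(ideal.fret[s:e].mean()) for _, s, e in segs]
        for (st0, _, _), (st1, _, _), m0, m1 in zip(
            segs[:-1], segs[1:], means[:-1], means[1:]
        ):
            if dark is not None and (st0 == dark or st1 == dark):
                continue
            before.append(m0)
            after.append(m1)
    if not before:
        raise ValueError("no transitions to histogram")
    counts, xe, ye = np.histogram2d(before, after, bins=[fret_edges, fret_edges])
    return Histogram2D(
        x_edges=xe, y_edges=ye, counts=counts, normalized=False, n_traces=n_traces
    )
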