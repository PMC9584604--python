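"""File formats: per-trace CSVs with an index TSV, dwell tables, rate
JSON, histogram TSV, and YAML run configurations.

A trace set on disk is a directory of ``trace_<id>.csv`` files with
columns ``time_s, donor, acceptor, fret, truth_state`` plus an
``index.tsv`` mapping trace id to condition, concentration, seed and
frame period.  All times are seconds, rates s^-1, FRET dimensionless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Trace

__all__ = [
    "TraceParseError",
    "write_traces",
    "read_traces",
    "write_dwells",
    "read_dwells",
    "write_rates_json",
    "write_histogram",
    "write_survival",
]

INDEX_NAME = "index.tsv"


class TraceParseError(ValueError):
    """Malformed trace file or index."""


def write_traces(traces, outdir) -> Path:
    """Write a trace set as one CSV per trace plus an index TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index_rows = []
    for i, tr in enumerate(traces):
        tid = tr.metadata.get("trace_id", i)
        fname = f"trace_{tid}.csv"
        truth = (
            tr.truth_states
            if tr.truth_states is not None
            else np.full(tr.n_frames, -1, dtype=int)
        )
        df = pd.DataFrame(
            {
                "time_s": np.round(tr.times, 9),
                "donor": tr.donor,
                "acceptor": tr.acceptor,
                "fret": tr.fret,
                "truth_state": truth,
            }
        )
        df.to_csv(outdir / fname, index=False, float_format="%.9g")
        index_rows.append(
            {
                "trace_id": tid,
                "file": fname,
                "condition": tr.metadata.get("condition"),
                "concentration_nM": tr.metadata.get("concentration_nM"),
                "seed": tr.metadata.get("seed"),
                "frame_period_s": tr.frame_period,
                "n_frames": tr.n_frames,
            }
        )
    pd.DataFrame(index_rows).to_csv(outdir / INDEX_NAME, sep="\t", index=False)
    return outdir


def read_traces(path) -> list:
    """Read a trace-set directory written by :func:`write_traces`.

    A missing ``fret`` column is recomputed from donor/acceptor.
    Malformed files raise :class:`TraceParseError` naming the file.
    """
    path = Path(path)
    index_path = path / INDEX_NAME
    if not index_path.exists():
        raise TraceParseError(f"missing index file: {index_path}")
    index = pd.read_csv(index_path, sep="\t")
    traces = []
    for row in index.itertuples(index=False):
        fpath = path / row.file
        try:
            df = pd.read_csv(fpath)
        except Exception as exc:
            raise TraceParseError(f"{fpath}: cannot parse ({exc})") from exc
        for col in ("donor", "acceptor"):
            if col not in df.columns:
                raise TraceParseError(f"{fpath}: missing column {col!r}")
        frame_period = float(row.frame_period_s)
        if frame_period <= 0:
            raise TraceParseError(f"{index_path}: frame_period_s <= 0 for {row.file}")
        donor = df["donor"].to_numpy(dtype=float)
        acceptor = df["acceptor"].to_numpy(dtype=float)
        if "fret" in df.columns:
            fret = df["fret"].to_numpy(dtype=float)
        else:
            total = donor + acceptor
            with np.errstate(invalid="ignore", divide="ignore"):
                fret = np.where(total > 0, acceptor / np.where(total > 0, total, 1.0), 0.0)
        truth = None
        if "truth_state" in df.columns:
            ts = df["truth_state"].to_numpy(dtype=int)
            if np.all(ts >= 0):
                truth = ts.astype(np.intp)
        meta = {
            "trace_id": row.trace_id,
            "condition": None if pd.isna(row.condition) else row.condition,
            "concentration_nM": None
            if pd.isna(row.concentration_nM)
            else float(row.concentration_nM),
            "seed": None if pd.isna(row.seed) else int(row.seed),
        }
        traces.append(
            Trace(
                donor=donor, acceptor=acceptor, fret=fret,
                frame_period=frame_period, metadata=meta, truth_states=truth,
            )
        )
    return traces


def write_dwells(dwells: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = dwells.copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.9g")
    return path


def read_dwells(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["censored"] = df["censored"].astype(bool)
    return df


def write_rates_json(est, path, provenance: dict | None = None) -> Path:
    """Rate matrix + SEs as JSON with state labels and provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = est.to_dict()
    doc["provenance"] = provenance or {}
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def write_histogram(hist, path_prefix) -> tuple:
    """Histogram counts as TSV with bin edges in a sidecar JSON."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = prefix.with_suffix(".tsv")
    np.savetxt(tsv, hist.counts, delimiter="\t", fmt="%.9g")
    sidecar = prefix.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "x_edges": hist.x_edges.tolist(),
                "y_edges": hist.y_edges.tolist(),
                "normalized": bool(hist.normalized),
                "n_traces": int(hist.n_traces),
            },
            indent=2,
        )
        + "\n"
    )
    return tsv, sidecar


def write_survival(curve, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"time_s": curve.time, "survival": curve.survival, "se": curve.se}
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")
    return path
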