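"""Readers and writers for traces, event lists and count matrices.

Traces travel as two-column delimited text (time_s, value) with a JSON
sidecar holding the units, sampling rate and acquisition metadata; ROI
tables as time plus one column per ROI; count matrices as MatrixMarket
with one-column gene and cell label files.  All formats are plain text.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .scrna import CountMatrix
from .trace import ParameterError, Trace


class DataError(ValueError):
    """Malformed or inconsistent on-disk data."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write samples plus a JSON sidecar next to them."""
    path = Path(path)
    data = np.column_stack([trace.times(), trace.values])
    np.savetxt(path, data, fmt="%.12g", header="time_s\tvalue", delimiter="\t")
    sidecar = {
        "units": trace.units,
        "sample_rate_hz": trace.sample_rate,
        "t0_s": trace.t0,
        "metadata": trace.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_trace(path: str | Path) -> Trace:
    """Read a trace and its sidecar; missing or malformed sidecar → error."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise DataError(f"missing sidecar {sidecar_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise DataError(f"sidecar {sidecar_path} is not valid JSON: {exc}") from exc
    for key in ("units", "sample_rate_hz"):
        if key not in sidecar:
            raise DataError(f"sidecar {sidecar_path} lacks required field {key!r}")
    data = np.loadtxt(path)
    values = data[:, 1] if data.ndim == 2 else np.atleast_1d(data)
    try:
        return Trace(
            values=values,
            sample_rate=float(sidecar["sample_rate_hz"]),
            units=str(sidecar["units"]),
            t0=float(sidecar.get("t0_s", 0.0)),
            metadata=dict(sidecar.get("metadata", {})),
        )
    except ParameterError as exc:
        raise DataError(str(exc)) from exc


def write_roi_table(traces: list[Trace], path: str | Path) -> None:
    """Multi-ROI fluorescence table: time_s plus one column per ROI."""
    if not traces:
        raise ParameterError("no traces to write")
    path = Path(path)
    cols = {"time_s": traces[0].times()}
    names = []
    for i, tr in enumerate(traces):
        if tr.n_samples != traces[0].n_samples:
            raise ParameterError("ROI traces must share a time base")
        name = tr.metadata.get("roi", f"roi{i:03d}")
        names.append(name)
        cols[name] = tr.values
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    sidecar = {
        "units": traces[0].units,
        "sample_rate_hz": traces[0].sample_rate,
        "t0_s": traces[0].t0,
        "rois": names,
        "metadata": {
            k: traces[0].metadata[k]
            for k in ("condition", "preparation", "drug_epochs")
            if k in traces[0].metadata
        },
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_roi_table(path: str | Path) -> list[Trace]:
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise DataError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("units", "sample_rate_hz", "rois"):
        if key not in sidecar:
            raise DataError(f"sidecar {sidecar_path} lacks required field {key!r}")
    df = pd.read_csv(path, sep="\t")
    shared = dict(sidecar.get("metadata", {}))
    traces = []
    for name in sidecar["rois"]:
        if name not in df.columns:
            raise DataError(f"ROI column {name!r} missing from {path}")
        md = dict(shared)
        md["roi"] = name
        traces.append(
            Trace(
                values=df[name].to_numpy(),
                sample_rate=float(sidecar["sample_rate_hz"]),
                units=str(sidecar["units"]),
                t0=float(sidecar.get("t0_s", 0.0)),
                metadata=md,
            )
        )
    return traces


def write_count_matrix(cm: CountMatrix, prefix: str | Path) -> None:
    """MatrixMarket file plus gene/cell label files sharing a prefix."""
    prefix = Path(prefix)
    sio.mmwrite(str(prefix.with_suffix(".mtx")), sp.coo_matrix(cm.counts))
    prefix.with_suffix(".genes.txt").write_text("\n".join(cm.gene_labels) + "\n")
    prefix.with_suffix(".cells.txt").write_text("\n".join(cm.cell_labels) + "\n")


def read_count_matrix(prefix: str | Path) -> CountMatrix:
    """Read a MatrixMarket matrix with its label files.

    Also accepts a delimited gene×cell table (genes as rows, first column
    gene names, header row of cell names) when ``prefix`` points at a
    ``.tsv``/``.csv`` file.
    """
    prefix = Path(prefix)
    if prefix.suffix in (".tsv", ".csv"):
        sep = "\t" if prefix.suffix == ".tsv" else ","
        df = pd.read_csv(prefix, sep=sep, index_col=0)
        return CountMatrix(
            counts=sp.csr_matrix(df.to_numpy(dtype=float)),
            gene_labels=[str(g) for g in df.index],
            cell_labels=[str(c) for c in df.columns],
        )
    mtx_path = prefix.with_suffix(".mtx")
    if not mtx_path.exists():
        raise DataError(f"missing matrix file {mtx_path}")
    counts = sp.csr_matrix(sio.mmread(str(mtx_path)))
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    cells = prefix.with_suffix(".cells.txt").read_text().splitlines()
    try:
        return CountMatrix(counts=counts, gene_labels=genes, cell_labels=cells)
    except ParameterError as exc:
        raise DataError(str(exc)) from exc
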