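"""Text formats: trajectories, ladders, exchange logs, occupancy, PMF, manifests.

All formats are plain TSV with ``#`` header lines and are stable contracts:
logs produced by external replica-exchange engines can be converted to these
and fed to the diagnostics.  Floats are serialized with ``repr`` (shortest
round-trip form), so write -> read -> write is byte-identical.

Format version: 1.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .ladder import ScalingLadder

FORMAT_VERSION = 1


def _fmt(x) -> str:
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return repr(float(x))


def _read_header(lines):
    meta = {}
    body = []
    for ln in lines:
        if ln.startswith("#"):
            if "=" in ln:
                key, _, val = ln[1:].partition("=")
                meta[key.strip()] = val.strip()
        elif ln.strip():
            body.append(ln)
    return meta, body


def write_trajectory_tsv(path, values, coordinate: str, units: str,
                         time_step: int = 1) -> None:
    """2-column TSV (time index, value); angles are written in degrees."""
    values = np.asarray(values, dtype=float)
    if units == "deg":
        values = np.degrees(values)
    with open(path, "w") as fh:
        fh.write(f"# coordinate = {coordinate}\n# units = {units}\n")
        fh.write(f"# format_version = {FORMAT_VERSION}\n")
        for i, v in enumerate(values):
            fh.write(f"{i * time_step}\t{_fmt(v)}\n")


def read_trajectory_tsv(path):
    """Returns (values, meta); angle values are converted back to radians."""
    meta, body = _read_header(Path(path).read_text().splitlines())
    vals = np.array([float(ln.split("\t")[1]) for ln in body])
    if meta.get("units") == "deg":
        vals = np.radians(vals)
    return vals, meta


def write_ladder_tsv(path, ladder: ScalingLadder, provenance: str = "geometric") -> None:
    """Single-column TSV of scaling factors with n/s_min/provenance metadata."""
    with open(path, "w") as fh:
        fh.write(f"# n = {ladder.n}\n# s_min = {_fmt(ladder.s_min)}\n")
        fh.write(f"# provenance = {provenance}\n")
        fh.write(f"# format_version = {FORMAT_VERSION}\n")
        for s in ladder.s:
            fh.write(f"{_fmt(s)}\n")


def read_ladder_tsv(path):
    meta, body = _read_header(Path(path).read_text().splitlines())
    s = tuple(float(ln) for ln in body)
    return ScalingLadder(s=s), meta


def write_exchange_log_tsv(path, log: dict) -> None:
    """Columns: sweep_index, pair_k (1-based), delta, accepted(0/1), s_k, s_k1."""
    cols = ("sweep", "pair", "delta", "accepted", "s_k", "s_k1")
    n = len(log["sweep"])
    with open(path, "w") as fh:
        fh.write("# columns = sweep_index\tpair_k\tdelta\taccepted\ts_k\ts_k1\n")
        fh.write(f"# format_version = {FORMAT_VERSION}\n")
        for i in range(n):
            fh.write("\t".join((
                str(int(log["sweep"][i])),
                str(int(log["pair"][i]) + 1),
                _fmt(log["delta"][i]),
                str(int(log["accepted"][i])),
                _fmt(log["s_k"][i]),
                _fmt(log["s_k1"][i]),
            )) + "\n")


def read_exchange_log_tsv(path):
    meta, body = _read_header(Path(path).read_text().splitlines())
    rows = [ln.split("\t") for ln in body]
    log = {
        "sweep": np.array([int(r[0]) for r in rows], dtype=np.int64),
        "pair": np.array([int(r[1]) - 1 for r in rows], dtype=np.int64),
        "delta": np.array([float(r[2]) for r in rows]),
        "accepted": np.array([int(r[3]) for r in rows], dtype=np.int64),
        "s_k": np.array([float(r[4]) for r in rows]),
        "s_k1": np.array([float(r[5]) for r in rows]),
    }
    return log, meta


def write_node_occupancy_tsv(path, node_of_replica) -> None:
    """sweep_index followed by the (1-based) node occupied by each replica walker."""
    arr = np.asarray(node_of_replica, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("# columns = sweep_index\t" +
                 "\t".join(f"node_of_replica_{i + 1}" for i in range(arr.shape[1])) + "\n")
        fh.write(f"# format_version = {FORMAT_VERSION}\n")
        for t in range(arr.shape[0]):
            fh.write(str(t) + "\t" + "\t".join(str(int(v) + 1) for v in arr[t]) + "\n")


def read_node_occupancy_tsv(path):
    meta, body = _read_header(Path(path).read_text().splitlines())
    rows = [ln.split("\t") for ln in body]
    arr = np.array([[int(v) - 1 for v in r[1:]] for r in rows], dtype=np.int64)
    return arr, meta


def write_pmf_tsv(path, pmf) -> None:
    """1D: bin center, probability, V_PMF, masked. 2D: long format with both centers."""
    dims = len(pmf.edges)
    with open(path, "w") as fh:
        if dims == 1:
            fh.write("# columns = center\tprobability\tv_pmf\tmasked\n")
            fh.write(f"# format_version = {FORMAT_VERSION}\n")
            (cx,) = pmf.centers
            for i in range(len(cx)):
                v = "NA" if pmf.mask[i] else _fmt(pmf.v[i])
                fh.write(f"{_fmt(cx[i])}\t{_fmt(pmf.p[i])}\t{v}\t{int(pmf.mask[i])}\n")
        else:
            fh.write("# columns = center_x\tcenter_y\tprobability\tv_pmf\tmasked\n")
            fh.write(f"# format_version = {FORMAT_VERSION}\n")
            cx, cy = pmf.centers
            for i in range(len(cx)):
                for j in range(len(cy)):
                    v = "NA" if pmf.mask[i, j] else _fmt(pmf.v[i, j])
                    fh.write(f"{_fmt(cx[i])}\t{_fmt(cy[j])}\t"
                             f"{_fmt(pmf.p[i, j])}\t{v}\t{int(pmf.mask[i, j])}\n")


def write_report_tsv(path, rows, columns) -> None:
    """Small metric report: header + one row per record; NA for missing values."""
    with open(path, "w") as fh:
        fh.write("# columns = " + "\t".join(columns) + "\n")
        fh.write(f"# format_version = {FORMAT_VERSION}\n")
        for row in rows:
            cells = []
            for c in columns:
                v = row.get(c)
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    cells.append("NA")
                elif isinstance(v, (int, np.integer)):
                    cells.append(str(int(v)))
                elif isinstance(v, float):
                    cells.append(_fmt(v))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_report_tsv(path):
    meta, body = _read_header(Path(path).read_text().splitlines())
    columns = meta["columns"].split("\t")
    rows = []
    for ln in body:
        row = {}
        for c, cell in zip(columns, ln.split("\t")):
            if cell == "NA":
                row[c] = math.nan
            else:
                try:
                    row[c] = int(cell)
                except ValueError:
                    try:
                        row[c] = float(cell)
                    except ValueError:
                        row[c] = cell
        rows.append(row)
    return rows, meta


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
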