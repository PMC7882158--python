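"""Plain-text input/output: TSV series, manifests, matrices and reports.

All files are tab-separated text.  A regional-series TSV carries the
subject metadata in ``# key=value`` comment lines followed by one row
per region (first column the region label).  Floats are written with 6
significant digits so byte-level determinism of outputs is auditable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import RegionTimeSeries

__all__ = [
    "write_series_tsv",
    "read_series_tsv",
    "write_manifest",
    "read_manifest",
    "write_matrix_tsv",
    "write_edge_list_tsv",
    "read_motion_trace",
]

FLOAT_FMT = "%.6g"


def write_series_tsv(series: RegionTimeSeries, path) -> Path:
    """Write one subject's regions x time matrix with metadata comments."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# subject_id={series.subject_id}\n")
        fh.write(f"# group={series.group}\n")
        fh.write(f"# tr_seconds={series.tr_seconds:g}\n")
        for rid, row in zip(series.region_ids, series.data):
            vals = "\t".join(FLOAT_FMT % v for v in row)
            fh.write(f"{rid}\t{vals}\n")
    return path


def read_series_tsv(path) -> RegionTimeSeries:
    """Read a series TSV written by :func:`write_series_tsv`."""
    meta: dict[str, str] = {}
    region_ids: list[int] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            region_ids.append(int(parts[0]))
            rows.append([float(v) for v in parts[1:]])
    return RegionTimeSeries(
        subject_id=meta.get("subject_id", Path(path).stem),
        group=meta.get("group", ""),
        data=np.array(rows),
        tr_seconds=float(meta.get("tr_seconds", 2.0)),
        region_ids=region_ids,
    )


def write_manifest(entries: Iterable[Mapping], path) -> Path:
    """Subject manifest TSV: subject_id, group, optional series path."""
    path = Path(path)
    pd.DataFrame(list(entries)).to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix_tsv(matrix: np.ndarray, path, region_ids: Sequence | None = None,
                     header_comment: str | None = None) -> Path:
    """Square connectivity matrix as TSV with region-label row/col headers."""
    matrix = np.asarray(matrix)
    r = matrix.shape[0]
    ids = list(region_ids) if region_ids is not None else list(range(1, r + 1))
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("region\t" + "\t".join(str(i) for i in ids) + "\n")
        for rid, row in zip(ids, matrix):
            vals = "\t".join("nan" if np.isnan(v) else FLOAT_FMT % v for v in row)
            fh.write(f"{rid}\t{vals}\n")
    return path


def write_edge_list_tsv(values: np.ndarray, index: Sequence[tuple], path,
                        header_comment: str | None = None,
                        value_name: str = "value") -> Path:
    """Edge-list TSV: source, target, value."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(f"source\ttarget\t{value_name}\n")
        for (src, tgt), v in zip(index, values):
            fh.write(f"{src}\t{tgt}\t{FLOAT_FMT % v}\n")
    return path


def read_motion_trace(path) -> np.ndarray:
    """Whitespace-delimited motion file: 6 columns, one row per volume."""
    trace = np.loadtxt(path)
    trace = np.atleast_2d(trace)
    if trace.shape[1] != 6:
        raise ValueError(f"expected 6 motion columns, got {trace.shape[1]}")
    return trace
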