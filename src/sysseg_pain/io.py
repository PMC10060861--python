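"""Plain-text readers and writers for the pipeline's artifacts.

ROI time series travel as TSV (one column per parcel, header row of node
labels); motion traces as whitespace-delimited 6-column ``.par`` text in the
MCFLIRT dialect (3 rotations in radians, then 3 translations in mm — a
``translations_first`` switch accepts the other common order); partitions as
two-column TSV (node_label, network); phenotypes and scored tables as CSV.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from .atlas import PartitionAtlas
from .connectivity import MotionTrace, RoiTimeSeries


def write_timeseries_tsv(ts: RoiTimeSeries, path) -> None:
    labels = ts.node_labels or [f"node_{i}" for i in range(ts.n_nodes)]
    pd.DataFrame(ts.values, columns=list(labels)).to_csv(path, sep="\t", index=False)


def read_timeseries(path, tr_seconds: float = 0.8) -> RoiTimeSeries:
    path = pathlib.Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".par"} else ","
    df = pd.read_csv(path, sep=sep)
    return RoiTimeSeries(df.values, tr_seconds=tr_seconds, node_labels=tuple(df.columns))


def write_motion_par(trace: MotionTrace, path) -> None:
    np.savetxt(path, trace.as_matrix(), fmt="%.10g")


def read_motion_par(path, translations_first: bool = False) -> MotionTrace:
    arr = np.atleast_2d(np.loadtxt(path))
    if arr.shape[1] != 6:
        raise ValueError(
            f"{path}: expected 6 whitespace-separated columns "
            "(3 rotations rad, 3 translations mm), got "
            f"{arr.shape[1]}"
        )
    if translations_first:
        return MotionTrace(arr[:, 3:], arr[:, :3])
    return MotionTrace(arr[:, :3], arr[:, 3:])


def write_partition(atlas: PartitionAtlas, path) -> None:
    atlas.to_frame().to_csv(path, sep="\t", index=False)


def read_partition(path) -> PartitionAtlas:
    df = pd.read_csv(path, sep="\t")
    return PartitionAtlas.from_frame(df)
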