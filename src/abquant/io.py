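"""File I/O for the standard interchange formats of the pipeline.

Traces travel as CSV (column 0 = time in seconds, one column per neuron) or
HDF5; movies as multi-page TIFF with a label-image TIFF for the ROI masks;
detected events and session summaries as CSV with the detection configuration
echoed into a comment header for provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidConfigError
from .events import DetectionConfig, TransientEvent
from .traces import Trace


def write_traces_csv(path: str | Path, traces: list[Trace]) -> None:
    if not traces:
        raise InvalidConfigError("no traces to write")
    t = traces[0].times
    data = {"time_s": t}
    for i, tr in enumerate(traces):
        if tr.values.size != t.size:
            raise InvalidConfigError("all traces must share one time grid")
        data[f"neuron_{tr.roi_label if tr.roi_label is not None else i + 1}"] = tr.values
    pd.DataFrame(data).to_csv(path, index=False)


def read_traces_csv(path: str | Path, channel: str = "calcium") -> list[Trace]:
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if t.size < 2:
        raise InvalidConfigError("trace file must contain at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return [
        Trace(df[col].to_numpy(dtype=float), fs, t0=float(t[0]), channel=channel,
              roi_label=i + 1)
        for i, col in enumerate(df.columns[1:])
    ]


def write_traces_hdf5(path: str | Path, traces: list[Trace]) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time_s", data=traces[0].times)
        grp = f.create_group("traces")
        for i, tr in enumerate(traces):
            d = grp.create_dataset(f"neuron_{i + 1}", data=tr.values)
            d.attrs["sampling_rate"] = tr.sampling_rate
            d.attrs["channel"] = tr.channel


def read_traces_hdf5(path: str | Path) -> list[Trace]:
    out = []
    with h5py.File(path, "r") as f:
        grp = f["traces"]
        for name in sorted(grp, key=lambda s: int(s.split("_")[1])):
            d = grp[name]
            out.append(Trace(d[()], float(d.attrs["sampling_rate"]),
                             channel=str(d.attrs["channel"])))
    return out


def write_movie_tiff(path: str | Path, movie: np.ndarray, rois: np.ndarray,
                     roi_path: str | Path | None = None) -> None:
    tifffile.imwrite(path, movie.astype(np.float32))
    if roi_path is None:
        roi_path = Path(path).with_name(Path(path).stem + "_rois.tif")
    tifffile.imwrite(roi_path, rois.astype(np.int32))


def read_movie_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_events_csv(
    path: str | Path,
    events_by_neuron: dict[int, list[TransientEvent]],
    config: DetectionConfig,
) -> None:
    """Events as CSV with the detection config echoed as '#' header lines."""
    lines = [f"# {k} = {v}" for k, v in asdict(config).items()]
    rows = [
        {"neuron_id": nid, "onset_s": e.onset_time, "peak_s": e.peak_time,
         "amplitude": e.peak_amplitude, "area": e.area}
        for nid, evs in events_by_neuron.items() for e in evs
    ]
    df = pd.DataFrame(rows, columns=["neuron_id", "onset_s", "peak_s", "amplitude", "area"])
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")
        df.to_csv(f, index=False)


def read_dose_response_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"dose_nM", "mean", "sem"} - set(df.columns)
    if missing:
        raise InvalidConfigError(f"dose-response CSV lacks columns: {sorted(missing)}")
    return df


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
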