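"""Readers and writers for channel data, sensitivity matrices and
connectivity matrices.

Channel data travels either as a minimal SNIRF-style HDF5 container or
as the documented CSV dialect: one file per wavelength, header row of
channel ids, '.' decimal, UTF-8, plus a JSON sidecar carrying sampling
rate, wavelengths, channel classes and quality flags.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import ChannelTimeSeries
from .rsfc import ConnectivityMatrix


class SchemaError(ValueError):
    """Raised when a file does not match the expected schema."""


def _sidecar(series: ChannelTimeSeries) -> dict:
    return {
        "fs": series.fs,
        "wavelengths": list(series.wavelengths),
        "units": series.units,
        "channel_class": (None if series.channel_class is None
                          else list(map(str, series.channel_class))),
        "channel_array": (None if series.channel_array is None
                          else [int(a) for a in series.channel_array]),
        "bad_channels": [int(i) for i in np.flatnonzero(series.bad_channels)],
        "saturated": [int(i) for i in np.flatnonzero(series.saturated)],
        "removed_timepoints": [int(i) for i in series.removed_timepoints],
    }


def _apply_sidecar(series: ChannelTimeSeries, meta: dict) -> ChannelTimeSeries:
    C = series.n_channels
    if meta.get("channel_class") is not None:
        series.channel_class = np.asarray(meta["channel_class"])
    if meta.get("channel_array") is not None:
        series.channel_array = np.asarray(meta["channel_array"])
    bad = np.zeros(C, dtype=bool)
    bad[meta.get("bad_channels", [])] = True
    series.bad_channels = bad
    sat = np.zeros(C, dtype=bool)
    sat[meta.get("saturated", [])] = True
    series.saturated = sat
    series.removed_timepoints = np.asarray(meta.get("removed_timepoints", []),
                                           dtype=int)
    return series


def write_channels_csv(series: ChannelTimeSeries, prefix: str | Path) -> list[Path]:
    """One CSV per wavelength (``<prefix>_w<nm>.csv``) plus a JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    cols = [f"ch{i:03d}" for i in range(series.n_channels)]
    written = []
    for wi, w in enumerate(series.wavelengths):
        p = prefix.with_name(f"{prefix.name}_w{int(w)}.csv")
        pd.DataFrame(series.data[:, :, wi], columns=cols).to_csv(p, index=False)
        written.append(p)
    side = prefix.with_name(f"{prefix.name}_meta.json")
    side.write_text(json.dumps(_sidecar(series), indent=1))
    written.append(side)
    return written


def read_channels_csv(prefix: str | Path) -> ChannelTimeSeries:
    prefix = Path(prefix)
    side = prefix.with_name(f"{prefix.name}_meta.json")
    if not side.exists():
        raise SchemaError(f"missing sidecar {side}; expected <prefix>_meta.json "
                          "plus <prefix>_w<nm>.csv per wavelength")
    meta = json.loads(side.read_text())
    mats = []
    for w in meta["wavelengths"]:
        p = prefix.with_name(f"{prefix.name}_w{int(w)}.csv")
        df = pd.read_csv(p)
        if not all(c.startswith("ch") for c in df.columns):
            raise SchemaError(f"{p}: header must list channel ids (ch000, ...)")
        mats.append(df.to_numpy())
    data = np.stack(mats, axis=2)
    series = ChannelTimeSeries(data, fs=float(meta["fs"]),
                               wavelengths=tuple(meta["wavelengths"]),
                               units=meta.get("units", "V"))
    return _apply_sidecar(series, meta)


def write_channels_h5(series: ChannelTimeSeries, path: str | Path) -> Path:
    """Minimal SNIRF-style HDF5 container (one data block, stacked
    wavelengths)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    T, C, W = series.data.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0-hbdot")
        nirs = f.create_group("nirs")
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries",
                          data=series.data.reshape(T, C * W))
        d1.create_dataset("time", data=np.arange(T) / series.fs)
        ml_src = np.repeat(np.arange(C), W)
        ml_wl = np.tile(np.arange(W), C)
        d1.create_dataset("measurementChannel", data=ml_src)
        d1.create_dataset("measurementWavelengthIndex", data=ml_wl)
        nirs.create_dataset("probe/wavelengths", data=np.asarray(series.wavelengths))
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SamplingRate", data=series.fs)
        meta.create_dataset("Units", data=series.units)
        meta.create_dataset("sidecar", data=json.dumps(_sidecar(series)))
    return path


def read_channels_h5(path: str | Path) -> ChannelTimeSeries:
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise SchemaError(f"{path}: no /nirs group; not a channel container")
        wl = tuple(float(w) for w in f["nirs/probe/wavelengths"][()])
        fs = float(f["nirs/metaDataTags/SamplingRate"][()])
        units = f["nirs/metaDataTags/Units"][()]
        units = units.decode() if isinstance(units, bytes) else str(units)
        flat = f["nirs/data1/dataTimeSeries"][()]
        meta = json.loads(f["nirs/metaDataTags/sidecar"][()])
    W = len(wl)
    T, CW = flat.shape
    data = flat.reshape(T, CW // W, W)
    series = ChannelTimeSeries(data, fs=fs, wavelengths=wl, units=units)
    return _apply_sidecar(series, meta)


def write_sensitivity_h5(S, path: str | Path) -> Path:
    """Sensitivity container: /S/<wavelength> matrices plus the grid
    (centers in mm, 0-based voxel indexing, origin recorded)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for w, M in S.matrices.items():
            f.create_dataset(f"S/{int(w)}", data=M)
        f.create_dataset("grid/centers", data=S.grid.centers)
        f.create_dataset("grid/voxel_size", data=S.grid.voxel_size)
        f.create_dataset("grid/labels",
                         data=np.array(S.grid.layer, dtype="S"))
        f.create_dataset("grid/compartment",
                         data=np.array(S.grid.compartment, dtype="S"))
        f.create_dataset("grid/array", data=S.grid.array.astype(int))
        f.create_dataset("grid/origin", data=S.grid.centers.min(axis=0))
        f.attrs["kernel"] = S.kernel
        f.attrs["medium_mua"] = S.medium.mua
        f.attrs["medium_mus"] = S.medium.mus
        f.attrs["medium_g"] = S.medium.g
        f.attrs["medium_n"] = S.medium.n
    return path


def read_sensitivity_h5(path: str | Path):
    from .geometry import SensitivityMatrix, TissueOptics, VoxelGrid

    with h5py.File(path, "r") as f:
        mats = {float(w): f[f"S/{w}"][()] for w in f["S"]}
        grid = VoxelGrid(
            centers=f["grid/centers"][()],
            voxel_size=float(f["grid/voxel_size"][()]),
            layer=f["grid/labels"][()].astype(str),
            compartment=f["grid/compartment"][()].astype(str),
            array=f["grid/array"][()],
        )
        medium = TissueOptics(f.attrs["medium_mua"], f.attrs["medium_mus"],
                              f.attrs["medium_g"], f.attrs["medium_n"])
        kernel = f.attrs["kernel"]
    return SensitivityMatrix(mats, grid, layout=None, medium=medium, kernel=kernel)


def write_connectivity_csv(C: ConnectivityMatrix, path: str | Path) -> Path:
    """ROI x ROI matrix CSV with ROI-name header plus a JSON metadata
    sidecar (subject, run, species, available ROIs)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = [f"ROI{int(i):03d}" for i in C.roi_ids]
    pd.DataFrame(C.matrix, index=names, columns=names).to_csv(path)
    meta = dict(C.meta)
    meta["roi_ids"] = [int(i) for i in C.roi_ids]
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_connectivity_csv(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    metapath = path.with_suffix(".json")
    meta = json.loads(metapath.read_text()) if metapath.exists() else {}
    roi_ids = meta.get("roi_ids",
                       [int(c.replace("ROI", "")) for c in df.columns])
    return ConnectivityMatrix(df.to_numpy(), np.asarray(roi_ids, dtype=int),
                              {k: v for k, v in meta.items() if k != "roi_ids"})
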