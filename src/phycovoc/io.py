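"""HDF5 / CSV / YAML persistence for spectra, tables and configs."""

from __future__ import annotations

import json

import h5py
import numpy as np
import yaml

from .spectral import RawSpectrumSeries

__all__ = [
    "write_series_h5",
    "read_series_h5",
    "write_series_csv",
    "load_config",
    "dump_config",
]

_META_ARRAYS = ("h3o_counts",)


def write_series_h5(path, series: RawSpectrumSeries) -> None:
    """Spectrum series layout: /axis, /cycles, /intensity, /meta (attrs +
    per-cycle arrays such as the H3O+ signal)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("axis", data=series.axis)
        f.create_dataset("cycles", data=series.cycles)
        f.create_dataset("intensity", data=series.intensity, compression="gzip")
        meta = f.create_group("meta")
        for key, value in series.meta.items():
            if key in _META_ARRAYS:
                meta.create_dataset(key, data=np.asarray(value, dtype=float))
            elif isinstance(value, (tuple, list)):
                meta.attrs[key] = np.asarray(value, dtype=float)
            else:
                meta.attrs[key] = value


def read_series_h5(path) -> RawSpectrumSeries:
    with h5py.File(path, "r") as f:
        meta = {k: v for k, v in f["meta"].attrs.items()}
        for key in _META_ARRAYS:
            if key in f["meta"]:
                meta[key] = f["meta"][key][...]
        for key, value in list(meta.items()):
            if isinstance(value, np.ndarray) and key != "h3o_counts":
                meta[key] = tuple(value.tolist())
        return RawSpectrumSeries(
            f["axis"][...], f["cycles"][...], f["intensity"][...], meta
        )


def write_series_csv(path, series: RawSpectrumSeries) -> None:
    """Long-format CSV (cycle_s, mz, counts) — for small excerpts only."""
    import pandas as pd

    cyc, mz = np.meshgrid(series.cycles, series.axis, indexing="ij")
    pd.DataFrame(
        {
            "cycle_s": cyc.ravel(),
            "mz": mz.ravel(),
            "counts": series.intensity.ravel(),
        }
    ).to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    import hashlib

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
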