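"""Run output container and persistence.

A :class:`RunOutput` holds the daily-mean series of every ecosystem tracer
plus derived diagnostics (mean size, size variance, growth rate, quota,
NPP, light, carbon-growth curvature), for one run or for a batch of
replicate columns integrated together.  Persistence is NetCDF (classic
format via the scipy backend, with unit attributes per variable and the
run metadata in global attributes) with a tidy per-day CSV mirror.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["RunOutput", "write_run", "read_run", "UNITS"]

#: Unit string for every series a run can carry.
UNITS = {
    "N": "mmol N m-3",
    "P": "mmol N m-3",
    "Z": "mmol N m-3",
    "D": "mmol N m-3",
    "fer": "umol Fe m-3",
    "DETFe": "umol Fe m-3",
    "PM1": "mmol N m-3 ln um3",
    "PM2": "mmol N m-3 (ln um3)2",
    "mean_l": "ln um3",
    "var_v": "(ln um3)2",
    "mu": "d-1",
    "QN": "mol N (mol C)-1",
    "NPP": "mg C m-3 d-1",
    "I": "W m-2",
    "d2muQ": "d-1 (ln um3)-2",
    "species_P": "mmol N m-3",
}

_FORMAT_VERSION = 1


@dataclass
class RunOutput:
    """Daily-mean model output with enough metadata to reproduce the run.

    ``data`` maps variable names to arrays of shape (n_days,) for a single
    run or (n_days, n_replicates) for a batch.  ``time`` is the day index
    (end of day, days since the start of the run).
    """

    time: np.ndarray
    data: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        for name, arr in self.data.items():
            if arr.shape[0] != n:
                raise ValueError(
                    f"series {name!r} has length {arr.shape[0]}, expected {n}"
                )

    @property
    def n_replicates(self) -> int:
        for arr in self.data.values():
            if arr.ndim >= 2:
                return arr.shape[1]
        return 1

    def select(self, replicate: int) -> "RunOutput":
        """Single-replicate view of a batch run."""
        data = {
            k: (v[:, replicate] if v.ndim >= 2 else v) for k, v in self.data.items()
        }
        meta = dict(self.metadata, replicate=int(replicate))
        return RunOutput(self.time, data, meta)

    def to_dataframe(self, replicate: int | None = None) -> pd.DataFrame:
        """Tidy per-day table; batches require choosing a replicate."""
        run = self
        if self.n_replicates > 1:
            if replicate is None:
                raise ValueError(
                    "batch run: pass replicate=<int> to extract a single column"
                )
            run = self.select(replicate)
        cols = {"time": run.time}
        cols.update({k: v for k, v in run.data.items() if v.ndim == 1})
        return pd.DataFrame(cols)

    def to_xarray(self) -> xr.Dataset:
        ds = xr.Dataset()
        ds["time"] = ("time", np.asarray(self.time, dtype=float))
        ds["time"].attrs["units"] = "days since start of run"
        for name, arr in self.data.items():
            if arr.ndim == 1:
                ds[name] = ("time", arr)
            elif arr.ndim == 2:
                ds[name] = (("time", "replicate"), arr)
            else:
                ds[name] = (("time", "replicate", "species"), arr)
            if name in UNITS:
                ds[name].attrs["units"] = UNITS[name]
        ds.attrs["metadata"] = json.dumps(self.metadata, default=str)
        ds.attrs["format_version"] = _FORMAT_VERSION
        return ds

    def final_year(self, days: int = 365) -> "RunOutput":
        """The last ``days`` days of the run (the analysis window)."""
        return RunOutput(
            self.time[-days:],
            {k: v[-days:] for k, v in self.data.items()},
            dict(self.metadata),
        )


def write_run(run: RunOutput, path, csv_path=None) -> None:
    """Persist a run as classic NetCDF; optionally mirror to a tidy CSV."""
    ds = run.to_xarray()
    ds.to_netcdf(path, engine="scipy")
    if csv_path is not None:
        rep = 0 if run.n_replicates > 1 else None
        run.to_dataframe(replicate=rep).to_csv(csv_path, index=False)


def read_run(path) -> RunOutput:
    """Load a run written by :func:`write_run`; truncated files raise cleanly."""
    try:
        with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
            ds = ds.load()
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read run file {path!r}: {exc}") from exc
    version = int(ds.attrs.get("format_version", -1))
    if version != _FORMAT_VERSION:
        import warnings

        warnings.warn(
            f"run file {path!r} has format version {version}, expected "
            f"{_FORMAT_VERSION}; attempting best-effort read",
            stacklevel=2,
        )
    meta = json.loads(ds.attrs.get("metadata", "{}"))
    time = np.asarray(ds["time"].values, dtype=float)
    data = {name: np.asarray(ds[name].values) for name in ds.data_vars if name != "time"}
    return RunOutput(time, data, meta)
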