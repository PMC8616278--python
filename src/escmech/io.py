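"""Plain-text interchange for trajectories and run manifests.

Trajectories travel as two-column delimited text (time_s, position_nm)
with a header line; sampling metadata (rate, bead radius, temperature,
labels) live in a YAML sidecar next to the data file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .errors import DataError
from .microrheology import TrajectoryRecord

__all__ = ["save_trajectory", "load_trajectory"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def save_trajectory(traj: TrajectoryRecord, path) -> None:
    path = Path(path)
    t = np.arange(traj.n_samples) / traj.sampling_rate
    header = "time_s\tposition_nm"
    np.savetxt(path, np.column_stack([t, traj.position_nm]),
               header=header, comments="", delimiter="\t", fmt="%.9g")
    meta = {"sampling_rate_Hz": traj.sampling_rate,
            "bead_radius_nm": traj.bead_radius_nm,
            "temperature_K": traj.temperature_K,
            "condition": traj.condition,
            "location": traj.location}
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def load_trajectory(path) -> TrajectoryRecord:
    path = Path(path)
    data = np.loadtxt(path, skiprows=1, delimiter="\t")
    if data.ndim != 2 or data.shape[1] != 2:
        raise DataError(f"{path}: expected two columns (time_s, position_nm)")
    t, x = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
        raise DataError(f"{path}: non-uniform sampling")
    sidecar = _sidecar(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    else:
        meta = {}
    fs = meta.get("sampling_rate_Hz") or (1.0 / dt[0] if dt.size else None)
    if fs is None:
        raise DataError(f"{path}: cannot determine the sampling rate")
    return TrajectoryRecord(position_nm=x, sampling_rate=float(fs),
                            bead_radius_nm=meta.get("bead_radius_nm"),
                            temperature_K=meta.get("temperature_K") or 310.15,
                            condition=meta.get("condition") or "",
                            location=meta.get("location") or "")
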