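"""File I/O: trajectories, calibration reports, metrics reports.

Tabular outputs are comma-separated text with a fixed column order and a
header row; floats are serialized with 10 significant digits so files
round-trip losslessly at test tolerance.  Every trajectory file carries a
JSON metadata sidecar (``<name>.meta.json``) with the scenario provenance,
seed, substeps and calibration id.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .drivers import DriverSeries
from .model_core import FLUX_NAMES, STOCK_NAMES, EcosystemState, ParameterSet
from .simulator import DIAG_NAMES, SimulationSpec, Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_calibration_report",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.10g"


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as CSV plus a ``.meta.json`` sidecar."""
    path = Path(path)
    traj.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)
    meta = {
        "calibration_id": traj.spec.calibration_id,
        "horizon": traj.spec.horizon,
        "substeps_per_year": traj.spec.substeps_per_year,
        "driver_provenance": traj.spec.drivers.provenance,
        "driver_hash": traj.spec.drivers.provenance_hash(),
        "cumulative": traj.cumulative,
        "params": {k: getattr(traj.params, k) for k in traj.params.__slots__},
        "drivers": {
            k: [float(v) for v in getattr(traj.spec.drivers, k)]
            for k in ("Ca", "T", "Nin", "V")
        },
    }
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    """Re-read a trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    frame = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    drivers = DriverSeries(
        Ca=np.asarray(meta["drivers"]["Ca"]),
        T=np.asarray(meta["drivers"]["T"]),
        Nin=np.asarray(meta["drivers"]["Nin"]),
        V=np.asarray(meta["drivers"]["V"]),
        provenance=meta["driver_provenance"],
    )
    spec = SimulationSpec(
        calibration_id=meta["calibration_id"],
        drivers=drivers,
        horizon=meta["horizon"],
        substeps_per_year=meta["substeps_per_year"],
        initial_state=EcosystemState(*frame.loc[0, list(STOCK_NAMES)].to_numpy()),
    )
    return Trajectory(
        spec=spec,
        params=ParameterSet(**meta["params"]),
        states=frame[list(STOCK_NAMES)].to_numpy(),
        fluxes=frame[list(FLUX_NAMES)].to_numpy(),
        diagnostics=frame[list(DIAG_NAMES)].to_numpy(),
        cumulative=meta["cumulative"],
    )


def write_calibration_report(calibrations: dict, path: str | Path) -> Path:
    """Comparison table of flux partitions and refit parameters across
    calibrations (aggregated / explicit-40 / explicit-100)."""
    rows = []
    order = list(calibrations)
    for name, quantity in [
        ("LitC", "flux"), ("GC", "vole"), ("mCB", "param"),
        ("Rh", "flux"), ("RV", "vole"), ("rD", "param"),
        ("LitN", "flux"), ("GN", "vole"), ("mNB", "param"),
        ("Nmin", "flux"), ("VUN", "vole"), ("mNm", "param"),
    ]:
        row: dict = {"symbol": name, "kind": quantity}
        for cid in order:
            cal = calibrations[cid]
            if quantity == "flux":
                row[cid] = cal.residual_parallel_fluxes[name]
            elif quantity == "vole":
                row[cid] = getattr(cal.vole_partition, name)
            else:
                row[cid] = getattr(cal.params, name)
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return Path(path)
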