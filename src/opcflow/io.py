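"""File formats, configuration schema and run manifests.

Conventions: traces on disk are kPa *gauge* with a seconds time column,
matching how chamber records are plotted; everything in memory is SI
absolute or SI gauge Pa.  The unit conversion happens here and only here.

Trace CSV layout (one channel per file)::

    # sample_rate=800000.0
    # role=static
    # units=kPa_gauge
    # t0=0.0
    # channel_id=specimen_static
    time_s,value
    0.000000e+00,0.000
    ...

The HDF5 mirror stores one dataset per channel with the same metadata as
attributes.  Both round-trip losslessly to float representation.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, ValidationError

from .trace_dx import PressureTrace, TraceRole

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_traces_hdf5", "read_traces_hdf5",
    "write_track_csv", "read_track_csv",
    "GeometryConfig", "BurstConfig", "NumericsConfig", "GasConfig",
    "SphereConfig", "PipelineConfig", "load_config", "ConfigError",
    "RunManifest",
]

_KPA = 1e3


# ---------------------------------------------------------------------------
# trace files

def write_trace_csv(path, trace: PressureTrace) -> None:
    path = Path(path)
    header = (f"# sample_rate={trace.sample_rate!r}\n"
              f"# role={trace.role.value}\n"
              f"# units=kPa_gauge\n"
              f"# t0={trace.t0!r}\n"
              f"# channel_id={trace.channel_id}\n"
              f"time_s,value\n")
    body = "\n".join(
        f"{t:.17e},{v:.17e}"
        for t, v in zip(trace.times, trace.samples / _KPA))
    path.write_text(header + body + "\n")


def read_trace_csv(path) -> PressureTrace:
    path = Path(path)
    meta = {}
    data_lines = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
        elif line and not line.startswith("time_s"):
            data_lines.append(line)
    if meta.get("units", "kPa_gauge") != "kPa_gauge":
        raise ValueError(f"unsupported units {meta.get('units')!r} in {path}")
    arr = np.array([[float(x) for x in ln.split(",")] for ln in data_lines])
    return PressureTrace(
        channel_id=meta.get("channel_id", path.stem),
        role=TraceRole(meta.get("role", "static")),
        samples=arr[:, 1] * _KPA,
        sample_rate=float(meta.get("sample_rate", 8e5)),
        t0=float(meta.get("t0", 0.0)),
    )


def write_traces_hdf5(path, traces: dict) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for name, trace in traces.items():
            ds = f.create_dataset(name, data=trace.samples / _KPA)
            ds.attrs["sample_rate"] = trace.sample_rate
            ds.attrs["role"] = trace.role.value
            ds.attrs["units"] = "kPa_gauge"
            ds.attrs["t0"] = trace.t0
            ds.attrs["channel_id"] = trace.channel_id


def read_traces_hdf5(path) -> dict:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            ds = f[name]
            out[name] = PressureTrace(
                channel_id=str(ds.attrs.get("channel_id", name)),
                role=TraceRole(str(ds.attrs["role"])),
                samples=np.asarray(ds) * _KPA,
                sample_rate=float(ds.attrs["sample_rate"]),
                t0=float(ds.attrs.get("t0", 0.0)),
            )
    return out


# ---------------------------------------------------------------------------
# track files (two-column time/position CSV, frame rate in the header)

def write_track_csv(path, track) -> None:
    path = Path(path)
    header = f"# frame_rate={track.frame_rate!r}\ntime_s,position_m\n"
    body = "\n".join(f"{t:.17e},{x:.17e}"
                     for t, x in zip(track.times, track.positions))
    path.write_text(header + body + "\n")


def read_track_csv(path):
    from .free_flight import TrackRecord

    path = Path(path)
    meta = {}
    rows = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
        elif line and not line.startswith("time_s"):
            rows.append([float(x) for x in line.split(",")])
    arr = np.asarray(rows)
    return TrackRecord(times=arr[:, 0], positions=arr[:, 1],
                       frame_rate=float(meta.get("frame_rate", 0.0) or
                                        1.0 / np.median(np.diff(arr[:, 0]))))


# ---------------------------------------------------------------------------
# configuration schema

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    diameter: float = 0.6
    total_length: float = 1.8
    driver_length: float = 0.20
    aperture_diameter: float = 0.14
    specimen_standoff: float = 0.127
    contraction_length: float = 0.04
    jet_column_length: float = 0.15
    expansion_length: float = 0.10


class BurstConfig(_Strict):
    burst_gauge_pressure: float = 138e3
    petal_duration: float = 3e-4
    bulge_radius: float = 0.07
    opening_profile: str = "linear_ramp"
    shock_fraction: float = 0.10


class NumericsConfig(_Strict):
    n_cells: int = 720
    cfl: float = 0.5
    t_end: float = 60e-3
    spherical_n_cells: int = 1200
    spherical_t_end: float = 2.0e-3


class GasConfig(_Strict):
    gamma: float = 1.4
    R_air: float = 287.05
    p_amb: float = 101_325.0
    T_amb: float = 293.15
    e_TNT: float = 4.184e6


class SphereConfig(_Strict):
    diameter: float = 0.040
    density: float = 1100.0
    drag_coefficient: float = 0.5


class PipelineConfig(_Strict):
    geometry: GeometryConfig = GeometryConfig()
    burst: BurstConfig = BurstConfig()
    numerics: NumericsConfig = NumericsConfig()
    gas: GasConfig = GasConfig()
    sphere: SphereConfig = SphereConfig()
    seed: int = 0

    def geometry_obj(self):
        from .opc_sim import ChamberGeometry

        return ChamberGeometry(**self.geometry.model_dump())

    def burst_obj(self):
        from .opc_sim import BurstModel

        return BurstModel(**self.burst.model_dump())

    def gas_obj(self):
        from .gas_core import GasConstants

        return GasConstants(**self.gas.model_dump())

    def sphere_obj(self):
        from .free_flight import SphereSpec

        return SphereSpec(**self.sphere.model_dump())

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


class ConfigError(ValueError):
    pass


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML pipeline config.

    Unknown keys anywhere in the document raise :class:`ConfigError`
    naming the offending keys.
    """
    import yaml

    data = {}
    if path is not None:
        with open(path) as f:
            data = yaml.safe_load(f) or {}
    if overrides:
        data.update(overrides)
    try:
        return PipelineConfig(**data)
    except ValidationError as exc:
        bad = sorted({".".join(str(p) for p in e["loc"]) for e in exc.errors()})
        raise ConfigError(
            f"invalid configuration keys/values: {', '.join(bad)}") from exc


# ---------------------------------------------------------------------------
# run manifests

@dataclass
class RunManifest:
    """Provenance record written by every CLI run.

    ``config_hash`` is the sha256 of the canonical config JSON; ``outputs``
    maps produced file paths to their sha256 digests, so identical
    config+seed reruns of deterministic stages yield identical digests.
    """

    config_hash: str
    seed: int
    versions: dict
    outputs: dict
    started: str
    finished: str = ""

    @classmethod
    def start(cls, config: PipelineConfig) -> "RunManifest":
        import numpy
        import scipy

        from . import __version__

        return cls(config_hash=config.config_hash, seed=config.seed,
                   versions={"opcflow": __version__,
                             "numpy": numpy.__version__,
                             "scipy": scipy.__version__},
                   outputs={},
                   started=_dt.datetime.now(_dt.timezone.utc).isoformat())

    def add_output(self, path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, path) -> None:
        self.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
        from dataclasses import asdict

        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")
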