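"""CSV serialization and run-configuration parsing.

Trace files are plain CSV with a mandatory header, ``time_min`` as the
first column and one column per channel; metadata travels in ``#
key=value`` comment lines above the header.  Values are written at full
precision (shortest round-tripping decimal) so write -> read reproduces a
TraceSet exactly.  Particle samples are single-column CSV
(``diameter_nm``).  Run configurations are TOML files with sections
``[circuit]``, ``[params]``, ``[geometry]``, ``[simulation]`` and
``[analysis]``.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import (
    CircuitConfig,
    ModelParams,
    TOPOLOGIES,
    build_configuration,
    get_params,
)
from .errors import ConfigurationError
from .traces import TraceSet
from .transport import FilterGeometry, PorositySample

__all__ = [
    "read_traces", "write_traces",
    "read_particles", "write_particles",
    "RunConfig", "parse_config",
]


def _format_meta_value(v: object) -> str:
    return repr(v) if isinstance(v, float) else str(v)


def write_traces(path: str | Path, trace: TraceSet) -> Path:
    """Write a TraceSet as commented-header CSV (full precision)."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in trace.metadata.items():
            fh.write(f"# {key}={_format_meta_value(value)}\n")
        fh.write(",".join(["time_min", *trace.channel_names]) + "\n")
        cols = [trace.times] + [trace.channels[c] for c in trace.channel_names]
        for row in zip(*cols):
            fh.write(",".join(repr(float(x)) for x in row) + "\n")
    return path


def _parse_meta_scalar(s: str) -> object:
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def read_traces(path: str | Path) -> TraceSet:
    """Read a TraceSet written by :func:`write_traces` (or hand-made CSV)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"trace file not found: {path}")
    metadata: dict[str, object] = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, raw = body.partition("=")
                metadata[key.strip()] = _parse_meta_scalar(raw.strip())
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "time_min" not in df.columns:
        raise ConfigurationError(
            f"{path}: first column must be 'time_min', got {list(df.columns)}"
        )
    channels = {c: df[c].to_numpy(dtype=float)
                for c in df.columns if c != "time_min"}
    if not channels:
        raise ConfigurationError(f"{path}: no channel columns found")
    return TraceSet(df["time_min"].to_numpy(dtype=float), channels, metadata)


def write_particles(path: str | Path, sample: PorositySample) -> Path:
    """Write a particle sample as single-column CSV with a stage comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# stage={sample.stage}\n")
        fh.write("diameter_nm\n")
        for d in sample.diameters:
            fh.write(repr(float(d)) + "\n")
    return path


def read_particles(path: str | Path, stage: str | None = None) -> PorositySample:
    """Read a particle-diameter CSV; stage comes from the file or the caller."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"particle file not found: {path}")
    file_stage = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if body.startswith("stage="):
                file_stage = body.split("=", 1)[1].strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "diameter_nm" not in df.columns:
        raise ConfigurationError(
            f"{path}: expected a 'diameter_nm' column, got {list(df.columns)}"
        )
    return PorositySample(df["diameter_nm"].to_numpy(dtype=float),
                          stage=stage or file_stage or "pre_filter")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CIRCUIT_FLAG_KEYS = {"has_luxI", "has_aiiA", "has_reporter", "driver",
                      "induction_time"}
_SIM_DEFAULTS = {"t_end": 1800.0, "dt": 0.05, "record_every": 1.0,
                 "seed": 0, "noise": False,
                 "sigma_rel": 0.05, "sigma_abs": 0.5}
_ANALYSIS_DEFAULTS = {"interval": 3.0, "min_prominence_frac": 0.2,
                      "min_separation": 15.0, "transient_min": 300.0}


@dataclass
class RunConfig:
    """Everything one pipeline run needs, resolved and validated up front."""

    circuit: CircuitConfig
    params: ModelParams
    geometry: FilterGeometry = field(default_factory=FilterGeometry)
    t_end: float = 1800.0
    dt: float = 0.05
    record_every: float = 1.0
    seed: int = 0
    noise: bool = False
    sigma_rel: float = 0.05
    sigma_abs: float = 0.5
    interval: float = 3.0
    min_prominence_frac: float = 0.2
    min_separation: float = 15.0
    transient_min: float = 300.0
    output_dir: Path = Path("luxlink-out")


def _reject_unknown(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in [{section}]: {', '.join(sorted(unknown))}"
        )


def parse_config(path: str | Path) -> RunConfig:
    """Parse a TOML run configuration, filling every documented default."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigurationError(f"config syntax error in {path}: {exc}") from exc

    _reject_unknown("<top level>", raw,
                    {"circuit", "params", "geometry", "simulation",
                     "analysis", "output_dir"})

    # --- circuit -----------------------------------------------------------
    circ_raw = dict(raw.get("circuit", {}))
    _reject_unknown("circuit", circ_raw,
                    {"topology", "coupling_enabled", "sender", "receiver"})
    topology = circ_raw.get("topology", "OSC_A")
    if topology not in TOPOLOGIES:
        raise ConfigurationError(
            f"unknown topology {topology!r}; valid: {sorted(TOPOLOGIES)}"
        )
    circuit = build_configuration(topology)
    overrides = {}
    if "coupling_enabled" in circ_raw:
        overrides["coupling_enabled"] = bool(circ_raw["coupling_enabled"])
    for pop in ("sender", "receiver"):
        pop_raw = dict(circ_raw.get(pop, {}))
        _reject_unknown(f"circuit.{pop}", pop_raw, _CIRCUIT_FLAG_KEYS)
        if pop_raw:
            overrides[pop] = dataclasses.replace(
                getattr(circuit, pop), **pop_raw
            )
    if overrides:
        circuit = dataclasses.replace(circuit, name=f"{topology}*", **overrides)

    # --- params ------------------------------------------------------------
    par_raw = dict(raw.get("params", {}))
    param_fields = {f.name for f in dataclasses.fields(ModelParams)} - {"name"}
    _reject_unknown("params", par_raw, param_fields | {"set"})
    params = get_params(par_raw.pop("set", "default-v1"))
    if par_raw:
        params = params.replace(name=f"{params.name}*", **par_raw)

    # --- geometry ----------------------------------------------------------
    geo_raw = dict(raw.get("geometry", {}))
    geo_fields = {f.name for f in dataclasses.fields(FilterGeometry)}
    _reject_unknown("geometry", geo_raw, geo_fields)
    geometry = FilterGeometry(**geo_raw)

    # --- simulation / analysis --------------------------------------------
    sim_raw = dict(raw.get("simulation", {}))
    _reject_unknown("simulation", sim_raw, set(_SIM_DEFAULTS))
    sim = {**_SIM_DEFAULTS, **sim_raw}
    ana_raw = dict(raw.get("analysis", {}))
    _reject_unknown("analysis", ana_raw, set(_ANALYSIS_DEFAULTS))
    ana = {**_ANALYSIS_DEFAULTS, **ana_raw}

    return RunConfig(
        circuit=circuit,
        params=params,
        geometry=geometry,
        t_end=float(sim["t_end"]),
        dt=float(sim["dt"]),
        record_every=float(sim["record_every"]),
        seed=int(sim["seed"]),
        noise=bool(sim["noise"]),
        sigma_rel=float(sim["sigma_rel"]),
        sigma_abs=float(sim["sigma_abs"]),
        interval=float(ana["interval"]),
        min_prominence_frac=float(ana["min_prominence_frac"]),
        min_separation=float(ana["min_separation"]),
        transient_min=float(ana["transient_min"]),
        output_dir=Path(raw.get("output_dir", "luxlink-out")),
    )
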