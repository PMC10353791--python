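"""Configuration and result serialisation.

Model configurations round-trip through a versioned YAML schema; traces go
to CSV (one row per sample, per-compartment voltage and calcium columns and
optional per-channel current columns); experiment results go to CSV/JSON
next to a run manifest that records the subcommand, seed, and versions
needed to reproduce the run.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from condpop.channels import ChannelSpec, GateSpec
from condpop.features import FeatureTargets
from condpop.model import (
    CalciumPoolSpec,
    CompartmentSpec,
    NeuronConfig,
    VoltageTrace,
)

SCHEMA_VERSION = 1

_GATE_KEYS = {
    "role", "exponent", "v_half", "slope", "tau_base", "tau_amp",
    "tau_v_half", "tau_sigma", "ca_half", "hill_coeff",
}
_CHANNEL_KEYS = {"name", "ion", "reversal", "gates", "feeds_ca_pool", "regions"}
_COMP_KEYS = {"name", "area", "capacitance", "parent", "axial_conductance_to_parent"}
_POOL_KEYS = {"influx_factor", "tau_removal", "ca_rest"}
_TOP_KEYS = {"schema_version", "compartments", "channels", "ca_pool", "conductance_table", "frozen_channels"}


class ConfigError(ValueError):
    pass


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown keys {sorted(unknown)} in {where}")


def config_to_dict(config: NeuronConfig) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "compartments": [asdict(c) for c in config.compartments],
        "channels": [
            {
                "name": ch.name,
                "ion": ch.ion,
                "reversal": ch.reversal,
                "feeds_ca_pool": ch.feeds_ca_pool,
                "regions": list(ch.regions),
                "gates": [asdict(g) for g in ch.gates],
            }
            for ch in config.channels
        ],
        "ca_pool": asdict(config.ca_pool),
        "conductance_table": [
            {"channel": k[0], "region": k[1], "density": v}
            for k, v in sorted(config.conductance_table.items())
        ],
        "frozen_channels": sorted(config.frozen_channels),
    }


def config_from_dict(data: dict) -> NeuronConfig:
    _check_keys(data, _TOP_KEYS, "model config")
    if data.get("schema_version") != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {data.get('schema_version')!r}")
    comps = []
    for c in data["compartments"]:
        _check_keys(c, _COMP_KEYS, "compartment")
        comps.append(CompartmentSpec(**c))
    channels = []
    for ch in data["channels"]:
        _check_keys(ch, _CHANNEL_KEYS, f"channel {ch.get('name')!r}")
        gates = []
        for g in ch.get("gates", []):
            _check_keys(g, _GATE_KEYS, "gate")
            gates.append(GateSpec(**g))
        channels.append(
            ChannelSpec(
                name=ch["name"],
                ion=ch["ion"],
                reversal=ch["reversal"],
                gates=tuple(gates),
                feeds_ca_pool=ch.get("feeds_ca_pool", False),
                regions=tuple(ch.get("regions", ("soma",))),
            )
        )
    pool = data.get("ca_pool", {})
    _check_keys(pool, _POOL_KEYS, "ca_pool")
    table = {
        (e["channel"], e["region"]): float(e["density"])
        for e in data["conductance_table"]
    }
    return NeuronConfig(
        compartments=tuple(comps),
        channels=tuple(channels),
        ca_pool=CalciumPoolSpec(**pool),
        conductance_table=table,
        frozen_channels=frozenset(data.get("frozen_channels", ("pas", "Kir21"))),
    )


def read_config(path: str | Path) -> NeuronConfig:
    """Read and validate a model configuration file (YAML/JSON dialect)."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    return config_from_dict(data)


def write_config(config: NeuronConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


# -- targets ----------------------------------------------------------------

def targets_to_frame(targets: FeatureTargets) -> pd.DataFrame:
    rows = [
        {"amplitude_pa": amp, "feature": name, "mean": m, "sd": s}
        for (amp, name), (m, s) in sorted(targets.entries.items())
    ]
    return pd.DataFrame(rows)


def targets_from_frame(df: pd.DataFrame, floors=None) -> FeatureTargets:
    entries = {
        (float(r.amplitude_pa), str(r.feature)): (float(r.mean), float(r.sd))
        for r in df.itertuples()
    }
    kwargs = {"floors": floors} if floors is not None else {}
    return FeatureTargets(entries=entries, **kwargs)


# -- traces -----------------------------------------------------------------

def trace_to_frame(trace: VoltageTrace) -> pd.DataFrame:
    cols = {"time_ms": trace.time_ms}
    for name, v in trace.vm.items():
        cols[f"Vm_{name}"] = v
    for name, c in trace.ca.items():
        cols[f"Ca_{name}"] = c
    if trace.currents is not None:
        for name, i in trace.currents.items():
            cols[f"I_{name}"] = i
    return pd.DataFrame(cols)


def write_trace_csv(trace: VoltageTrace, path: str | Path) -> None:
    trace_to_frame(trace).to_csv(path, index=False, float_format="%.12g")


# -- run manifests ----------------------------------------------------------

@dataclass
class RunManifest:
    subcommand: str
    seed: int
    arguments: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION
    package_version: str = "0.1.0"
    wall_time_s: float = 0.0
    n_evaluations: int = 0


def write_results(outdir: str | Path, manifest: RunManifest, **artifacts) -> list[Path]:
    """Write result artifacts plus exactly one manifest into ``outdir``.

    ``artifacts`` maps stem names to DataFrames (written as CSV) or
    JSON-serialisable objects (written as JSON).  Numeric CSV formatting
    keeps 12 significant digits.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for stem, obj in artifacts.items():
        if obj is None:
            continue
        if isinstance(obj, pd.DataFrame):
            p = outdir / f"{stem}.csv"
            obj.to_csv(p, index=False, float_format="%.12g")
        else:
            p = outdir / f"{stem}.json"
            with open(p, "w") as fh:
                json.dump(obj, fh, indent=2, default=_json_default)
        written.append(p)
    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(asdict(manifest), fh, indent=2)
    written.append(mpath)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


class Stopwatch:
    def __init__(self):
        self.t0 = time.time()

    @property
    def elapsed(self) -> float:
        return time.time() - self.t0


__all__ = [
    "SCHEMA_VERSION",
    "ConfigError",
    "config_to_dict",
    "config_from_dict",
    "read_config",
    "write_config",
    "targets_to_frame",
    "targets_from_frame",
    "trace_to_frame",
    "write_trace_csv",
    "RunManifest",
    "write_results",
    "Stopwatch",
]
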