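"""Neuron model configuration: compartments, conductance tables, traces.

A :class:`NeuronConfig` bundles a small tree of isopotential compartments
(soma, AIS, dendrite), a roster of :class:`~condpop.channels.ChannelSpec`
channels, a calcium pool per compartment, and a region-resolved conductance
table in mS/cm².  The sampled parameter subset (every table entry whose
channel is not in the frozen passive backbone) is exposed as an ordered
:class:`ParameterVector`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from condpop.channels import ChannelSpec, make_isoform as _make_channel_isoform

#: Pseudo-region meaning "every compartment"; counts as one table entry.
REGION_ALL = "all"


@dataclass(frozen=True)
class CompartmentSpec:
    name: str
    area: float  # cm²
    capacitance: float = 1.0  # µF/cm²
    parent: str | None = None
    axial_conductance_to_parent: float = 0.0  # µS

    def __post_init__(self) -> None:
        if self.area <= 0.0:
            raise ValueError("compartment area must be positive")
        if self.capacitance <= 0.0:
            raise ValueError("compartment capacitance must be positive")


@dataclass(frozen=True)
class CalciumPoolSpec:
    """First-order intracellular calcium pool, one per compartment.

    d[Ca]/dt = -influx_factor · I_Ca + (ca_rest - [Ca]) / tau_removal,
    with I_Ca in nA (inward negative, hence the sign).
    """

    influx_factor: float = 0.1  # µM per nA·ms
    tau_removal: float = 15.0  # ms
    ca_rest: float = 0.05  # µM

    def __post_init__(self) -> None:
        if self.tau_removal <= 0.0 or self.ca_rest <= 0.0:
            raise ValueError("calcium pool requires tau_removal > 0 and ca_rest > 0")


@dataclass(frozen=True)
class StimulusProtocol:
    """Somatic current-clamp step: pre / step / post segments."""

    amplitude: float  # pA
    pre_ms: float = 50.0
    step_ms: float = 200.0
    post_ms: float = 50.0
    site: str = "soma"


@dataclass(frozen=True)
class SolverOptions:
    dt: float = 0.025  # ms
    settle_ms: float = 500.0  # unstimulated settle-in defining Vrest
    record_currents: bool = False
    #: early settle exit once max |dV/dt| over a 20 ms window drops below this
    settle_tol: float = 1e-4  # mV/ms

    def __post_init__(self) -> None:
        if not (0.0 < self.dt <= 0.1):
            raise ValueError("solver dt must be in (0, 0.1] ms")


class ParameterVector(dict):
    """Ordered mapping (channel, region) → density in mS/cm²."""

    def as_array(self, keys: list[tuple[str, str]]) -> np.ndarray:
        return np.array([self[k] for k in keys], dtype=float)

    @classmethod
    def from_array(cls, keys: list[tuple[str, str]], values: np.ndarray) -> "ParameterVector":
        return cls(zip(keys, np.asarray(values, dtype=float)))


@dataclass(frozen=True)
class NeuronConfig:
    compartments: tuple[CompartmentSpec, ...]
    channels: tuple[ChannelSpec, ...]
    ca_pool: CalciumPoolSpec
    conductance_table: dict[tuple[str, str], float]
    frozen_channels: frozenset[str] = frozenset({"pas", "Kir21"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "compartments", tuple(self.compartments))
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "frozen_channels", frozenset(self.frozen_channels))
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique within one model")
        comp_names = {c.name for c in self.compartments}
        roots = [c for c in self.compartments if c.parent is None]
        if len(roots) != 1 or roots[0].name != "soma":
            raise ValueError("exactly one root compartment named 'soma' is required")
        for c in self.compartments:
            if c.parent is not None and c.parent not in comp_names:
                raise ValueError(f"compartment {c.name} has unknown parent {c.parent}")
        chan_by_name = {c.name: c for c in self.channels}
        for (chan, region), dens in self.conductance_table.items():
            if chan not in chan_by_name:
                raise ValueError(f"conductance table names unknown channel {chan!r}")
            if region != REGION_ALL and region not in comp_names:
                raise ValueError(f"conductance table names unknown region {region!r}")
            if dens < 0.0:
                raise ValueError(f"negative density for ({chan}, {region})")

    # ---- parameter bookkeeping -------------------------------------------

    def channel(self, name: str) -> ChannelSpec:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def parameter_keys(self) -> list[tuple[str, str]]:
        """All (channel, region) table entries, in roster order."""
        order = {c.name: i for i, c in enumerate(self.channels)}
        return sorted(self.conductance_table, key=lambda k: (order[k[0]], k[1]))

    @property
    def free_keys(self) -> list[tuple[str, str]]:
        """Sampled (non-frozen) table entries, in roster order."""
        return [k for k in self.parameter_keys if k[0] not in self.frozen_channels]

    def extract_vector(self) -> ParameterVector:
        return ParameterVector((k, self.conductance_table[k]) for k in self.free_keys)

    def free_array(self) -> np.ndarray:
        return np.array([self.conductance_table[k] for k in self.free_keys], dtype=float)

    def with_free_array(self, values: np.ndarray) -> "NeuronConfig":
        keys = self.free_keys
        values = np.asarray(values, dtype=float)
        if values.shape != (len(keys),):
            raise ValueError(f"expected {len(keys)} free parameters, got shape {values.shape}")
        table = dict(self.conductance_table)
        for k, v in zip(keys, values):
            table[k] = float(v)
        return replace(self, conductance_table=table)

    def region_compartments(self, region: str) -> list[str]:
        if region == REGION_ALL:
            return [c.name for c in self.compartments]
        return [region]


def apply_parameters(config: NeuronConfig, vector: ParameterVector) -> NeuronConfig:
    """Return ``config`` with the listed free densities replaced.

    Frozen entries (the pas/Kir21 passive backbone by default) and entries
    absent from ``vector`` are untouched; naming a frozen or unknown key is
    an error.
    """
    table = dict(config.conductance_table)
    for key, value in vector.items():
        chan, region = key
        if key not in table:
            raise KeyError(f"unknown parameter key {key}")
        if chan in config.frozen_channels:
            raise ValueError(f"parameter key {key} is frozen")
        if value < 0.0:
            raise ValueError(f"negative density for {key}")
        table[key] = float(value)
    return replace(config, conductance_table=table)


def add_isoform(
    config: NeuronConfig,
    parent_channel: str,
    rng: np.random.Generator | int,
    name: str | None = None,
    density_scale: float = 1.0,
) -> NeuronConfig:
    """Add a randomised isoform of ``parent_channel`` to the roster.

    The isoform inherits the parent's regions; its initial densities are the
    parent's baseline densities scaled by ``density_scale``.
    """
    parent = config.channel(parent_channel)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    existing = {c.name for c in config.channels}
    if name is None:
        i = 1
        while f"{parent_channel}_iso{i}" in existing:
            i += 1
        name = f"{parent_channel}_iso{i}"
    iso = _make_channel_isoform(parent, rng, name=name)
    table = dict(config.conductance_table)
    for (chan, region), dens in config.conductance_table.items():
        if chan == parent_channel:
            table[(name, region)] = dens * density_scale
    return replace(config, channels=config.channels + (iso,), conductance_table=table)


@dataclass
class VoltageTrace:
    """Result of one current-clamp simulation.

    All series share one time base of ``n`` samples at spacing ``dt`` starting
    at the beginning of the protocol (after the settle-in); feature timings
    are measured from ``stim_onset_ms``.
    """

    dt: float  # ms
    vm: dict[str, np.ndarray]  # mV per compartment
    ca: dict[str, np.ndarray]  # µM per compartment
    protocol: StimulusProtocol
    vrest: float  # mV, settled pre-stimulus somatic potential
    currents: dict[str, np.ndarray] | None = None  # nA per channel (cell total)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.vm.values())))

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    @property
    def stim_onset_ms(self) -> float:
        return self.protocol.pre_ms

    @property
    def stim_onset_index(self) -> int:
        return int(round(self.protocol.pre_ms / self.dt))

    @property
    def soma_vm(self) -> np.ndarray:
        return self.vm["soma"]


__all__ = [
    "REGION_ALL",
    "CompartmentSpec",
    "CalciumPoolSpec",
    "StimulusProtocol",
    "SolverOptions",
    "ParameterVector",
    "NeuronConfig",
    "VoltageTrace",
    "apply_parameters",
    "add_isoform",
]

# re-export for the package surface
make_isoform = _make_channel_isoform
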