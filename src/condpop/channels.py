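"""Parameterised surrogate ion-channel kinetics.

Each channel is a product of independent gating variables.  Voltage-dependent
gates follow a Boltzmann steady state with a Gaussian-bell voltage-dependent
time constant; calcium-dependent gates follow a Hill steady state with a
fixed time constant.  These are deliberately generic Hodgkin–Huxley-style
parameterisations: the channel *names* mirror the granule-cell roster
(pas, Kir21, na8st, Kv…, BK, SK, Cav…) but the kinetic constants are
engineering surrogates, not fits to the published mechanisms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: Lower bound on every gate time constant (ms); bounds stiffness of the ODEs.
TAU_MIN = 0.05

ROLE_ACTIVATION = "activation"
ROLE_INACTIVATION = "inactivation"
ROLE_CALCIUM = "calcium_activation"

_ROLES = (ROLE_ACTIVATION, ROLE_INACTIVATION, ROLE_CALCIUM)
_IONS = ("Na", "K", "Ca", "leak")


@dataclass(frozen=True)
class GateSpec:
    """One gating variable of a channel.

    Voltage gates: steady state ``1 / (1 + exp(-(V - v_half)/slope))`` with a
    signed slope (negative slope → gate opens with hyperpolarisation, as for
    inactivation or inward rectification) and time constant
    ``tau_base + tau_amp * exp(-((V - tau_v_half)/tau_sigma)^2)`` floored at
    :data:`TAU_MIN`.

    Calcium gates: steady state ``ca^h / (ca^h + ca_half^h)`` with constant
    time constant ``tau_base``.
    """

    role: str
    exponent: int = 1
    v_half: float = -40.0  # mV
    slope: float = 5.0  # mV, signed, nonzero
    tau_base: float = 1.0  # ms
    tau_amp: float = 0.0  # ms
    tau_v_half: float = -40.0  # mV
    tau_sigma: float = 15.0  # mV, > 0
    ca_half: float = 1.0  # µM (calcium gates)
    hill_coeff: float = 2.0  # unitless (calcium gates)

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown gate role {self.role!r}")
        if self.exponent < 0:
            raise ValueError("gate exponent must be non-negative")
        if self.role != ROLE_CALCIUM and self.slope == 0.0:
            raise ValueError("voltage gate slope must be nonzero")
        if self.tau_sigma <= 0.0:
            raise ValueError("tau_sigma must be positive")
        if self.role == ROLE_CALCIUM and (self.ca_half <= 0.0 or self.hill_coeff <= 0.0):
            raise ValueError("calcium gate requires ca_half > 0 and hill_coeff > 0")


@dataclass(frozen=True)
class ChannelSpec:
    """A channel type: an ion, a reversal potential and a product of gates."""

    name: str
    ion: str
    reversal: float  # mV
    gates: tuple[GateSpec, ...] = field(default_factory=tuple)
    feeds_ca_pool: bool = False
    regions: tuple[str, ...] = ("soma",)

    def __post_init__(self) -> None:
        if self.ion not in _IONS:
            raise ValueError(f"unknown ion {self.ion!r}")
        if self.feeds_ca_pool and self.ion != "Ca":
            raise ValueError("feeds_ca_pool requires ion == 'Ca'")
        object.__setattr__(self, "gates", tuple(self.gates))
        object.__setattr__(self, "regions", tuple(self.regions))

    @property
    def has_calcium_gate(self) -> bool:
        return any(g.role == ROLE_CALCIUM for g in self.gates)


def gate_steady_state(gate: GateSpec, vm: float, ca: float | None = None) -> float:
    """Steady-state open fraction of one gate at membrane potential ``vm`` (mV).

    ``ca`` (µM) must be given for — and only matters for — calcium gates.
    """
    if gate.role == ROLE_CALCIUM:
        if ca is None:
            raise ValueError("calcium-activated gate evaluated without calcium concentration")
        if ca <= 0.0:
            return 0.0
        r = (ca / gate.ca_half) ** gate.hill_coeff
        return r / (1.0 + r)
    # Boltzmann; clip the exponent to keep the tails exact 0/1 instead of overflowing
    x = -(vm - gate.v_half) / gate.slope
    if x > 500.0:
        return 0.0
    if x < -500.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(x))


def gate_time_constant(gate: GateSpec, vm: float) -> float:
    """Gate time constant (ms) at ``vm``; calcium gates are voltage independent."""
    if gate.role == ROLE_CALCIUM:
        return max(TAU_MIN, gate.tau_base)
    z = (vm - gate.tau_v_half) / gate.tau_sigma
    bell = math.exp(-(z * z)) if abs(z) < 30.0 else 0.0
    return max(TAU_MIN, gate.tau_base + gate.tau_amp * bell)


def channel_open_fraction(channel: ChannelSpec, vm: float, ca: float | None = None) -> float:
    """Steady-state open probability of the whole channel (product of gates)."""
    p = 1.0
    for g in channel.gates:
        p *= gate_steady_state(g, vm, ca) ** g.exponent
    return p


def make_isoform(channel: ChannelSpec, rng: np.random.Generator | int, name: str | None = None) -> ChannelSpec:
    """Create an artificial isoform of ``channel`` with randomised dynamics.

    Every gate time-constant parameter (``tau_base`` and ``tau_amp``) is
    multiplied by an independent uniform factor on [0, 2); steady-state
    parameters, ion and reversal are untouched, so the isoform differs from
    its parent only in how fast its gates move.
    """
    if not channel.gates:
        raise ValueError("channel has no gates to randomise")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    new_gates = []
    for g in channel.gates:
        fb = rng.uniform(0.0, 2.0)
        fa = rng.uniform(0.0, 2.0)
        new_gates.append(replace(g, tau_base=g.tau_base * fb, tau_amp=g.tau_amp * fa))
    if name is None:
        name = f"{channel.name}_iso{rng.integers(0, 10**9)}"
    return replace(channel, name=name, gates=tuple(new_gates))
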