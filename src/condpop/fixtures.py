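"""Synthetic fixtures: baseline surrogate models, targets, ground-truth traces.

The study's original inputs — a published 15-channel granule-cell model with
a reconstructed morphology, and unpublished experimental spike-feature
statistics — are emulated here by self-contained surrogates:

* :func:`make_baseline_models` builds three few-compartment conductance-based
  models (``gc5``/``gc9``/``gc15``) sharing a passive backbone, whose channel
  rosters mirror the granule-cell roster and whose region-resolved parameter
  counts are 9, 13 and 27.  The kinetic constants are engineering defaults
  tuned so each baseline rests near −80 mV and fires a handful of spikes at
  90 pA; they are surrogates, not published channel fits.
* :func:`generate_feature_targets` turns a reference simulation into
  experimental-style targets (mean per feature, SD = fraction of the mean
  with per-feature floors).
* :func:`synth_trace` builds piecewise-linear voltage traces with exactly
  known spike times, amplitudes, half-widths and fAHP depths — ground truth
  for the feature-extraction tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from condpop.channels import ChannelSpec, GateSpec
from condpop.engine import run_protocols
from condpop.features import DEFAULT_SD_FLOORS, FeatureTargets, extract_features
from condpop.model import (
    REGION_ALL,
    CalciumPoolSpec,
    CompartmentSpec,
    NeuronConfig,
    SolverOptions,
    StimulusProtocol,
    VoltageTrace,
)

E_NA = 60.0
E_K = -90.0
E_CA = 120.0
E_PAS = -78.0

GC5_ROSTER = ("pas", "Kir21", "na8st", "BK", "Cav22")
GC9_ROSTER = GC5_ROSTER + ("Kv21", "Kv34", "Kv42", "Kv723")
GC15_ROSTER = GC9_ROSTER + ("Kv11", "Kv14", "SK", "Cav12", "Cav13", "Cav32")


def _act(vh, k, tb, ta, tvh, ts, exp=1):
    return GateSpec("activation", exponent=exp, v_half=vh, slope=k,
                    tau_base=tb, tau_amp=ta, tau_v_half=tvh, tau_sigma=ts)


def _inact(vh, k, tb, ta, tvh, ts, exp=1):
    return GateSpec("inactivation", exponent=exp, v_half=vh, slope=k,
                    tau_base=tb, tau_amp=ta, tau_v_half=tvh, tau_sigma=ts)


def _cagate(kd, hill, tau, exp=1):
    return GateSpec("calcium_activation", exponent=exp, ca_half=kd,
                    hill_coeff=hill, tau_base=tau)


def channel_library() -> dict[str, ChannelSpec]:
    """Surrogate kinetics for the full 15-channel roster.

    Channels within a functional class (fast repolarising K, Ca influx) have
    deliberately overlapping but non-identical kinetics, so that they can
    substitute for one another — the degeneracy the population analyses
    quantify.
    """
    lib = {
        "pas": ChannelSpec("pas", "leak", E_PAS, (), regions=(REGION_ALL,)),
        "Kir21": ChannelSpec(
            "Kir21", "K", E_K,
            (_act(-75.0, -6.0, 1.0, 0.0, -80.0, 15.0),),
            regions=(REGION_ALL,),
        ),
        "na8st": ChannelSpec(
            "na8st", "Na", E_NA,
            (
                _act(-38.0, 5.5, 0.05, 0.10, -40.0, 18.0, exp=3),
                _inact(-50.0, -6.0, 0.8, 5.0, -55.0, 14.0),
            ),
            regions=("soma", "AIS"),
        ),
        # --- calcium-activated K class (repolarisation + AHP) -------------
        "BK": ChannelSpec(
            "BK", "K", E_K,
            (
                _act(-30.0, 10.0, 0.2, 0.3, -30.0, 20.0),
                _cagate(0.5, 2.0, 1.5),
            ),
            regions=("soma", "AIS"),
        ),
        "SK": ChannelSpec(
            "SK", "K", E_K,
            (
                _act(-32.0, 11.0, 0.4, 0.6, -30.0, 20.0),
                _cagate(0.55, 2.0, 3.0),
            ),
            regions=("soma", "AIS", "dendrite"),
        ),
        # --- voltage-gated K class: shared steady state, kinetic variants --
        "Kv21": ChannelSpec(
            "Kv21", "K", E_K,
            (_act(-30.0, 9.0, 0.5, 1.5, -35.0, 20.0, exp=2),),
            regions=("soma",),
        ),
        "Kv34": ChannelSpec(
            "Kv34", "K", E_K,
            (_act(-30.0, 9.0, 0.3, 1.0, -35.0, 20.0, exp=2),),
            regions=("AIS",),
        ),
        "Kv42": ChannelSpec(
            "Kv42", "K", E_K,
            (_act(-30.0, 9.0, 0.7, 2.0, -35.0, 20.0, exp=2),),
            regions=("soma",),
        ),
        "Kv723": ChannelSpec(
            "Kv723", "K", E_K,
            (_act(-30.0, 9.0, 1.0, 3.0, -35.0, 20.0, exp=2),),
            regions=("AIS",),
        ),
        "Kv11": ChannelSpec(
            "Kv11", "K", E_K,
            (_act(-30.0, 9.0, 0.4, 1.2, -35.0, 20.0, exp=2),),
            regions=("soma", "AIS"),
        ),
        "Kv14": ChannelSpec(
            "Kv14", "K", E_K,
            (_act(-30.0, 9.0, 0.8, 2.5, -35.0, 20.0, exp=2),),
            regions=("soma", "AIS"),
        ),
        # --- high-threshold Ca class: shared steady state, kinetic variants
        "Cav22": ChannelSpec(
            "Cav22", "Ca", E_CA,
            (_act(-5.0, 5.0, 0.3, 0.8, -20.0, 18.0, exp=2),),
            feeds_ca_pool=True,
            regions=("soma", "AIS", "dendrite"),
        ),
        "Cav12": ChannelSpec(
            "Cav12", "Ca", E_CA,
            (_act(-5.0, 5.0, 0.4, 1.0, -20.0, 18.0, exp=2),),
            feeds_ca_pool=True,
            regions=("soma", "dendrite"),
        ),
        "Cav13": ChannelSpec(
            "Cav13", "Ca", E_CA,
            (_act(-5.0, 5.0, 0.6, 1.5, -20.0, 18.0, exp=2),),
            feeds_ca_pool=True,
            regions=("soma", "dendrite"),
        ),
        "Cav32": ChannelSpec(
            "Cav32", "Ca", E_CA,
            (_act(-5.0, 5.0, 0.8, 2.0, -20.0, 18.0, exp=2),),
            feeds_ca_pool=True,
            regions=("soma", "AIS", "dendrite"),
        ),
    }
    return lib


def _compartments() -> tuple[CompartmentSpec, ...]:
    return (
        CompartmentSpec("soma", area=2.5e-5, capacitance=1.0),
        CompartmentSpec("AIS", area=2.5e-6, capacitance=1.0,
                        parent="soma", axial_conductance_to_parent=0.05),
        CompartmentSpec("dendrite", area=5e-5, capacitance=1.0,
                        parent="soma", axial_conductance_to_parent=0.04),
    )


_CA_POOL = CalciumPoolSpec(influx_factor=0.3, tau_removal=8.0, ca_rest=0.05)

# Region-resolved baseline densities (mS/cm²).  Within each functional class
# the per-channel densities shrink as the class gains members, holding the
# class totals roughly constant across gc5/gc9/gc15.
GC5_TABLE = {
    ("pas", REGION_ALL): 0.01,
    ("Kir21", REGION_ALL): 0.01,
    ("na8st", "soma"): 25.0,
    ("na8st", "AIS"): 120.0,
    ("BK", "soma"): 9.0,
    ("BK", "AIS"): 12.0,
    ("Cav22", "soma"): 1.2,
    ("Cav22", "AIS"): 1.2,
    ("Cav22", "dendrite"): 0.15,
}

GC9_TABLE = {
    ("pas", REGION_ALL): 0.01,
    ("Kir21", REGION_ALL): 0.01,
    ("na8st", "soma"): 25.0,
    ("na8st", "AIS"): 120.0,
    ("BK", "soma"): 7.0,
    ("BK", "AIS"): 9.0,
    ("Cav22", "soma"): 1.2,
    ("Cav22", "AIS"): 1.2,
    ("Cav22", "dendrite"): 0.15,
    ("Kv21", "soma"): 0.8,
    ("Kv42", "soma"): 0.8,
    ("Kv34", "AIS"): 1.0,
    ("Kv723", "AIS"): 1.0,
}

GC15_TABLE = {
    ("pas", REGION_ALL): 0.01,
    ("Kir21", REGION_ALL): 0.01,
    ("na8st", "soma"): 25.0,
    ("na8st", "AIS"): 120.0,
    ("BK", "soma"): 2.0,
    ("BK", "AIS"): 2.6,
    ("SK", "soma"): 2.0,
    ("SK", "AIS"): 2.6,
    ("SK", "dendrite"): 0.2,
    ("Kv21", "soma"): 1.0,
    ("Kv42", "soma"): 1.0,
    ("Kv34", "AIS"): 1.3,
    ("Kv723", "AIS"): 1.3,
    ("Kv11", "soma"): 0.5,
    ("Kv11", "AIS"): 0.7,
    ("Kv14", "soma"): 0.5,
    ("Kv14", "AIS"): 0.7,
    ("Cav22", "soma"): 0.4,
    ("Cav22", "AIS"): 0.6,
    ("Cav22", "dendrite"): 0.05,
    ("Cav12", "soma"): 0.3,
    ("Cav12", "dendrite"): 0.04,
    ("Cav13", "soma"): 0.3,
    ("Cav13", "dendrite"): 0.04,
    ("Cav32", "soma"): 0.2,
    ("Cav32", "AIS"): 0.6,
    ("Cav32", "dendrite"): 0.02,
}

_TABLES = {"gc5": GC5_TABLE, "gc9": GC9_TABLE, "gc15": GC15_TABLE}
_ROSTERS = {"gc5": GC5_ROSTER, "gc9": GC9_ROSTER, "gc15": GC15_ROSTER}


def make_baseline_model(name: str) -> NeuronConfig:
    """Build one baseline surrogate (``gc5``, ``gc9`` or ``gc15``)."""
    if name not in _TABLES:
        raise KeyError(f"unknown baseline {name!r}; expected one of {sorted(_TABLES)}")
    lib = channel_library()
    channels = tuple(lib[ch] for ch in _ROSTERS[name])
    return NeuronConfig(
        compartments=_compartments(),
        channels=channels,
        ca_pool=_CA_POOL,
        conductance_table=dict(_TABLES[name]),
    )


def make_baseline_models() -> dict[str, NeuronConfig]:
    """The three baseline surrogates sharing compartments and passive backbone."""
    return {name: make_baseline_model(name) for name in ("gc5", "gc9", "gc15")}


DEFAULT_SD_FRACTION = 0.15


def generate_feature_targets(
    reference: NeuronConfig,
    sd_fractions: float | dict[str, float] = DEFAULT_SD_FRACTION,
    floors: dict[str, float] | None = None,
    solver: SolverOptions | None = None,
) -> FeatureTargets:
    """Experimental-style targets from a reference simulation.

    Means are the reference model's features at 50 and 90 pA; SDs are
    ``max(sd_fraction × |mean|, floor)`` per feature, emulating the
    cell-to-cell variability of a recorded population.
    """
    floors = dict(DEFAULT_SD_FLOORS) if floors is None else dict(floors)
    traces = run_protocols(reference, (50.0, 90.0), solver=solver)
    feats = extract_features(traces[50.0], traces[90.0])
    if feats.by_protocol[90.0]["spike_count"] == 0:
        raise ValueError("reference model is non-spiking at 90 pA; cannot define targets")
    entries: dict[tuple[float, str], tuple[float, float]] = {}
    for (amp, name), value in feats.defined():
        frac = sd_fractions if isinstance(sd_fractions, float) else sd_fractions.get(name, DEFAULT_SD_FRACTION)
        sd = max(frac * abs(value), floors.get(name, 0.0))
        if sd <= 0.0:
            sd = floors.get(name, 0.05) or 0.05
        entries[(amp, name)] = (value, sd)
    return FeatureTargets(entries=entries, floors=floors)


# --------------------------------------------------------------------------
# ground-truth trace synthesis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthSpike:
    """Ground truth for one synthetic spike (all times relative to onset)."""

    onset_ms: float
    amplitude: float
    half_width: float
    fahp_depth: float


def synth_trace(
    spike_times: list[float],
    amplitude: float = 80.0,
    width: float = 1.0,
    fahp: float = 8.0,
    rest: float = -80.0,
    noise_sd: float = 0.0,
    amplitude_pa: float = 90.0,
    dt: float = 0.025,
    seed: int | None = None,
) -> VoltageTrace:
    """Build a stereotyped trace with exactly known spike parameters.

    ``spike_times`` are onsets in ms after stimulus onset and must lie inside
    the 200 ms step.  Each spike is piecewise linear: a fast rise (slope well
    above the 15 mV/ms criterion) from rest to ``rest + amplitude``, a fall to
    ``rest − fahp`` timed so that the width at half amplitude is exactly
    ``width``, and a slow sub-criterion recovery.  Linear interpolation makes
    the half-width exact irrespective of dt.
    """
    proto = StimulusProtocol(amplitude=amplitude_pa)
    total = proto.pre_ms + proto.step_ms + proto.post_ms
    n = int(round(total / dt)) + 1
    t = np.arange(n) * dt
    vm = np.full(n, rest)

    rise = 0.4  # ms; slope = amplitude / rise >> 15 mV/ms
    plateau = 2 * dt  # guarantees the exact peak value lands on the grid
    if width <= rise / 2 + plateau:
        raise ValueError("requested half-width too small for the rise time")
    # half-width = rise/2 + plateau + fall·(A/2)/(A+D), solved for the fall time
    fall = (width - rise / 2 - plateau) * (amplitude + fahp) / (amplitude / 2.0)
    if fall > 5.0:
        raise ValueError("fall time exceeds the 5 ms fAHP window; increase fahp depth")
    recover = 4.0
    span = rise + plateau + fall + recover + 2 * dt

    times = sorted(spike_times)
    min_sep = max(width + 5.0, span)
    for a, b in zip(times, times[1:]):
        if b - a < min_sep:
            raise ValueError(f"spikes at {a} and {b} ms overlap (separation < {min_sep:.1f} ms)")
    for st in times:
        if not (0.0 <= st <= proto.step_ms):
            raise ValueError(f"spike time {st} ms outside the stimulus window")

    for st in times:
        # snap the onset to the grid so onset/threshold/amplitude are exact
        t0 = round((proto.pre_ms + st) / dt) * dt
        seg = [
            (t0, rest),
            (t0 + rise, rest + amplitude),
            (t0 + rise + plateau, rest + amplitude),
            (t0 + rise + plateau + fall, rest - fahp),
            (t0 + rise + plateau + fall + recover, rest),
        ]
        for (ta, va), (tb, vb) in zip(seg, seg[1:]):
            ia = int(math.ceil(ta / dt))
            ib = min(int(math.floor(tb / dt)), n - 1)
            if ib >= ia:
                frac = (t[ia : ib + 1] - ta) / (tb - ta)
                vm[ia : ib + 1] = va + frac * (vb - va)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        vm = vm + rng.normal(0.0, noise_sd, size=n)

    return VoltageTrace(
        dt=dt,
        vm={"soma": vm},
        ca={"soma": np.full(n, _CA_POOL.ca_rest)},
        protocol=proto,
        vrest=rest,
    )


__all__ = [
    "GC5_ROSTER",
    "GC9_ROSTER",
    "GC15_ROSTER",
    "GC5_TABLE",
    "GC9_TABLE",
    "GC15_TABLE",
    "channel_library",
    "make_baseline_model",
    "make_baseline_models",
    "generate_feature_targets",
    "synth_trace",
    "SynthSpike",
    "DEFAULT_SD_FRACTION",
]
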