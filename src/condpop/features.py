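"""Spike-feature extraction and multi-objective fitness.

Nine spike features are extracted from the somatic voltage trace of the
standard two-amplitude current-clamp protocol (50 and 90 pA):

1. number of spikes fired within the 200 ms step,
2. latency of the first spike after stimulus onset (ms),
3. voltage threshold — Vm where dVm/dt first exceeds 15 mV/ms (mV),
4. mean spike amplitude above threshold (mV),
5. fast after-hyperpolarisation (fAHP) amplitude: threshold minus the
   minimum Vm within 5 ms after the spike peak (signed, mV),
6. absolute value of the fAHP amplitude (mV),
7. action-potential width at half amplitude (ms),
8. first interspike interval (ms),
9. adaptation index AI = 1 − ISI₁/ISI_end.

Each candidate feature is scored in units of the target standard deviation,
``F_i = |SF_i − mean_i| / SD_i``, and the Pareto efficiency ``P`` is the
maximum over all defined (feature, protocol) pairs.  A model is valid iff
``P < 2`` (strict).  A model that fires no spike at any amplitude receives
the sentinel ``P = 6``.

Undefined features (NaN) arise when their prerequisites are absent (e.g. no
second spike → no ISI) and are skipped in the maximum; the deviation in
spike count itself then carries the penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from condpop.model import VoltageTrace

RATE_THRESHOLD = 15.0  # mV/ms
FAHP_WINDOW_MS = 5.0
VALIDITY_THRESHOLD = 2.0
NONSPIKING_SENTINEL = 6.0

FEATURE_NAMES = (
    "spike_count",
    "latency",
    "threshold",
    "mean_amplitude",
    "fahp_amplitude",
    "abs_fahp_amplitude",
    "ap_width",
    "isi_first",
    "adaptation_index",
)

#: default SD floors by feature, in feature units (spikes / ms / mV / unitless)
DEFAULT_SD_FLOORS = {
    "spike_count": 0.5,
    "latency": 1.0,
    "threshold": 1.0,
    "mean_amplitude": 1.0,
    "fahp_amplitude": 1.0,
    "abs_fahp_amplitude": 1.0,
    "ap_width": 1.0,
    "isi_first": 1.0,
    "adaptation_index": 0.05,
}


@dataclass(frozen=True)
class SpikeEvent:
    onset_time: float  # ms from trace start
    peak_time: float
    peak_vm: float
    threshold_vm: float
    fahp_vm: float  # minimum within the post-peak window (NaN if trace ends)


def detect_spikes(
    trace: VoltageTrace | np.ndarray,
    dt: float | None = None,
    rate_threshold: float = RATE_THRESHOLD,
) -> list[SpikeEvent]:
    """Detect spikes on the somatic voltage by the dV/dt rate criterion.

    A spike onset is an upward crossing of ``rate_threshold``; the threshold
    voltage is Vm at the onset sample.  After an onset, no new onset is
    accepted until Vm has fallen back below that spike's threshold voltage
    (refractory rule).  The peak is the Vm maximum between onset and that
    fall; the fAHP is the Vm minimum within 5 ms after the peak.
    """
    if isinstance(trace, VoltageTrace):
        vm = trace.soma_vm
        dt = trace.dt
    else:
        vm = np.asarray(trace, dtype=float)
        if dt is None:
            raise ValueError("dt required when passing a bare array")
    if len(vm) < 2:
        raise ValueError("trace must have at least 2 samples")
    if dt > 1.0:
        raise ValueError("dt too coarse for the dV/dt rate criterion (dt > 1 ms)")

    dvdt = np.diff(vm) / dt
    fast = dvdt >= rate_threshold
    # upward crossings: sample i where fast[i] and not fast[i-1]
    crossings = np.flatnonzero(fast & ~np.concatenate(([False], fast[:-1])))

    events: list[SpikeEvent] = []
    fahp_n = int(round(FAHP_WINDOW_MS / dt))
    release_idx = 0  # first index at which a new onset may be accepted
    for i in crossings:
        if i < release_idx:
            continue
        thr = vm[i]
        # find where Vm falls back below threshold after the onset
        after = vm[i + 1 :]
        below = np.flatnonzero(after < thr)
        if below.size:
            fall = i + 1 + below[0]
        else:
            fall = len(vm)
        seg = vm[i : max(fall, i + 1)]
        pk_rel = int(np.argmax(seg))
        pk = i + pk_rel
        w0, w1 = pk + 1, min(pk + 1 + fahp_n, len(vm))
        fahp = float(np.min(vm[w0:w1])) if w1 > w0 else math.nan
        events.append(
            SpikeEvent(
                onset_time=i * dt,
                peak_time=pk * dt,
                peak_vm=float(vm[pk]),
                threshold_vm=float(thr),
                fahp_vm=fahp,
            )
        )
        release_idx = fall
    return events


def adaptation_index(isis: list[float] | np.ndarray) -> float:
    """AI = 1 − ISI₁/ISI_end; NaN when fewer than two ISIs exist."""
    isis = np.asarray(isis, dtype=float)
    if np.any(isis <= 0.0):
        raise ValueError("interspike intervals must be positive")
    if len(isis) < 2:
        return math.nan
    return float(1.0 - isis[0] / isis[-1])


def _half_width(vm: np.ndarray, dt: float, ev: SpikeEvent) -> float:
    """AP width at half amplitude via linear interpolation between samples."""
    level = ev.threshold_vm + 0.5 * (ev.peak_vm - ev.threshold_vm)
    pk = int(round(ev.peak_time / dt))
    # left crossing: walk back from the peak until vm < level
    i = pk
    while i > 0 and vm[i - 1] >= level:
        i -= 1
    if i == 0 and vm[0] >= level:
        return math.nan
    tl = (i - 1) * dt + dt * (level - vm[i - 1]) / (vm[i] - vm[i - 1])
    # right crossing
    j = pk
    while j < len(vm) - 1 and vm[j + 1] >= level:
        j += 1
    if j == len(vm) - 1 and vm[j] >= level:
        return math.nan
    tr = j * dt + dt * (vm[j] - level) / (vm[j] - vm[j + 1])
    return tr - tl


def _protocol_features(trace: VoltageTrace) -> dict[str, float]:
    vm = trace.soma_vm
    dt = trace.dt
    onset_ms = trace.stim_onset_ms
    end_ms = onset_ms + trace.protocol.step_ms
    events = [e for e in detect_spikes(trace) if onset_ms <= e.onset_time <= end_ms]
    f: dict[str, float] = {name: math.nan for name in FEATURE_NAMES}
    f["spike_count"] = float(len(events))
    if not events:
        return f
    f["latency"] = events[0].onset_time - onset_ms
    f["threshold"] = float(np.mean([e.threshold_vm for e in events]))
    amps = [e.peak_vm - e.threshold_vm for e in events]
    f["mean_amplitude"] = float(np.mean(amps))
    fahps = [e.threshold_vm - e.fahp_vm for e in events if math.isfinite(e.fahp_vm)]
    if fahps:
        f["fahp_amplitude"] = float(np.mean(fahps))
        f["abs_fahp_amplitude"] = abs(f["fahp_amplitude"])
    widths = [w for w in (_half_width(vm, dt, e) for e in events) if math.isfinite(w)]
    if widths:
        f["ap_width"] = float(np.mean(widths))
    if len(events) >= 2:
        onsets = np.array([e.onset_time for e in events])
        isis = np.diff(onsets)
        f["isi_first"] = float(isis[0])
        if len(isis) >= 2:
            f["adaptation_index"] = adaptation_index(isis)
    return f


@dataclass
class FeatureVector:
    """Per-protocol feature values; NaN marks an undefined feature."""

    by_protocol: dict[float, dict[str, float]]

    def defined(self):
        for amp, feats in self.by_protocol.items():
            for name, val in feats.items():
                if math.isfinite(val):
                    yield (amp, name), val

    @property
    def total_spikes(self) -> float:
        return sum(f["spike_count"] for f in self.by_protocol.values())


def extract_features(trace_50: VoltageTrace, trace_90: VoltageTrace) -> FeatureVector:
    """Extract the 9 features at both standard amplitudes."""
    for tr, amp in ((trace_50, 50.0), (trace_90, 90.0)):
        p = tr.protocol
        if (p.pre_ms, p.step_ms, p.post_ms) != (50.0, 200.0, 50.0):
            raise ValueError(
                f"protocol mismatch: expected 50/200/50 ms segments, got "
                f"{p.pre_ms}/{p.step_ms}/{p.post_ms}"
            )
        if p.amplitude != amp:
            raise ValueError(f"expected {amp} pA trace, got {p.amplitude} pA")
    return FeatureVector(
        by_protocol={
            50.0: _protocol_features(trace_50),
            90.0: _protocol_features(trace_90),
        }
    )


@dataclass(frozen=True)
class FeatureTargets:
    """Target mean and SD per (protocol amplitude, feature).

    SDs are floored at construction; entries may be absent for features the
    reference itself does not define.
    """

    entries: dict[tuple[float, str], tuple[float, float]]
    floors: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SD_FLOORS))

    def __post_init__(self) -> None:
        for (amp, name), (mean, sd) in self.entries.items():
            floor = self.floors.get(name, 0.0)
            if sd < floor or sd <= 0.0:
                raise ValueError(
                    f"target SD for ({amp}, {name}) is {sd}, below its floor {floor}"
                )


@dataclass
class FitnessResult:
    per_feature: dict[tuple[float, str], float]
    pareto_efficiency: float
    valid: bool
    sentinel_applied: bool

    @property
    def P(self) -> float:
        return self.pareto_efficiency


def feature_fitness(features: FeatureVector, targets: FeatureTargets) -> FitnessResult:
    """Score a feature vector against targets; P = max SD-deviation.

    Validity is strict (P < 2).  A fully non-spiking model (zero spikes at
    every amplitude) receives the sentinel P = 6.
    """
    if features.total_spikes == 0:
        return FitnessResult(
            per_feature={},
            pareto_efficiency=NONSPIKING_SENTINEL,
            valid=False,
            sentinel_applied=True,
        )
    per: dict[tuple[float, str], float] = {}
    for key, value in features.defined():
        tgt = targets.entries.get(key)
        if tgt is None:
            continue
        mean, sd = tgt
        per[key] = abs(value - mean) / sd
    # spike count must always be scored even at zero (it is always defined)
    P = max(per.values()) if per else NONSPIKING_SENTINEL
    return FitnessResult(
        per_feature=per,
        pareto_efficiency=P,
        valid=P < VALIDITY_THRESHOLD,
        sentinel_applied=not per,
    )


__all__ = [
    "RATE_THRESHOLD",
    "VALIDITY_THRESHOLD",
    "NONSPIKING_SENTINEL",
    "FEATURE_NAMES",
    "DEFAULT_SD_FLOORS",
    "SpikeEvent",
    "FeatureVector",
    "FeatureTargets",
    "FitnessResult",
    "detect_spikes",
    "adaptation_index",
    "extract_features",
    "feature_fitness",
]
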