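"""Current-clamp simulation engine.

Fixed-step integrator: exponential-Euler updates for gating variables and the
calcium pools, an implicit (backward-Euler) voltage update solved exactly on
the small compartment tree.  Gate steady states and exponential-Euler factors
are tabulated on a voltage grid (0.05 mV spacing) at simulation start, which
keeps the inner loop free of transcendental calls; the tables are built from
the same :func:`~condpop.channels.gate_steady_state` /
:func:`~condpop.channels.gate_time_constant` functions that define the
kinetics, so tabulated and direct evaluation agree to interpolation error.

Every simulation starts from a settle-in period at zero current (500 ms cap)
whose final state defines the resting potential; the settle exits early once
the state has stopped moving, which leaves the dynamics unchanged.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pandas as pd
from numba import njit

from condpop.channels import ROLE_CALCIUM, gate_steady_state, gate_time_constant
from condpop.model import (
    REGION_ALL,
    NeuronConfig,
    SolverOptions,
    StimulusProtocol,
    VoltageTrace,
)

# voltage grid for the gate tables
_V_LO = -130.0
_V_HI = 80.0
_DV = 0.05


class SimulationError(RuntimeError):
    """Raised when the solver state becomes non-finite."""


# --------------------------------------------------------------------------
# model compilation: frozen structure -> flat arrays for the kernel
# --------------------------------------------------------------------------

class CompiledModel:
    """Flat-array view of a model structure, shared across density vectors."""

    def __init__(self, compartments, channels, ca_pool):
        self.compartments = compartments
        self.channels = channels
        self.ca_pool = ca_pool

        comp_index = {c.name: i for i, c in enumerate(compartments)}
        n_comp = len(compartments)
        self.n_comp = n_comp
        self.comp_names = [c.name for c in compartments]
        self.cm = np.array([c.capacitance for c in compartments])
        self.area = np.array([c.area for c in compartments])
        self.parent = np.array(
            [comp_index[c.parent] if c.parent is not None else -1 for c in compartments],
            dtype=np.int64,
        )
        self.gax = np.array([c.axial_conductance_to_parent for c in compartments])

        # unique (channel, gate) rows for the voltage tables
        self.chan_names = [c.name for c in channels]
        chan_index = {c.name: i for i, c in enumerate(channels)}
        gate_rows = []  # list of (channel name, GateSpec)
        self._row_of = {}
        for c in channels:
            for gi, g in enumerate(c.gates):
                self._row_of[(c.name, gi)] = len(gate_rows)
                gate_rows.append(g)
        self.gate_rows = gate_rows

        # instances: one per (channel, compartment) with nonzero possible density;
        # built per conductance-table layout, so store layout at first use
        self._instances_key = None
        self._tables = {}
        self.chan_index = chan_index

    # -- instance layout ----------------------------------------------------

    def build_instances(self, config: NeuronConfig):
        """Expand the conductance table into per-compartment channel instances.

        Returns (structure arrays, param_keys) where ``param_keys`` is the
        full ordered key list; densities for a given config come from
        :meth:`density_array`.
        """
        comp_index = {c.name: i for i, c in enumerate(self.compartments)}
        param_keys = config.parameter_keys
        key_index = {k: i for i, k in enumerate(param_keys)}

        inst_comp, inst_rev, inst_feeds, inst_chan, inst_param = [], [], [], [], []
        gate_row, gate_is_ca, gate_exp = [], [], []
        gate_ca_half, gate_hill = [], []
        inst_gate_start, inst_gate_count = [], []
        for (chan_name, region) in param_keys:
            chan = config.channel(chan_name)
            for comp_name in config.region_compartments(region):
                inst_comp.append(comp_index[comp_name])
                inst_rev.append(chan.reversal)
                inst_feeds.append(1 if chan.feeds_ca_pool else 0)
                inst_chan.append(self.chan_index[chan_name])
                inst_param.append(key_index[(chan_name, region)])
                inst_gate_start.append(len(gate_row))
                inst_gate_count.append(len(chan.gates))
                for gi, g in enumerate(chan.gates):
                    gate_row.append(self._row_of[(chan_name, gi)])
                    gate_is_ca.append(1 if g.role == ROLE_CALCIUM else 0)
                    gate_exp.append(g.exponent)
                    gate_ca_half.append(g.ca_half)
                    gate_hill.append(g.hill_coeff)

        arrays = dict(
            inst_comp=np.array(inst_comp, dtype=np.int64),
            inst_rev=np.array(inst_rev, dtype=float),
            inst_feeds=np.array(inst_feeds, dtype=np.int64),
            inst_chan=np.array(inst_chan, dtype=np.int64),
            inst_param=np.array(inst_param, dtype=np.int64),
            inst_gate_start=np.array(inst_gate_start, dtype=np.int64),
            inst_gate_count=np.array(inst_gate_count, dtype=np.int64),
            gate_row=np.array(gate_row, dtype=np.int64),
            gate_is_ca=np.array(gate_is_ca, dtype=np.int64),
            gate_exp=np.array(gate_exp, dtype=np.int64),
            gate_ca_half=np.array(gate_ca_half, dtype=float),
            gate_hill=np.array(gate_hill, dtype=float),
        )
        return arrays, param_keys

    def tables(self, dt: float):
        """Voltage-grid tables of steady state and exp(-dt/tau) per gate row."""
        key = round(dt, 9)
        if key not in self._tables:
            vgrid = np.arange(_V_LO, _V_HI + _DV / 2, _DV)
            n_rows = len(self.gate_rows)
            tab_inf = np.empty((n_rows, len(vgrid)))
            tab_ef = np.empty((n_rows, len(vgrid)))
            for r, g in enumerate(self.gate_rows):
                if g.role == ROLE_CALCIUM:
                    # voltage independent; rows kept for uniform indexing
                    tab_inf[r, :] = 0.0
                    tab_ef[r, :] = math.exp(-dt / max(g.tau_base, 0.05))
                else:
                    for j, v in enumerate(vgrid):
                        tab_inf[r, j] = gate_steady_state(g, v)
                        tab_ef[r, j] = math.exp(-dt / gate_time_constant(g, v))
            self._tables[key] = (tab_inf, tab_ef)
        return self._tables[key]


@lru_cache(maxsize=64)
def _compiled(compartments, channels, ca_pool) -> CompiledModel:
    return CompiledModel(compartments, channels, ca_pool)


def compile_model(config: NeuronConfig) -> CompiledModel:
    return _compiled(config.compartments, config.channels, config.ca_pool)


# --------------------------------------------------------------------------
# numba kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _step_kernel(
    n_steps,
    dt,
    # state (modified in place)
    v,
    ca,
    gstate,
    # densities per instance (mS/cm²)
    inst_g,
    # structure
    inst_comp,
    inst_rev,
    inst_feeds,
    inst_chan,
    inst_gate_start,
    inst_gate_count,
    gate_row,
    gate_is_ca,
    gate_exp,
    gate_ca_half,
    gate_hill,
    # tables
    tab_inf,
    tab_ef,
    v_lo,
    inv_dv,
    n_tab,
    # passive structure
    cm,
    area,
    parent,
    gax,
    # calcium pool
    ca_kin,
    ca_tau,
    ca_rest,
    # stimulus: injected current density (µA/cm²) at soma, on [i0, i1)
    inj_dens,
    stim_i0,
    stim_i1,
    # recording (n_steps+1 columns when rec_* true; else 1x1 dummies)
    rec_vm,
    rec_ca,
    rec_cur,
    do_record,
    do_record_cur,
    # settle early exit: stop when max|dv| < exit_dv for exit_window steps (0 = off)
    exit_dv,
    exit_window,
):
    n_comp = v.shape[0]
    n_inst = inst_comp.shape[0]
    A = np.empty((n_comp, n_comp))
    rhs = np.empty(n_comp)
    gsum = np.empty(n_comp)
    gE = np.empty(n_comp)
    Gi = np.empty(n_inst)
    ica = np.empty(n_comp)
    prev_v = np.empty(n_comp)
    efca = math.exp(-dt / ca_tau)
    quiet = 0

    if do_record:
        for c in range(n_comp):
            rec_vm[c, 0] = v[c]
            rec_ca[c, 0] = ca[c]

    for step in range(n_steps):
        for c in range(n_comp):
            prev_v[c] = v[c]
        # gate updates and conductances
        for c in range(n_comp):
            gsum[c] = 0.0
            gE[c] = 0.0
        for i in range(n_inst):
            c = inst_comp[i]
            p = 1.0
            g0 = inst_gate_start[i]
            for k in range(inst_gate_count[i]):
                j = g0 + k
                r = gate_row[j]
                if gate_is_ca[j] == 1:
                    cc = ca[c]
                    if cc <= 0.0:
                        inf = 0.0
                    else:
                        ratio = (cc / gate_ca_half[j]) ** gate_hill[j]
                        inf = ratio / (1.0 + ratio)
                    ef = tab_ef[r, 0]
                else:
                    x = (v[c] - v_lo) * inv_dv
                    if x < 0.0:
                        x = 0.0
                    elif x > n_tab - 1.001:
                        x = n_tab - 1.001
                    i0 = int(x)
                    f = x - i0
                    inf = tab_inf[r, i0] + f * (tab_inf[r, i0 + 1] - tab_inf[r, i0])
                    ef = tab_ef[r, i0] + f * (tab_ef[r, i0 + 1] - tab_ef[r, i0])
                s = inf + (gstate[j] - inf) * ef
                gstate[j] = s
                e = gate_exp[j]
                for _ in range(e):
                    p *= s
            G = inst_g[i] * p
            Gi[i] = G
            gsum[c] += G
            gE[c] += G * inst_rev[i]

        # implicit voltage update on the compartment tree
        for a in range(n_comp):
            for b in range(n_comp):
                A[a, b] = 0.0
            A[a, a] = cm[a] / dt + gsum[a]
            rhs[a] = cm[a] / dt * v[a] + gE[a]
        for c in range(n_comp):
            pidx = parent[c]
            if pidx >= 0:
                gc = gax[c] * 1e-3 / area[c]
                gp = gax[c] * 1e-3 / area[pidx]
                A[c, c] += gc
                A[c, pidx] -= gc
                A[pidx, pidx] += gp
                A[pidx, c] -= gp
        if step >= stim_i0 and step < stim_i1:
            rhs[0] += inj_dens
        # gaussian elimination (tiny dense system)
        for col in range(n_comp - 1):
            piv = A[col, col]
            for row in range(col + 1, n_comp):
                if A[row, col] != 0.0:
                    fac = A[row, col] / piv
                    for cc2 in range(col, n_comp):
                        A[row, cc2] -= fac * A[col, cc2]
                    rhs[row] -= fac * rhs[col]
        for row in range(n_comp - 1, -1, -1):
            acc = rhs[row]
            for cc2 in range(row + 1, n_comp):
                acc -= A[row, cc2] * v[cc2]
            v[row] = acc / A[row, row]

        # calcium pools (exponential Euler towards ca_inf)
        for c in range(n_comp):
            ica[c] = 0.0
        for i in range(n_inst):
            if inst_feeds[i] == 1:
                c = inst_comp[i]
                ica[c] += Gi[i] * (v[c] - inst_rev[i]) * area[c] * 1e3  # nA
        for c in range(n_comp):
            influx = -ca_kin * ica[c]  # µM/ms, inward Ca current is negative
            ca_inf = ca_rest + influx * ca_tau
            newca = ca_inf + (ca[c] - ca_inf) * efca
            if newca < 0.0:
                newca = 0.0
            ca[c] = newca

        # blow-up guard
        maxdv = 0.0
        for c in range(n_comp):
            if not math.isfinite(v[c]) or abs(v[c]) > 500.0:
                return -(step * 10 + c + 1)  # encodes step and compartment
        if do_record:
            for c in range(n_comp):
                rec_vm[c, step + 1] = v[c]
                rec_ca[c, step + 1] = ca[c]
        if do_record_cur:
            n_chan = rec_cur.shape[0]
            for q in range(n_chan):
                rec_cur[q, step + 1] = 0.0
            for i in range(n_inst):
                c = inst_comp[i]
                rec_cur[inst_chan[i], step + 1] += Gi[i] * (v[c] - inst_rev[i]) * area[c] * 1e3

        if exit_window > 0:
            moved = False
            for c in range(n_comp):
                if abs(v[c] - prev_v[c]) > exit_dv:
                    moved = True
            if moved:
                quiet = 0
            else:
                quiet += 1
                if quiet >= exit_window:
                    return step + 1
    return n_steps


def _initial_state(compiled: CompiledModel, arrays, v0: float = -80.0):
    n_comp = compiled.n_comp
    v = np.full(n_comp, v0)
    ca = np.full(n_comp, compiled.ca_pool.ca_rest)
    gstate = np.empty(len(arrays["gate_row"]))
    for j in range(len(gstate)):
        r = arrays["gate_row"][j]
        g = compiled.gate_rows[r]
        if g.role == ROLE_CALCIUM:
            cc = compiled.ca_pool.ca_rest
            ratio = (cc / g.ca_half) ** g.hill_coeff
            gstate[j] = ratio / (1.0 + ratio)
        else:
            gstate[j] = gate_steady_state(g, v0)
    return v, ca, gstate


_DUMMY = np.zeros((1, 1))


def _kernel_args(compiled, arrays, dt):
    tab_inf, tab_ef = compiled.tables(dt)
    return dict(
        inst_comp=arrays["inst_comp"],
        inst_rev=arrays["inst_rev"],
        inst_feeds=arrays["inst_feeds"],
        inst_chan=arrays["inst_chan"],
        inst_gate_start=arrays["inst_gate_start"],
        inst_gate_count=arrays["inst_gate_count"],
        gate_row=arrays["gate_row"],
        gate_is_ca=arrays["gate_is_ca"],
        gate_exp=arrays["gate_exp"],
        gate_ca_half=arrays["gate_ca_half"],
        gate_hill=arrays["gate_hill"],
        tab_inf=tab_inf,
        tab_ef=tab_ef,
        v_lo=_V_LO,
        inv_dv=1.0 / _DV,
        n_tab=tab_inf.shape[1],
        cm=compiled.cm,
        area=compiled.area,
        parent=compiled.parent,
        gax=compiled.gax,
        ca_kin=compiled.ca_pool.influx_factor,
        ca_tau=compiled.ca_pool.tau_removal,
        ca_rest=compiled.ca_pool.ca_rest,
    )


def _raise_blowup(code: int, compiled: CompiledModel, phase: str):
    enc = -code
    step = enc // 10
    comp = compiled.comp_names[(enc % 10) - 1]
    raise SimulationError(
        f"non-finite state during {phase} at step {step} in compartment {comp!r}"
    )


def run_protocols(
    config: NeuronConfig,
    amplitudes: tuple[float, ...],
    solver: SolverOptions | None = None,
    protocol_template: StimulusProtocol | None = None,
) -> dict[float, VoltageTrace]:
    """Simulate the standard protocol at several amplitudes with one settle-in.

    The settle-in (zero current) is run once from the canonical initial state;
    its final state seeds every protocol, so the traces are exactly what
    per-amplitude :func:`simulate_current_clamp` calls would produce while
    paying the settle cost once.
    """
    solver = solver or SolverOptions()
    compiled = compile_model(config)
    arrays, param_keys = compiled.build_instances(config)
    dens_full = np.array([config.conductance_table[k] for k in param_keys])
    inst_g = dens_full[arrays["inst_param"]]
    common = _kernel_args(compiled, arrays, solver.dt)

    # settle-in
    v, ca, gstate = _initial_state(compiled, arrays)
    n_settle = int(round(solver.settle_ms / solver.dt))
    window = max(1, int(round(20.0 / solver.dt)))
    code = _step_kernel(
        n_settle,
        solver.dt,
        v,
        ca,
        gstate,
        inst_g,
        **common,
        inj_dens=0.0,
        stim_i0=0,
        stim_i1=0,
        rec_vm=_DUMMY,
        rec_ca=_DUMMY,
        rec_cur=_DUMMY,
        do_record=False,
        do_record_cur=False,
        exit_dv=solver.settle_tol * solver.dt,
        exit_window=window,
    )
    if code < 0:
        _raise_blowup(code, compiled, "settle-in")
    vrest = float(v[0])

    out: dict[float, VoltageTrace] = {}
    for amp in amplitudes:
        proto = protocol_template or StimulusProtocol(amplitude=amp)
        proto = StimulusProtocol(
            amplitude=amp,
            pre_ms=proto.pre_ms,
            step_ms=proto.step_ms,
            post_ms=proto.post_ms,
            site=proto.site,
        )
        total_ms = proto.pre_ms + proto.step_ms + proto.post_ms
        n_steps = int(round(total_ms / solver.dt))
        i0 = int(round(proto.pre_ms / solver.dt))
        i1 = int(round((proto.pre_ms + proto.step_ms) / solver.dt))
        vp, cap, gp = v.copy(), ca.copy(), gstate.copy()
        rec_vm = np.empty((compiled.n_comp, n_steps + 1))
        rec_ca = np.empty((compiled.n_comp, n_steps + 1))
        if solver.record_currents:
            rec_cur = np.zeros((len(compiled.chan_names), n_steps + 1))
        else:
            rec_cur = _DUMMY
        inj_dens = amp * 1e-6 / compiled.area[0]  # pA -> µA/cm² at soma
        code = _step_kernel(
            n_steps,
            solver.dt,
            vp,
            cap,
            gp,
            inst_g,
            **common,
            inj_dens=inj_dens,
            stim_i0=i0,
            stim_i1=i1,
            rec_vm=rec_vm,
            rec_ca=rec_ca,
            rec_cur=rec_cur,
            do_record=True,
            do_record_cur=solver.record_currents,
            exit_dv=0.0,
            exit_window=0,
        )
        if code < 0:
            _raise_blowup(code, compiled, f"{amp} pA protocol")
        vm = {name: rec_vm[c] for c, name in enumerate(compiled.comp_names)}
        cad = {name: rec_ca[c] for c, name in enumerate(compiled.comp_names)}
        currents = None
        if solver.record_currents:
            rec_cur[:, 0] = rec_cur[:, 1]
            currents = {name: rec_cur[q] for q, name in enumerate(compiled.chan_names)}
        out[amp] = VoltageTrace(
            dt=solver.dt, vm=vm, ca=cad, protocol=proto, vrest=vrest, currents=currents
        )
    return out


def simulate_current_clamp(
    config: NeuronConfig,
    protocol: StimulusProtocol,
    solver: SolverOptions | None = None,
) -> VoltageTrace:
    """Simulate one somatic current-clamp step and return the trace."""
    if protocol.site != "soma":
        raise ValueError("stimulation site must be the soma")
    traces = run_protocols(
        config, (protocol.amplitude,), solver=solver, protocol_template=protocol
    )
    return traces[protocol.amplitude]


# --------------------------------------------------------------------------
# current decomposition
# --------------------------------------------------------------------------

def decompose_currents(trace: VoltageTrace) -> dict[str, pd.DataFrame]:
    """Fractional contribution of each channel to total inward/outward current.

    At every time step, inward fractions (%) are computed over the channels
    with negative current only and sum to 100 wherever total inward current
    is nonzero; likewise for outward over positive currents.  Steps with an
    empty sign class carry NaN.
    """
    if trace.currents is None:
        raise ValueError("trace was recorded without per-channel currents")
    names = list(trace.currents)
    I = np.vstack([trace.currents[n] for n in names])  # nA, (n_chan, n_t)
    neg = np.where(I < 0.0, I, 0.0)
    pos = np.where(I > 0.0, I, 0.0)
    tot_in = neg.sum(axis=0)
    tot_out = pos.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_in = np.where(tot_in != 0.0, neg / tot_in * 100.0, np.nan)
        frac_out = np.where(tot_out != 0.0, pos / tot_out * 100.0, np.nan)
    t = trace.time_ms
    return {
        "inward": pd.DataFrame(frac_in.T, columns=names, index=t),
        "outward": pd.DataFrame(frac_out.T, columns=names, index=t),
    }


__all__ = [
    "SimulationError",
    "CompiledModel",
    "compile_model",
    "run_protocols",
    "simulate_current_clamp",
    "decompose_currents",
]
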