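"""Compiled fixed-step forward-Euler integration of the membrane model.

The channel registry plus a parameter vector are flattened into numeric
arrays (:func:`pack_kernel`) consumed by numba-jitted loops.  Calcium-coupled
gates are resolved at pack time: their steady-state template/constants are
copied from the paired CaV channel's activation gate, so the integrator sees
only plain voltage-dependent gates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .hh_core import (
    SS_TEMPLATES,
    TAU_TEMPLATES,
    ParameterVector,
    Registry,
)

SS_CODE = {"boltzmann": 0, "boltzmann_floor": 1, "const": 2}
TAU_CODE = {"const": 0, "bell": 1, "bell_skew": 2, "bell2": 3}

_DIVERGE_V = 1.0e4  # |V| beyond which a trace is flagged divergent


@dataclass
class KernelPack:
    g: np.ndarray  # (16,) nS
    E: np.ndarray  # (16,) mV
    C: float  # pF
    V0: float  # mV
    x0: np.ndarray  # (25,)
    ch_of_gate: np.ndarray  # (25,) int
    exps: np.ndarray  # (25,) float
    ss_kind: np.ndarray  # (25,) int
    ss_p: np.ndarray  # (25, 3)
    tau_kind: np.ndarray  # (25,) int
    tau_p: np.ndarray  # (25, 7)

    def as_args(self):
        return (
            self.g, self.E, self.C, self.V0, self.x0, self.ch_of_gate,
            self.exps, self.ss_kind, self.ss_p, self.tau_kind, self.tau_p,
        )


def _resolved_gate(reg: Registry, channel, gate, params: ParameterVector):
    """(ss_template, ss_vals, tau_template, tau_vals) with coupling resolved."""
    if gate.ss_template == "cav_coupled":
        src_ch = reg.channel(gate.coupled_to)
        src = reg.activation_gate(gate.coupled_to)
        ss_t, ss_v, _, _ = _resolved_gate(reg, src_ch, src, params)
    else:
        ss_t = gate.ss_template
        if gate.trainable:
            ss_v = [params[f"{channel.name}_{gate.name}_{s}"] for s in SS_TEMPLATES[ss_t]]
        else:
            ss_v = [gate.ss_params[s] for s in SS_TEMPLATES[ss_t]]
    tau_t = gate.tau_template
    if gate.trainable:
        tau_v = [params[f"{channel.name}_{gate.name}_{s}"] for s in TAU_TEMPLATES[tau_t]]
    else:
        tau_v = [gate.tau_params[s] for s in TAU_TEMPLATES[tau_t]]
    return ss_t, ss_v, tau_t, tau_v


def pack_kernel(params: ParameterVector) -> KernelPack:
    space = params.space
    reg = space.registry
    n_ch = len(reg.channels)
    n_g = reg.n_gates
    g = np.empty(n_ch)
    E = np.empty(n_ch)
    ch_of_gate = np.empty(n_g, dtype=np.int64)
    exps = np.empty(n_g)
    x0 = np.empty(n_g)
    ss_kind = np.empty(n_g, dtype=np.int64)
    ss_p = np.zeros((n_g, 3))
    tau_kind = np.empty(n_g, dtype=np.int64)
    tau_p = np.zeros((n_g, 7))
    gi = 0
    for ci, c in enumerate(reg.channels):
        g[ci] = params[f"{c.name}_g"]
        E[ci] = params[c.reversal]
        for gate in c.gates:
            ch_of_gate[gi] = ci
            exps[gi] = float(gate.exponent)
            x0[gi] = params[f"{c.name}_{gate.name}_0"]
            ss_t, ss_v, tau_t, tau_v = _resolved_gate(reg, c, gate, params)
            ss_kind[gi] = SS_CODE[ss_t]
            ss_p[gi, : len(ss_v)] = ss_v
            tau_kind[gi] = TAU_CODE[tau_t]
            tau_p[gi, : len(tau_v)] = tau_v
            gi += 1
    return KernelPack(
        g=g, E=E, C=params["C_m"], V0=params["V_0"], x0=x0,
        ch_of_gate=ch_of_gate, exps=exps, ss_kind=ss_kind, ss_p=ss_p,
        tau_kind=tau_kind, tau_p=tau_p,
    )


@njit(cache=True, inline="always")
def _xinf(kind, p, V):
    if kind == 0:
        return 1.0 / (1.0 + math.exp(-(V - p[0]) / p[1]))
    if kind == 1:
        return p[2] + (1.0 - p[2]) / (1.0 + math.exp(-(V - p[0]) / p[1]))
    return p[0]  # const


@njit(cache=True, inline="always")
def _tau(kind, p, V):
    if kind == 0:
        return p[0]
    if kind == 1:
        z = (V - p[2]) / p[3]
        return p[0] + p[1] * math.exp(-z * z)
    if kind == 2:
        w = p[3] if V < p[2] else p[4]
        z = (V - p[2]) / w
        return p[0] + p[1] * math.exp(-z * z)
    z1 = (V - p[2]) / p[3]
    z2 = (V - p[5]) / p[6]
    return p[0] + p[1] * math.exp(-z1 * z1) + p[4] * math.exp(-z2 * z2)


@njit(cache=True)
def _ionic_current(g, E, ch_of_gate, exps, x, V):
    n_ch = g.shape[0]
    open_frac = np.ones(n_ch)
    for i in range(x.shape[0]):
        open_frac[ch_of_gate[i]] *= x[i] ** exps[i]
    I = 0.0
    for c in range(n_ch):
        I += g[c] * open_frac[c] * (V - E[c])
    return I


@njit(cache=True)
def simulate_cc_kernel(
    g, E, C, V0, x0, ch_of_gate, exps, ss_kind, ss_p, tau_kind, tau_p,
    levels, dt, n_steps, stim_lo, stim_hi, rec_stride,
):
    """Current clamp: forward Euler at dt (ms); records V every rec_stride steps."""
    n_lev = levels.shape[0]
    n_g = x0.shape[0]
    n_rec = n_steps // rec_stride + 1
    V_out = np.full((n_lev, n_rec), np.nan)
    diverged = np.zeros(n_lev, np.bool_)
    for li in range(n_lev):
        V = V0
        x = x0.copy()
        V_out[li, 0] = V
        for s in range(1, n_steps + 1):
            I_ion = _ionic_current(g, E, ch_of_gate, exps, x, V)
            I_ext = levels[li] if stim_lo <= s - 1 < stim_hi else 0.0
            V_new = V + dt * (-I_ion + I_ext) / C
            for i in range(n_g):
                xi = _xinf(ss_kind[i], ss_p[i], V)
                ti = _tau(tau_kind[i], tau_p[i], V)
                xn = x[i] + dt * (xi - x[i]) / ti
                if xn < 0.0:
                    xn = 0.0
                elif xn > 1.0:
                    xn = 1.0
                x[i] = xn
            V = V_new
            if not math.isfinite(V) or abs(V) > _DIVERGE_V:
                diverged[li] = True
                break
            if s % rec_stride == 0:
                V_out[li, s // rec_stride] = V
    return V_out, diverged


@njit(cache=True)
def simulate_vc_kernel(
    g, E, C, V0, x0, ch_of_gate, exps, ss_kind, ss_p, tau_kind, tau_p,
    voltages, dt, n_steps,
):
    """Voltage clamp: V held fixed, gate ODEs integrated; terminal current."""
    n_lev = voltages.shape[0]
    n_g = x0.shape[0]
    out = np.empty(n_lev)
    for li in range(n_lev):
        V = voltages[li]
        x = x0.copy()
        xi = np.empty(n_g)
        ti = np.empty(n_g)
        for i in range(n_g):  # kinetics constant at fixed V
            xi[i] = _xinf(ss_kind[i], ss_p[i], V)
            ti[i] = _tau(tau_kind[i], tau_p[i], V)
        for s in range(n_steps):
            for i in range(n_g):
                xn = x[i] + dt * (xi[i] - x[i]) / ti[i]
                if xn < 0.0:
                    xn = 0.0
                elif xn > 1.0:
                    xn = 1.0
                x[i] = xn
        out[li] = _ionic_current(g, E, ch_of_gate, exps, x, V)
    return out
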