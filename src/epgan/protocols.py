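"""Current-/voltage-clamp protocols, integration under them, and windowing.

Shipped presets follow the standard recording configuration: 15 s episodes
with the stimulus applied during t = [5, 10) s, current steps -15:5:35 pA
(11 levels) and voltage steps -120:10:50 mV (18 levels).  Network inputs are
windowed to t = [4, 11] s at 50 Hz: 350 samples per trace (20 ms spacing),
covering one second before stimulus onset and one second after offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .hh_core import IVProfile, ParameterVector

__all__ = [
    "ClampProtocol",
    "TraceSet",
    "WindowedInput",
    "build_protocol",
    "get_preset",
    "PRESETS",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "window_traces",
    "WINDOW_START_S",
    "WINDOW_END_S",
    "WINDOW_DT_S",
    "N_WINDOW_SAMPLES",
]

WINDOW_START_S = 4.0
WINDOW_END_S = 11.0
WINDOW_DT_S = 0.02  # 50 Hz
N_WINDOW_SAMPLES = 350


@dataclass(frozen=True)
class ClampProtocol:
    kind: str  # "current" (levels in pA) or "voltage" (levels in mV)
    levels: np.ndarray
    duration: float = 15.0  # s
    stim_window: tuple[float, float] = (5.0, 10.0)  # s, half-open [on, off)

    def __post_init__(self):
        if self.kind not in ("current", "voltage"):
            raise ValueError(f"kind must be 'current' or 'voltage', got {self.kind!r}")
        object.__setattr__(self, "levels", np.asarray(self.levels, dtype=float))


def build_protocol(minv: float, step: float, maxv: float, kind: str) -> ClampProtocol:
    """Inclusive arithmetic sequence of clamp levels min:step:max."""
    if step <= 0:
        raise ValueError("step must be positive")
    if minv > maxv:
        raise ValueError("min must not exceed max")
    n = int(np.floor((maxv - minv) / step + 1e-9)) + 1
    return ClampProtocol(kind=kind, levels=minv + step * np.arange(n))


# Table of shipped presets (simulated-neuron configuration plus the narrower
# current ranges used for low-input-resistance cells).
PRESETS = {
    "simulated_cc": (-15.0, 5.0, 35.0, "current"),
    "simulated_vc": (-120.0, 10.0, 50.0, "voltage"),
    "narrow_cc": (-2.0, 1.0, 8.0, "current"),
    "medium_cc": (-4.0, 2.0, 16.0, "current"),
}


def get_preset(name: str) -> ClampProtocol:
    try:
        return build_protocol(*PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown protocol preset {name!r}; available: {sorted(PRESETS)}") from None


@dataclass
class TraceSet:
    """Membrane-potential and stimulus traces on a shared time grid."""

    time: np.ndarray  # (n_t,) s
    V: np.ndarray  # (n_levels, n_t) mV
    stim: np.ndarray  # (n_levels, n_t) pA
    protocol: ClampProtocol
    dt_ms: float  # internal integration step
    diverged: np.ndarray = field(default=None)  # (n_levels,) bool

    def __post_init__(self):
        if self.diverged is None:
            self.diverged = np.zeros(len(self.protocol.levels), dtype=bool)


@dataclass
class WindowedInput:
    """Network input: 350-sample V and stimulus vectors plus the I-V profile."""

    time: np.ndarray  # (350,) s, 4.0 + 0.02*k
    V: np.ndarray  # (n_levels, 350) mV
    stim: np.ndarray  # (n_levels, 350) pA
    iv: IVProfile
    levels: np.ndarray  # (n_levels,) pA


def _stim_trace(protocol: ClampProtocol, time: np.ndarray) -> np.ndarray:
    on, off = protocol.stim_window
    gate = ((time >= on) & (time < off)).astype(float)
    return protocol.levels[:, None] * gate[None, :]


def simulate_current_clamp(
    params: ParameterVector,
    protocol: ClampProtocol,
    dt: float = 0.1,
    record_dt: float = 0.02,
) -> TraceSet:
    """Integrate the model under each current step with forward Euler.

    ``dt`` is the integration step in ms; ``record_dt`` the output grid in
    seconds.  Non-finite excursions flag the trace as divergent rather than
    raising, so bulk rejection sampling can discard them.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if protocol.kind != "current":
        raise ValueError("current-clamp simulation requires a current protocol")
    rec_ms = record_dt * 1e3
    stride = int(round(rec_ms / dt))
    if abs(stride * dt - rec_ms) > 1e-9 * rec_ms:
        raise ValueError("record_dt must be an integer multiple of dt")
    n_steps = int(round(protocol.duration * 1e3 / dt))
    on, off = protocol.stim_window
    pack = _kernel.pack_kernel(params)
    V, diverged = _kernel.simulate_cc_kernel(
        *pack.as_args(),
        protocol.levels,
        dt,
        n_steps,
        int(round(on * 1e3 / dt)),
        int(round(off * 1e3 / dt)),
        stride,
    )
    time = np.arange(V.shape[1]) * record_dt
    return TraceSet(
        time=time, V=V, stim=_stim_trace(protocol, time), protocol=protocol,
        dt_ms=dt, diverged=diverged,
    )


def simulate_voltage_clamp(
    params: ParameterVector,
    protocol: ClampProtocol,
    dt: float = 0.1,
    hold_duration: float = 5.0,
) -> IVProfile:
    """Hold V at each level, integrate the gate ODEs, report terminal current."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if protocol.kind != "voltage":
        raise ValueError("voltage-clamp simulation requires a voltage protocol")
    pack = _kernel.pack_kernel(params)
    n_steps = int(round(hold_duration * 1e3 / dt))
    currents = _kernel.simulate_vc_kernel(
        *pack.as_args(), protocol.levels, dt, n_steps
    )
    return IVProfile(voltages=protocol.levels, currents=currents)


def window_traces(traces: TraceSet, iv: IVProfile) -> WindowedInput:
    """Decimate full traces onto the 350-point [4, 11] s input grid."""
    t_w = WINDOW_START_S + WINDOW_DT_S * np.arange(N_WINDOW_SAMPLES)
    grid_dt = float(np.median(np.diff(traces.time)))
    idx = np.round((t_w - traces.time[0]) / grid_dt).astype(int)
    if idx[0] < 0 or idx[-1] >= traces.time.size:
        raise ValueError("trace grid does not cover the [4, 11] s window")
    if not np.allclose(traces.time[idx], t_w, atol=1e-6):
        raise ValueError("trace grid is not alignable with the 20 ms window grid")
    return WindowedInput(
        time=t_w,
        V=traces.V[:, idx],
        stim=traces.stim[:, idx],
        iv=iv,
        levels=traces.protocol.levels.copy(),
    )
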