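"""Conductance-based model core for graded (non-spiking) neurons.

The model is a single-compartment Hodgkin-Huxley-type system with 16 ionic
current terms (11 potassium, 3 calcium, an ohmic leak and a sodium leak):

    C dV/dt = -sum_i I_i + I_ext,    I_i = g_i * m_i^p * h_i^p * (V - E_i)

with first-order gating kinetics dx/dt = (x_inf(V) - x) / tau(V).  There are
25 gating variables, so the ODE state is 26-dimensional.  Channel identities,
gate structure and kinetic templates are data, loaded from a YAML registry;
the parameter space (name, default, bounds, trainable flag) is assembled from
that registry in either ``small`` mode (47 trainable entries: conductances,
reversals, capacitance and initial conditions) or ``large`` mode (175
trainable entries: the small set plus the per-channel kinetic constants,
bounded at baseline +/-50%).

Units are mV, ms, pA, nS, pF throughout (nS*mV = pA, pA/pF = mV/ms).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "GateSpec",
    "ChannelSpec",
    "Registry",
    "load_registry",
    "ParamEntry",
    "ParameterSpace",
    "ParameterVector",
    "build_parameter_space",
    "assemble_parameter_vector",
    "ModelState",
    "IVProfile",
    "gating_steady_state",
    "gating_time_constant",
    "channel_current",
    "membrane_rhs",
    "steady_state_iv",
    "IV_VOLTAGES",
]


class ConfigError(ValueError):
    """Raised when the registry or a parameter table is inconsistent."""


# Clamp levels of the standard steady-state I-V protocol: -120:10:50 mV.
IV_VOLTAGES = np.arange(-120.0, 50.0 + 1e-9, 10.0)

# steady-state templates: id -> parameter slot names
SS_TEMPLATES = {
    "boltzmann": ("vhalf", "k"),
    "boltzmann_floor": ("vhalf", "k", "floor"),
    "const": ("value",),
    "cav_coupled": (),
}
# time-constant templates
TAU_TEMPLATES = {
    "const": ("tau",),
    "bell": ("tau_min", "tau_amp", "v_peak", "v_width"),
    "bell_skew": ("tau_min", "tau_amp", "v_peak", "w_left", "w_right"),
    "bell2": ("tau_min", "a1", "vp1", "w1", "a2", "vp2", "w2"),
}


def _sigmoid(z):
    with np.errstate(over="ignore"):  # saturates cleanly to 0
        return 1.0 / (1.0 + np.exp(-z))


def _ss_eval(template: str, p: dict, V):
    V = np.asarray(V, dtype=float)
    if template == "boltzmann":
        return _sigmoid((V - p["vhalf"]) / p["k"])
    if template == "boltzmann_floor":
        s = _sigmoid((V - p["vhalf"]) / p["k"])
        return p["floor"] + (1.0 - p["floor"]) * s
    if template == "const":
        return np.broadcast_to(np.float64(p["value"]), V.shape).copy() if V.shape else np.float64(p["value"])
    raise ConfigError(f"unknown steady-state template {template!r}")


def _tau_eval(template: str, p: dict, V):
    V = np.asarray(V, dtype=float)
    if template == "const":
        return np.broadcast_to(np.float64(p["tau"]), V.shape).copy() if V.shape else np.float64(p["tau"])
    if template == "bell":
        return p["tau_min"] + p["tau_amp"] * np.exp(-(((V - p["v_peak"]) / p["v_width"]) ** 2))
    if template == "bell_skew":
        w = np.where(V < p["v_peak"], p["w_left"], p["w_right"])
        return p["tau_min"] + p["tau_amp"] * np.exp(-(((V - p["v_peak"]) / w) ** 2))
    if template == "bell2":
        return (
            p["tau_min"]
            + p["a1"] * np.exp(-(((V - p["vp1"]) / p["w1"]) ** 2))
            + p["a2"] * np.exp(-(((V - p["vp2"]) / p["w2"]) ** 2))
        )
    raise ConfigError(f"unknown time-constant template {template!r}")


@dataclass(frozen=True)
class GateSpec:
    name: str
    kind: str  # activation | inactivation
    exponent: int
    trainable: bool
    ss_template: str
    ss_params: dict
    tau_template: str
    tau_params: dict
    coupled_to: str | None = None  # paired CaV channel for calcium-driven gates


@dataclass(frozen=True)
class ChannelSpec:
    name: str
    ion: str  # K | Ca | leak | Na-leak
    reversal: str  # E_K | E_Ca | E_Na | E_L
    g_default: float
    g_min: float
    g_max: float
    gates: tuple[GateSpec, ...] = ()


@dataclass(frozen=True)
class Registry:
    channels: tuple[ChannelSpec, ...]
    globals: dict

    @property
    def n_gates(self) -> int:
        return sum(len(c.gates) for c in self.channels)

    def channel(self, name: str) -> ChannelSpec:
        for c in self.channels:
            if c.name == name:
                return c
        raise ConfigError(f"unknown channel {name!r}")

    def activation_gate(self, channel_name: str) -> GateSpec:
        ch = self.channel(channel_name)
        for g in ch.gates:
            if g.kind == "activation" and g.ss_template != "cav_coupled":
                return g
        raise ConfigError(f"channel {channel_name!r} has no voltage activation gate")


def load_registry(path=None) -> Registry:
    """Load (and structurally validate) the channel registry."""
    if path is None:
        ref = importlib.resources.files("epgan").joinpath("data/channels.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    channels = []
    for ch in raw["channels"]:
        gates = []
        for gd in ch.get("gates", []):
            ss, tau = gd["ss"], gd["tau"]
            for tmpl_set, node, what in (
                (SS_TEMPLATES, ss, "steady-state"),
                (TAU_TEMPLATES, tau, "time-constant"),
            ):
                tid = node["template"]
                if tid not in tmpl_set:
                    raise ConfigError(f"unknown {what} template {tid!r}")
                missing = set(tmpl_set[tid]) - set(node.get("params", {}))
                if missing:
                    raise ConfigError(
                        f"{ch['name']}.{gd['name']}: missing {what} constants {sorted(missing)}"
                    )
            tau_vals = tau.get("params", {})
            if tau["template"] == "const" and tau_vals["tau"] <= 0:
                raise ConfigError(f"{ch['name']}.{gd['name']}: non-positive time constant")
            gates.append(
                GateSpec(
                    name=gd["name"],
                    kind=gd["kind"],
                    exponent=int(gd.get("exponent", 1)),
                    trainable=bool(gd.get("trainable", True)),
                    ss_template=ss["template"],
                    ss_params=dict(ss.get("params", {})),
                    tau_template=tau["template"],
                    tau_params=dict(tau_vals),
                    coupled_to=gd.get("coupled_to"),
                )
            )
        channels.append(
            ChannelSpec(
                name=ch["name"],
                ion=ch["ion"],
                reversal=ch["reversal"],
                g_default=float(ch["g"]["default"]),
                g_min=float(ch["g"]["min"]),
                g_max=float(ch["g"]["max"]),
                gates=tuple(gates),
            )
        )
    reg = Registry(channels=tuple(channels), globals=raw["globals"])
    _validate_registry(reg)
    return reg


def _validate_registry(reg: Registry) -> None:
    names = [c.name for c in reg.channels]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate channel names")
    if len(reg.channels) != 16:
        raise ConfigError(f"registry must define 16 channels, got {len(reg.channels)}")
    ions = [c.ion for c in reg.channels]
    counts = {ion: ions.count(ion) for ion in set(ions)}
    if counts.get("K") != 11 or counts.get("Ca") != 3:
        raise ConfigError(f"expected 11 K and 3 Ca channels, got {counts}")
    if reg.n_gates != 25:
        raise ConfigError(f"expected 25 gating variables, got {reg.n_gates}")
    for c in reg.channels:
        for g in c.gates:
            if g.ss_template == "cav_coupled":
                reg.activation_gate(g.coupled_to)  # must resolve


# ---------------------------------------------------------------------------
# parameter space
# ---------------------------------------------------------------------------

GROUPS = ("conductance", "reversal", "capacitance", "initial_condition", "kinetics")


@dataclass(frozen=True)
class ParamEntry:
    name: str
    default: float
    min: float
    max: float
    trainable: bool
    group: str


class ParameterSpace:
    """Ordered, named, bounded parameter table for one model mode."""

    def __init__(self, entries: list[ParamEntry], mode: str, registry: Registry):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate parameter names")
        for e in entries:
            if not (e.min <= e.default <= e.max):
                raise ConfigError(f"{e.name}: default {e.default} outside [{e.min}, {e.max}]")
            if e.trainable and not (e.min < e.max):
                raise ConfigError(f"{e.name}: degenerate bounds for trainable entry")
        self.entries = tuple(entries)
        self.mode = mode
        self.registry = registry
        self.names = tuple(names)
        self._index = {n: i for i, n in enumerate(names)}
        self.defaults = np.array([e.default for e in entries])
        self.lower = np.array([e.min for e in entries])
        self.upper = np.array([e.max for e in entries])
        self.trainable = np.array([e.trainable for e in entries], dtype=bool)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_trainable(self) -> int:
        return int(self.trainable.sum())

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ConfigError(f"unknown parameter {name!r}") from None

    def validate_values(self, values: np.ndarray) -> None:
        values = np.asarray(values)
        if values.shape[-1] != len(self):
            raise ConfigError(
                f"expected {len(self)} values, got {values.shape[-1]}"
            )
        bad = (values < self.lower - 1e-12) | (values > self.upper + 1e-12)
        if bad.any():
            offenders = [self.names[i] for i in np.unique(np.nonzero(bad)[-1])][:10]
            raise ConfigError(f"values out of bounds for: {offenders}")

    # affine map between raw units and the network's [-1, 1] scale
    def normalize(self, values: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(values) - self.lower) / (self.upper - self.lower) - 1.0

    def denormalize(self, z: np.ndarray) -> np.ndarray:
        return self.lower + (np.asarray(z) + 1.0) * 0.5 * (self.upper - self.lower)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "default": self.defaults,
                "min": self.lower,
                "max": self.upper,
                "trainable": self.trainable,
                "group": [e.group for e in self.entries],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_parameter_space(mode: str = "large", registry: Registry | None = None) -> ParameterSpace:
    """Assemble the ordered parameter table from the channel registry.

    Ordering: conductances (registry order), reversal potentials, membrane
    capacitance, initial conditions (V_0 then gate values), then per-channel
    kinetic constants.  In ``small`` mode the kinetics group is frozen at the
    registry baselines; in ``large`` mode it is trainable with bounds at
    baseline +/-50%.
    """
    if mode not in ("small", "large"):
        raise ConfigError(f"mode must be 'small' or 'large', got {mode!r}")
    reg = registry if registry is not None else load_registry()
    gl = reg.globals
    entries: list[ParamEntry] = []
    for c in reg.channels:
        entries.append(
            ParamEntry(f"{c.name}_g", c.g_default, c.g_min, c.g_max, True, "conductance")
        )
    for key in ("E_Ca", "E_K", "E_Na", "E_L"):
        r = gl["reversals"][key]
        entries.append(ParamEntry(key, r["default"], r["min"], r["max"], True, "reversal"))
    cm = gl["capacitance"]
    entries.append(ParamEntry("C_m", cm["default"], cm["min"], cm["max"], True, "capacitance"))
    v0 = gl["v_init"]
    entries.append(ParamEntry("V_0", v0["default"], v0["min"], v0["max"], True, "initial_condition"))
    for c in reg.channels:
        for g in c.gates:
            ic = gl["gate_init"]["activation" if g.kind == "activation" else "inactivation"]
            entries.append(
                ParamEntry(
                    f"{c.name}_{g.name}_0", ic["default"], ic["min"], ic["max"], True,
                    "initial_condition",
                )
            )
    kin_trainable = mode == "large"
    for c in reg.channels:
        for g in c.gates:
            if not g.trainable:
                continue  # fixed-kinetics gates never enter the table
            for slot in SS_TEMPLATES[g.ss_template]:
                val = float(g.ss_params[slot])
                entries.append(_kinetics_entry(f"{c.name}_{g.name}_{slot}", val, kin_trainable))
            for slot in TAU_TEMPLATES[g.tau_template]:
                val = float(g.tau_params[slot])
                entries.append(_kinetics_entry(f"{c.name}_{g.name}_{slot}", val, kin_trainable))
    return ParameterSpace(entries, mode, reg)


def _kinetics_entry(name: str, default: float, trainable: bool) -> ParamEntry:
    half = 0.5 * abs(default)
    return ParamEntry(name, default, default - half, default + half, trainable, "kinetics")


@dataclass
class ParameterVector:
    """Values for every entry of a :class:`ParameterSpace`."""

    space: ParameterSpace
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.space.validate_values(self.values)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.space.index(name)])

    def normalized(self) -> np.ndarray:
        return self.space.normalize(self.values)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.space.names))

    def with_updates(self, **updates) -> "ParameterVector":
        vals = self.values.copy()
        for name, v in updates.items():
            vals[self.space.index(name)] = v
        return ParameterVector(self.space, vals)


def assemble_parameter_vector(space: ParameterSpace, values=None) -> ParameterVector:
    """Build a vector from defaults, optionally overriding entries by name."""
    vals = space.defaults.copy()
    if values is None:
        pass
    elif isinstance(values, dict):
        unknown = set(values) - set(space.names)
        if unknown:
            raise ConfigError(f"unknown parameter names: {sorted(unknown)}")
        for name, v in values.items():
            vals[space.index(name)] = v
    else:
        values = np.asarray(values, dtype=float)
        if values.shape != vals.shape:
            raise ConfigError(f"expected {len(space)} values, got {values.shape}")
        vals = values.copy()
    return ParameterVector(space, vals)


# ---------------------------------------------------------------------------
# model state and dynamics
# ---------------------------------------------------------------------------

@dataclass
class ModelState:
    """ODE state: membrane potential plus the 25 gating variables."""

    V: float
    gates: np.ndarray = field(default_factory=lambda: np.zeros(25))

    @classmethod
    def from_params(cls, params: ParameterVector) -> "ModelState":
        space = params.space
        gate_vals = []
        for c in space.registry.channels:
            for g in c.gates:
                gate_vals.append(params[f"{c.name}_{g.name}_0"])
        return cls(V=params["V_0"], gates=np.array(gate_vals))


@dataclass
class IVProfile:
    """Steady-state currents (pA) at the clamp voltages (mV)."""

    voltages: np.ndarray
    currents: np.ndarray
    label: str | None = None

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.voltages.shape != self.currents.shape:
            raise ConfigError("voltage and current grids differ in length")
        if np.any(np.diff(self.voltages) <= 0):
            raise ConfigError("clamp voltages must be strictly increasing")


def _gate_constants(gate: GateSpec, channel: ChannelSpec, params: ParameterVector, which: str) -> dict:
    """Resolve a gate's kinetic constants from the table (trainable) or registry."""
    template = gate.ss_template if which == "ss" else gate.tau_template
    slots = SS_TEMPLATES[template] if which == "ss" else TAU_TEMPLATES[template]
    frozen = gate.ss_params if which == "ss" else gate.tau_params
    if not gate.trainable:
        return dict(frozen)
    out = {}
    for slot in slots:
        name = f"{channel.name}_{gate.name}_{slot}"
        try:
            out[slot] = params[name]
        except ConfigError:
            raise ConfigError(f"missing kinetics constant {name!r}") from None
    return out


def _find_channel_of_gate(reg: Registry, gate: GateSpec) -> ChannelSpec:
    for c in reg.channels:
        if gate in c.gates:
            return c
    raise ConfigError("gate does not belong to the registry")


def gating_steady_state(V, gate: GateSpec, params: ParameterVector):
    """x_inf(V) for one gate.

    Calcium-coupled gates relax toward the steady activation of their paired
    CaV channel, so their x_inf is the paired channel's activation curve.
    """
    reg = params.space.registry
    if gate.ss_template == "cav_coupled":
        src = reg.activation_gate(gate.coupled_to)
        return gating_steady_state(V, src, params)
    ch = _find_channel_of_gate(reg, gate)
    return _ss_eval(gate.ss_template, _gate_constants(gate, ch, params, "ss"), V)


def gating_time_constant(V, gate: GateSpec, params: ParameterVector):
    """tau(V) in ms for one gate; strictly positive by construction."""
    ch = _find_channel_of_gate(params.space.registry, gate)
    tau = _tau_eval(gate.tau_template, _gate_constants(gate, ch, params, "tau"), V)
    if np.any(np.asarray(tau) <= 0):
        raise ConfigError(f"non-positive time constant for {ch.name}_{gate.name}")
    return tau


def channel_current(channel: ChannelSpec, V, gates, params: ParameterVector):
    """I = g * prod(x^p) * (V - E_rev) in pA; positive is outward."""
    g = params[f"{channel.name}_g"]
    E = params[channel.reversal]
    open_frac = 1.0
    gates = np.atleast_1d(np.asarray(gates, dtype=float)) if len(channel.gates) else np.zeros(0)
    for x, gs in zip(gates, channel.gates):
        open_frac = open_frac * x**gs.exponent
    return g * open_frac * (np.asarray(V, dtype=float) - E)


def membrane_rhs(state: ModelState, I_ext: float, params: ParameterVector) -> ModelState:
    """Time derivative of the full 26-dimensional state (mV/ms, 1/ms)."""
    C = params["C_m"]
    if C <= 0:
        raise ConfigError("capacitance must be positive")
    reg = params.space.registry
    I_ion = 0.0
    dgates = np.empty_like(state.gates)
    i = 0
    for c in reg.channels:
        n = len(c.gates)
        I_ion += channel_current(c, state.V, state.gates[i : i + n], params)
        for j, g in enumerate(c.gates):
            xinf = gating_steady_state(state.V, g, params)
            tau = gating_time_constant(state.V, g, params)
            dgates[i + j] = (xinf - state.gates[i + j]) / tau
        i += n
    dV = (-I_ion + I_ext) / C
    return ModelState(V=dV, gates=dgates)


def steady_state_iv(params: ParameterVector, voltages=None) -> IVProfile:
    """Analytic steady-state I-V: gates fixed at x_inf(V), currents summed.

    Calcium-coupled gates sit at the steady activation of their paired CaV
    channel.  Equivalent (within integration error) to the terminal current
    of a long voltage-clamp simulation; the simulation path is retained as a
    cross-check oracle.
    """
    V = np.asarray(IV_VOLTAGES if voltages is None else voltages, dtype=float)
    reg = params.space.registry
    total = np.zeros_like(V)
    for c in reg.channels:
        xinf = [gating_steady_state(V, g, params) for g in c.gates]
        if xinf:
            total = total + channel_current(c, V, np.stack(xinf), params)
        else:
            total = total + channel_current(c, V, [], params)
    return IVProfile(voltages=V, currents=total)
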