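"""Serialization: parameter tables (CSV), I-V profiles (CSV), trace sets and
datasets (HDF5), run configs (YAML), model checkpoints (HDF5).

Every bulk artifact carries the seed and configuration needed to regenerate
it.  Readers raise errors naming the missing field/column rather than
failing downstream.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
import yaml

from .datagen import DatasetRecord
from .hh_core import IVProfile, ParameterSpace, ParameterVector, build_parameter_space
from .protocols import ClampProtocol, TraceSet, WindowedInput

__all__ = [
    "save_parameter_vector",
    "load_parameter_vector",
    "save_iv",
    "load_iv",
    "save_traceset",
    "load_traceset",
    "save_dataset",
    "load_dataset",
    "save_config",
    "load_config",
    "save_model",
    "load_model",
]


def _ds(grp, name, data):
    # track_times=False keeps files byte-identical across reruns
    grp.create_dataset(name, data=data, track_times=False)


def save_parameter_vector(pv: ParameterVector, path) -> None:
    pd.DataFrame({"name": pv.space.names, "value": pv.values}).to_csv(path, index=False)


def load_parameter_vector(space: ParameterSpace, path) -> ParameterVector:
    df = pd.read_csv(path)
    for col in ("name", "value"):
        if col not in df.columns:
            raise ValueError(f"parameter CSV missing column {col!r}")
    values = dict(zip(df["name"], df["value"]))
    missing = set(space.names) - set(values)
    if missing:
        raise ValueError(f"parameter CSV missing entries: {sorted(missing)[:5]}")
    return ParameterVector(space, np.array([values[n] for n in space.names]))


def save_iv(iv: IVProfile, path) -> None:
    pd.DataFrame({"voltage_mV": iv.voltages, "current_pA": iv.currents}).to_csv(
        path, index=False
    )


def load_iv(path) -> IVProfile:
    df = pd.read_csv(path)
    for col in ("voltage_mV", "current_pA"):
        if col not in df.columns:
            raise ValueError(f"I-V CSV missing column {col!r}")
    return IVProfile(df["voltage_mV"].to_numpy(), df["current_pA"].to_numpy())


def _write_protocol(grp, protocol: ClampProtocol) -> None:
    grp.attrs["kind"] = protocol.kind
    grp.attrs["duration"] = protocol.duration
    grp.attrs["stim_window"] = protocol.stim_window
    _ds(grp, "levels", protocol.levels)


def _read_protocol(grp) -> ClampProtocol:
    return ClampProtocol(
        kind=grp.attrs["kind"],
        levels=grp["levels"][...],
        duration=float(grp.attrs["duration"]),
        stim_window=tuple(grp.attrs["stim_window"]),
    )


def save_traceset(ts: TraceSet, path) -> None:
    with h5py.File(path, "w") as f:
        _ds(f, "time", ts.time)
        _ds(f, "V", ts.V)
        _ds(f, "stim", ts.stim)
        _ds(f, "diverged", ts.diverged)
        f.attrs["dt_ms"] = ts.dt_ms
        _write_protocol(f.create_group("protocol"), ts.protocol)


def load_traceset(path) -> TraceSet:
    with h5py.File(path, "r") as f:
        return TraceSet(
            time=f["time"][...], V=f["V"][...], stim=f["stim"][...],
            protocol=_read_protocol(f["protocol"]), dt_ms=float(f.attrs["dt_ms"]),
            diverged=f["diverged"][...],
        )


def save_dataset(records: list[DatasetRecord], path, seed=None, config=None) -> None:
    """HDF5 corpus: /records/{i}/(V, stim, V_noisy, iv, params, label, seed)."""
    if not records:
        raise ValueError("no records to save")
    space = records[0].params.space
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["n_records"] = len(records)
        meta.attrs["mode"] = space.mode
        if seed is not None:
            meta.attrs["seed"] = int(seed)
        meta.attrs["config"] = json.dumps(config if config is not None else {})
        root = f.create_group("records")
        for i, r in enumerate(records):
            g = root.create_group(str(i))
            _ds(g, "time", r.windowed.time)
            _ds(g, "V", r.windowed.V)
            _ds(g, "stim", r.windowed.stim)
            _ds(g, "V_noisy", r.v_noisy)
            _ds(g, "iv_voltages", r.iv.voltages)
            _ds(g, "iv_currents", r.iv.currents)
            _ds(g, "levels", r.windowed.levels)
            _ds(g, "params", r.params.values)
            g.attrs["label"] = r.label
            g.attrs["seed"] = r.seed


def load_dataset(path, space: ParameterSpace | None = None) -> list[DatasetRecord]:
    with h5py.File(path, "r") as f:
        if "records" not in f:
            raise ValueError("dataset file missing 'records' group")
        mode = f["meta"].attrs["mode"]
        if space is None:
            space = build_parameter_space(mode)
        elif space.mode != mode:
            raise ValueError(f"dataset is {mode!r} mode, given space is {space.mode!r}")
        out = []
        root = f["records"]
        for key in sorted(root, key=int):
            g = root[key]
            iv = IVProfile(g["iv_voltages"][...], g["iv_currents"][...],
                           label=g.attrs["label"])
            w = WindowedInput(
                time=g["time"][...], V=g["V"][...], stim=g["stim"][...], iv=iv,
                levels=g["levels"][...],
            )
            out.append(
                DatasetRecord(
                    windowed=w, v_noisy=g["V_noisy"][...], iv=iv,
                    params=ParameterVector(space, g["params"][...]),
                    label=str(g.attrs["label"]), seed=int(g.attrs["seed"]),
                )
            )
        return out


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_model(model, path) -> None:
    """Checkpoint: estimator hyperparameters + all network weights."""
    from .gan import EPGAN  # noqa: F401  (type context)

    model._check_fitted()
    params = model.get_params()
    params.pop("registry", None)
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in params.items()}
        )
        f.attrs["mode"] = model.space_.mode
        for name in ("encoder_", "generator_", "critic_"):
            grp = f.create_group(name)
            for i, arr in enumerate(getattr(model, name).state_dict()):
                _ds(grp, str(i), arr)


def load_model(path):
    from .gan import EPGAN, Critic, DifferentiableHH, Encoder, Generator
    from .hh_core import IV_VOLTAGES

    with h5py.File(path, "r") as f:
        cfg = json.loads(f.attrs["config"])
        for k in ("gen_widths", "critic_widths"):
            cfg[k] = tuple(cfg[k])
        model = EPGAN(**cfg)
        model.space_ = build_parameter_space(str(f.attrs["mode"]))
        model.diff_ = DifferentiableHH(model.space_)
        rng = np.random.default_rng(0)
        n_cond = model.latent_size + IV_VOLTAGES.size
        model.encoder_ = Encoder(model.latent_size, rng)
        model.generator_ = Generator(n_cond, model.diff_.n_train, rng,
                                     widths=model.gen_widths)
        model.critic_ = Critic(n_cond, model.diff_.n_train, rng,
                               widths=model.critic_widths)
        for name in ("encoder_", "generator_", "critic_"):
            grp = f[name]
            arrs = [grp[str(i)][...] for i in range(len(grp))]
            getattr(model, name).load_state_dict(arrs)
        model.history_ = []
        model.candidates_ = []
    return model
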