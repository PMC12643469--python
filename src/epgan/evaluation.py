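"""Metrics and input-ablation tools for judging inferred parameter sets.

The headline metric is the windowed membrane-potential RMSE: errors are
pooled over all stimulus levels separately within the pre-activation
[4, 5) s, mid-activation [5, 10] s and post-activation (10, 11] s windows
(boundary samples at exactly 5 s and 10 s belong to mid), then the three
window RMSEs are averaged.  Steady-state current agreement is the RMSE over
the 18 clamp voltages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hh_core import IVProfile, ParameterVector, steady_state_iv
from .protocols import (
    ClampProtocol,
    WindowedInput,
    simulate_current_clamp,
    window_traces,
)

__all__ = [
    "RMSEReport",
    "window_rmse",
    "iv_rmse",
    "ablate_traces",
    "ablate_iv",
    "evaluate_candidate",
    "benchmark_report",
]

_WINDOWS = {
    "pre": lambda t: (t >= 4.0) & (t < 5.0),
    "mid": lambda t: (t >= 5.0) & (t <= 10.0),
    "post": lambda t: (t > 10.0) & (t <= 11.0),
}


@dataclass
class RMSEReport:
    pre: float
    mid: float
    post: float
    mean: float
    iv: float | None = None

    def __post_init__(self):
        expected = (self.pre + self.mid + self.post) / 3.0
        if np.isfinite(expected) and abs(self.mean - expected) > 1e-9 * max(1.0, expected):
            raise ValueError("mean must equal (pre + mid + post)/3")


def _as_grid(x):
    """(time, V) from a TraceSet or WindowedInput."""
    return np.asarray(x.time), np.asarray(x.V)


def window_rmse(pred, truth) -> RMSEReport:
    """Pooled per-window V RMSE between two trace sets on one grid."""
    t_p, v_p = _as_grid(pred)
    t_t, v_t = _as_grid(truth)
    if t_p.shape != t_t.shape or not np.allclose(t_p, t_t, atol=1e-9):
        raise ValueError("prediction and truth are on different time grids")
    if v_p.shape != v_t.shape:
        raise ValueError("prediction and truth differ in trace count")
    out = {}
    for name, mask_fn in _WINDOWS.items():
        m = mask_fn(t_t)
        d = v_p[:, m] - v_t[:, m]
        out[name] = float(np.sqrt(np.mean(d * d))) if m.any() else 0.0
    return RMSEReport(
        pre=out["pre"], mid=out["mid"], post=out["post"],
        mean=(out["pre"] + out["mid"] + out["post"]) / 3.0,
    )


def iv_rmse(pred: IVProfile, truth: IVProfile) -> float:
    """RMSE over the steady-state currents (pA)."""
    if pred.voltages.shape != truth.voltages.shape or not np.allclose(
        pred.voltages, truth.voltages
    ):
        raise ValueError("I-V profiles are on different voltage grids")
    d = pred.currents - truth.currents
    return float(np.sqrt(np.mean(d * d)))


def ablate_traces(inp: WindowedInput, keep_fraction: float) -> WindowedInput:
    """Keep the floor(keep_fraction * L) traces with the lowest stimuli.

    Emulates recordings truncated from the top of the stimulus range; at
    least one trace is always retained.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    L = len(inp.levels)
    k = max(1, int(np.floor(keep_fraction * L)))
    order = np.argsort(inp.levels)
    keep = np.sort(order[:k])
    return WindowedInput(
        time=inp.time, V=inp.V[keep], stim=inp.stim[keep], iv=inp.iv,
        levels=inp.levels[keep],
    )


def ablate_iv(iv: IVProfile, keep_fraction: float) -> IVProfile:
    """Replace the first (1 - keep_fraction) currents by linear extrapolation.

    The lowest-voltage points are overwritten with the line through the two
    lowest retained points; the voltage grid is unchanged.  Exact on linear
    profiles.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    n = iv.voltages.size
    n_drop = int(np.round((1.0 - keep_fraction) * n))
    if n - n_drop < 2:
        raise ValueError("fewer than two retained I-V points")
    if n_drop == 0:
        return IVProfile(iv.voltages.copy(), iv.currents.copy(), label=iv.label)
    v0, v1 = iv.voltages[n_drop], iv.voltages[n_drop + 1]
    i0, i1 = iv.currents[n_drop], iv.currents[n_drop + 1]
    slope = (i1 - i0) / (v1 - v0)
    currents = iv.currents.copy()
    currents[:n_drop] = i0 + slope * (iv.voltages[:n_drop] - v0)
    return IVProfile(iv.voltages.copy(), currents, label=iv.label)


def evaluate_candidate(
    params: ParameterVector,
    truth: WindowedInput,
    protocol: ClampProtocol,
    dt: float = 0.1,
) -> RMSEReport:
    """Simulate a candidate under the truth's protocol and score it.

    Divergent simulations yield an infinite report rather than raising.
    """
    traces = simulate_current_clamp(params, protocol, dt=dt)
    iv_pred = steady_state_iv(params, truth.iv.voltages)
    if np.any(traces.diverged):
        return RMSEReport(np.inf, np.inf, np.inf, np.inf, iv=iv_rmse(iv_pred, truth.iv))
    pred_w = window_traces(traces, iv_pred)
    rep = window_rmse(pred_w, truth)
    rep.iv = iv_rmse(iv_pred, truth.iv)
    return rep


def benchmark_report(results: dict, confidence: float = 0.95):
    """Wide per-neuron table plus per-method summary statistics.

    ``results`` maps method name -> {neuron name -> RMSEReport}.  Returns
    (table, summary): the table has one V-RMSE row and one IV-RMSE row per
    method (columns = neurons plus a median column); the summary carries the
    median and a t-based confidence interval of the mean V-RMSE.
    """
    if not results:
        raise ValueError("no results to report")
    rows, summary = {}, {}
    for method, per_neuron in results.items():
        if not per_neuron:
            raise ValueError(f"method {method!r} has no results")
        neurons = list(per_neuron)
        v = np.array([per_neuron[n].mean for n in neurons])
        iv = np.array(
            [per_neuron[n].iv if per_neuron[n].iv is not None else np.nan for n in neurons]
        )
        rows[(method, "V_rmse_mV")] = dict(zip(neurons, v), median=float(np.median(v)))
        rows[(method, "IV_rmse_pA")] = dict(zip(neurons, iv), median=float(np.median(iv)))
        n = v.size
        m, s = float(np.mean(v)), float(np.std(v, ddof=1)) if n > 1 else 0.0
        half = (
            float(stats.t.ppf(0.5 + confidence / 2.0, n - 1) * s / np.sqrt(n))
            if n > 1
            else 0.0
        )
        summary[method] = {
            "median_v_rmse": float(np.median(v)),
            "mean_v_rmse": m,
            "ci_low": m - half,
            "ci_high": m + half,
            "median_iv_rmse": float(np.nanmedian(iv)) if np.isfinite(iv).any() else np.nan,
        }
    table = pd.DataFrame(rows).T
    table.index.names = ["method", "metric"]
    return table, summary
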