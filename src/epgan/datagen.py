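"""Constraint-based synthetic training-corpus generation.

Parameter sets are drawn from the biologically plausible box of the parameter
table (skew-normal around the baseline for conductances, uniform elsewhere),
then filtered in three steps: (1) the analytic steady-state I-V is classified
into one of three graded-response types (transient outward rectifier, outward
rectifier, bistable) and its dI/dV slopes must lie inside per-class bound
curves; (2) the full current-clamp response must stay inside a voltage window
(default -100 to 150 mV, closed interval) with no divergent trace; (3) the
windowed traces get additive Gaussian recording noise on V only.  Class
counts are balanced to within one record.

The per-class slope-bound curves stand in for confidence bands estimated
from experimental recordings; they are configuration data (piecewise-linear
in V) so measured bands can be dropped in without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hh_core import IVProfile, ParameterSpace, ParameterVector, steady_state_iv
from .protocols import (
    ClampProtocol,
    TraceSet,
    WindowedInput,
    get_preset,
    simulate_current_clamp,
    window_traces,
)

__all__ = [
    "CLASS_LABELS",
    "ConstraintSpec",
    "DatasetRecord",
    "GenerationError",
    "sample_parameter_set",
    "iv_slopes",
    "didv_check",
    "classify_iv",
    "vrange_check",
    "add_recording_noise",
    "generate_dataset",
]

CLASS_LABELS = ("transient_outward_rectifier", "outward_rectifier", "bistable")


class GenerationError(RuntimeError):
    """Raised when the rejection sampler cannot reach the requested corpus."""


def _default_didv_bounds() -> dict:
    # slope bounds in nS (= pA/mV) at the knot voltages; linear in between
    knots = np.array([-120.0, 50.0])
    flat = lambda lo, hi: {  # noqa: E731
        "v": knots, "lower": np.array([lo, lo]), "upper": np.array([hi, hi])
    }
    return {
        "transient_outward_rectifier": flat(-0.01, 50.0),
        "outward_rectifier": flat(-0.01, 50.0),
        "bistable": flat(-10.0, 50.0),
    }


@dataclass
class ConstraintSpec:
    """Acceptance constraints and classification thresholds."""

    didv_bounds: dict = field(default_factory=_default_didv_bounds)
    v_min: float = -100.0  # mV, closed interval
    v_max: float = 150.0
    neg_slope_tol: float = 0.01  # nS; interior slope below -tol marks bistability
    peak_factor: float = 1.5  # mid-voltage slope peak vs terminal slope

    def __post_init__(self):
        for label, b in self.didv_bounds.items():
            lo = np.interp(b["v"], b["v"], b["lower"])
            hi = np.interp(b["v"], b["v"], b["upper"])
            if np.any(lo >= hi):
                raise ValueError(f"{label}: lower bound must stay below upper bound")
        if self.v_min >= self.v_max:
            raise ValueError("v_min must be below v_max")


@dataclass
class DatasetRecord:
    """One training sample: windowed clean input, noisy V copy, truth parameters."""

    windowed: WindowedInput  # noiseless
    v_noisy: np.ndarray  # (n_levels, 350) mV
    iv: IVProfile  # noiseless
    params: ParameterVector
    label: str
    seed: int


def sample_parameter_set(space: ParameterSpace, rng: np.random.Generator,
                         skew_shape: float = 4.0) -> ParameterVector:
    """Draw one in-bounds parameter vector.

    Conductances: skew-normal located at the baseline with scale
    (max-min)/6 and shape ``skew_shape`` (right-skewed by default), truncated
    to the bounds by resampling.  Other trainable entries: uniform on
    [min, max].  Frozen entries stay at their defaults.
    """
    vals = space.defaults.copy()
    groups = np.array([e.group for e in space.entries])
    for i in np.nonzero(space.trainable)[0]:
        lo, hi = space.lower[i], space.upper[i]
        if groups[i] == "conductance":
            scale = (hi - lo) / 6.0
            for _ in range(1000):
                v = stats.skewnorm.rvs(
                    skew_shape, loc=space.defaults[i], scale=scale, random_state=rng
                )
                if lo <= v <= hi:
                    break
            else:  # pragma: no cover - bounds always contain the location
                v = space.defaults[i]
            vals[i] = v
        else:
            vals[i] = rng.uniform(lo, hi)
    return ParameterVector(space, vals)


def iv_slopes(iv: IVProfile) -> np.ndarray:
    """dI/dV in nS: central differences at interior points, one-sided at ends."""
    return np.gradient(iv.currents, iv.voltages)


def didv_check(iv: IVProfile, spec: ConstraintSpec, cls: str) -> bool:
    """All slopes inside the class's [lower, upper] bound curves (inclusive)."""
    if cls not in spec.didv_bounds:
        raise ValueError(f"no slope bounds configured for class {cls!r}")
    b = spec.didv_bounds[cls]
    s = iv_slopes(iv)
    lo = np.interp(iv.voltages, b["v"], b["lower"])
    hi = np.interp(iv.voltages, b["v"], b["upper"])
    return bool(np.all(s >= lo) and np.all(s <= hi))


def classify_iv(iv: IVProfile, spec: ConstraintSpec | None = None) -> str:
    """Assign a graded-response type from the steady-state I-V shape.

    bistable: some interior slope is negative (N-shaped I-V, two stable
    branches); transient outward rectifier: slope profile is non-monotone
    with a mid-voltage peak exceeding the terminal slope by ``peak_factor``;
    outward rectifier: otherwise (slope keeps growing toward depolarization).
    """
    spec = spec if spec is not None else ConstraintSpec()
    s = iv_slopes(iv)
    if np.min(s[1:-1]) < -spec.neg_slope_tol:
        return "bistable"
    interior = s[:-2]
    j = int(np.argmax(interior))
    if interior[j] > spec.peak_factor * s[-1]:
        return "transient_outward_rectifier"
    return "outward_rectifier"


def vrange_check(traces, spec: ConstraintSpec) -> bool:
    """Every sample of every trace inside [v_min, v_max] and none divergent."""
    V = traces.V
    diverged = getattr(traces, "diverged", None)
    if diverged is not None and np.any(diverged):
        return False
    if np.any(~np.isfinite(V)):
        return False
    return bool(np.all(V >= spec.v_min) and np.all(V <= spec.v_max))


def add_recording_noise(windowed: WindowedInput, sigma: float,
                        rng: np.random.Generator) -> WindowedInput:
    """Additive i.i.d. zero-mean Gaussian on the V samples only."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    V = windowed.V + (rng.normal(0.0, sigma, size=windowed.V.shape) if sigma > 0 else 0.0)
    return WindowedInput(
        time=windowed.time, V=V, stim=windowed.stim, iv=windowed.iv,
        levels=windowed.levels,
    )


def generate_dataset(
    n: int,
    space: ParameterSpace,
    constraints: ConstraintSpec | None = None,
    protocol: ClampProtocol | None = None,
    rng: np.random.Generator | int | None = None,
    dt: float = 0.1,
    noise_sigma: float = 1.0,
    iv_voltages=None,
    max_attempt_factor: int = 60,
    return_stats: bool = False,
):
    """Rejection-sample ``n`` constraint-satisfying records, class-balanced.

    Pipeline per attempt: sample parameters -> analytic steady-state I-V ->
    classify + slope-bound check (cheap prefilter) -> current-clamp
    simulation -> voltage-range check -> window -> additive noise.  Per-class
    counts land within one of n/3.  Raises :class:`GenerationError` with
    per-class acceptance statistics if the attempt budget is exhausted.
    """
    if n < 3:
        raise ValueError("need n >= 3 for class balancing")
    constraints = constraints if constraints is not None else ConstraintSpec()
    protocol = protocol if protocol is not None else get_preset("simulated_cc")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    base, extra = divmod(n, 3)
    quota = {lbl: base + (1 if i < extra else 0) for i, lbl in enumerate(CLASS_LABELS)}
    counts = {lbl: 0 for lbl in CLASS_LABELS}
    attempts = {lbl: 0 for lbl in CLASS_LABELS}
    records: list[DatasetRecord] = []
    max_attempts = max(30, max_attempt_factor * n)
    total_attempts = 0
    while len(records) < n:
        if total_attempts >= max_attempts:
            rates = {
                lbl: (counts[lbl] / attempts[lbl] if attempts[lbl] else 0.0)
                for lbl in CLASS_LABELS
            }
            raise GenerationError(
                f"acceptance too low after {total_attempts} attempts; "
                f"per-class acceptance rates: {rates}"
            )
        total_attempts += 1
        params = sample_parameter_set(space, rng)
        iv = steady_state_iv(params, iv_voltages)
        label = classify_iv(iv, constraints)
        attempts[label] += 1
        if counts[label] >= quota[label]:
            continue
        if not didv_check(iv, constraints, label):
            continue
        traces = simulate_current_clamp(params, protocol, dt=dt)
        if not vrange_check(traces, constraints):
            continue
        windowed = window_traces(traces, IVProfile(iv.voltages, iv.currents, label=label))
        noisy = add_recording_noise(windowed, noise_sigma, rng)
        records.append(
            DatasetRecord(
                windowed=windowed, v_noisy=noisy.V, iv=iv, params=params,
                label=label, seed=total_attempts,
            )
        )
        counts[label] += 1
    if return_stats:
        stats_out = {
            "attempts": dict(attempts), "accepted": dict(counts),
            "total_attempts": total_attempts,
        }
        return records, stats_out
    return records
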