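"""Model-informed generative estimation of HH parameters (EP-GAN).

A recurrent encoder compresses a set of current-clamp traces (each 350 V
samples concatenated with the matching 350-sample stimulus trace, one GRU
step per stimulus level) into a 1024-dimensional latent vector, which is
concatenated with the normalized 18-point steady-state current profile to
form the conditioning vector.  A four-layer generator maps conditioning to
parameters scaled to [-1, 1] (affinely rescaled into the parameter bounds, so
generated parameters are in-bounds by construction).  A critic scores
(conditioning, parameters) pairs and is trained as a Wasserstein critic with
gradient penalty:

    J_D = E[D(p_fake)] - E[D(p_real)] + lambda * E[(||grad_p D(p_hat)|| - 1)^2]

The generator minimizes the adversarial term plus two model-informed
reconstruction losses: an L1 loss on the membrane potential rebuilt from the
generated parameters by teacher-forced forward-Euler integration (the model
derivative is evaluated at the ground-truth V, gate states are co-integrated
under the ground-truth voltage, and V is rebuilt cumulatively from the window
start), and an L1 loss on the analytic steady-state currents.  Both are part
of the generator's computation graph, so the membrane equation itself shapes
the gradients.

During training a linearly decaying fraction of encoder steps is dropped
(75% -> 0%), which makes the trained network robust to recordings with
missing stimulus levels.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from . import _autodiff as ad
from ._autodiff import Tensor, grad
from ._nn import GRU, Adam, LayerNorm, Linear, Module, leaky_relu
from .hh_core import (
    IV_VOLTAGES,
    ParameterSpace,
    ParameterVector,
    build_parameter_space,
)
from .evaluation import evaluate_candidate
from .protocols import ClampProtocol, WindowedInput, get_preset

__all__ = [
    "MaskSchedule",
    "TrainConfig",
    "mask_rate",
    "Encoder",
    "Generator",
    "Critic",
    "DifferentiableHH",
    "discriminator_loss",
    "generator_loss",
    "reconstruct_voltage",
    "EPGAN",
    "train",
    "infer",
    "select_best_candidate",
]


# ---------------------------------------------------------------------------
# masking schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskSchedule:
    total_epochs: int
    initial_rate: float = 0.75
    final_rate: float = 0.0


def mask_rate(epoch: int, schedule: MaskSchedule) -> float:
    """Linear interpolation from the initial to the final masking rate."""
    E = schedule.total_epochs
    if not 0 <= epoch < E:
        raise ValueError(f"epoch {epoch} outside [0, {E})")
    if E == 1:
        return schedule.initial_rate
    frac = epoch / (E - 1)
    return schedule.initial_rate + frac * (schedule.final_rate - schedule.initial_rate)


@dataclass
class TrainConfig:
    """Hyperparameters of one training run (defaults are the shipped ones)."""

    mode: str = "small"
    epochs: int = 20
    batch_size: int = 16
    critic_steps: int = 5
    lam: float = 10.0  # gradient-penalty weight
    lr: float = 1e-4
    h: float = 20.0  # reconstruction Euler step, ms (the 50 Hz grid)
    anchor_every: int | None = 1  # re-anchor the Euler rebuild at truth every k samples
    eval_cadence: int = 1
    mask_initial: float = 0.75
    w_adv: float = 1.0
    w_v: float = 1.0
    w_iv: float = 20.0
    w_logit: float = 1.0  # keeps pre-tanh outputs out of saturation
    latent_size: int = 1024
    gen_widths: tuple = (1024, 1024, 512)
    critic_widths: tuple = (512, 256, 128)
    v_scale: float = 100.0  # mV, input normalization
    stim_scale: float = 35.0  # pA
    iv_scale: float = 100.0  # pA
    seed: int = 0


# ---------------------------------------------------------------------------
# network modules
# ---------------------------------------------------------------------------

class Encoder(Module):
    """GRU over (V || stimulus) steps; final hidden state + normalized I-V."""

    def __init__(self, n_latent: int, rng: np.random.Generator, n_step: int = 700):
        self.gru = GRU(n_step, n_latent, rng)

    def __call__(self, v_norm, stim_norm, iv_norm, keep=None) -> Tensor:
        """v_norm, stim_norm: (B, L, 350) arrays; iv_norm: (B, 18) array.

        ``keep`` selects the unmasked stimulus levels (ascending); None keeps
        all.  Raises if every level would be masked.
        """
        B, L, _ = v_norm.shape
        keep = list(range(L)) if keep is None else sorted(keep)
        if len(keep) == 0:
            raise ValueError("at least one trace must remain unmasked")
        steps = [
            ad.concatenate(
                [Tensor(np.ascontiguousarray(v_norm[:, l, :])),
                 Tensor(np.ascontiguousarray(stim_norm[:, l, :]))], axis=1
            )
            for l in keep
        ]
        h = self.gru(steps)
        return ad.concatenate([h, Tensor(np.asarray(iv_norm))], axis=1)


class Generator(Module):
    """Four dense layers, layer normalization after the first two, tanh out."""

    def __init__(self, n_cond: int, n_out: int, rng, widths=(1024, 1024, 512)):
        w1, w2, w3 = widths
        self.l1 = Linear(n_cond, w1, rng)
        self.n1 = LayerNorm(w1)
        self.l2 = Linear(w1, w2, rng)
        self.n2 = LayerNorm(w2)
        self.l3 = Linear(w2, w3, rng)
        self.l4 = Linear(w3, n_out, rng)

    def __call__(self, cond: Tensor) -> Tensor:
        x = leaky_relu(self.n1(self.l1(cond)))
        x = leaky_relu(self.n2(self.l2(x)))
        x = leaky_relu(self.l3(x))
        logits = self.l4(x)
        self.last_logits = logits  # read by the logit regularizer
        return ad.tanh(logits)


class Critic(Module):
    """Four affine layers with leaky-rectifier activations; scalar output."""

    def __init__(self, n_cond: int, n_params: int, rng, widths=(512, 256, 128)):
        w1, w2, w3 = widths
        self.l1 = Linear(n_cond + n_params, w1, rng)
        self.l2 = Linear(w1, w2, rng)
        self.l3 = Linear(w2, w3, rng)
        self.l4 = Linear(w3, 1, rng)

    def __call__(self, cond: Tensor, p_norm: Tensor) -> Tensor:
        x = ad.concatenate([cond, p_norm], axis=1)
        x = leaky_relu(self.l1(x))
        x = leaky_relu(self.l2(x))
        x = leaky_relu(self.l3(x))
        return self.l4(x).reshape(-1)


# ---------------------------------------------------------------------------
# differentiable model evaluation
# ---------------------------------------------------------------------------

def _exp_relax_scan(xinf: Tensor, decay: Tensor, x0: Tensor) -> Tensor:
    """Gate trajectories x[t] = xinf[t-1] + (x[t-1]-xinf[t-1])*decay[t-1].

    One custom linear-scan primitive with a hand-written adjoint recursion;
    first-order differentiable in all three inputs (that is all the
    reconstruction loss needs).
    Shapes: xinf, decay (B, L, T, G); x0 (B, G).
    """
    xi, de, x0d = xinf.data, decay.data, x0.data
    B, L, T, G = xi.shape
    x = np.empty_like(xi)
    x[:, :, 0, :] = x0d[:, None, :]
    for t in range(1, T):
        x[:, :, t, :] = xi[:, :, t - 1, :] + (x[:, :, t - 1, :] - xi[:, :, t - 1, :]) * de[:, :, t - 1, :]

    cache: dict[int, tuple] = {}

    def adjoint(g: Tensor):
        if id(g) not in cache:
            gd = g.data
            lam = np.ascontiguousarray(gd[:, :, T - 1, :])
            g_xi = np.zeros_like(xi)
            g_de = np.zeros_like(de)
            for t in range(T - 1, 0, -1):
                d_prev = de[:, :, t - 1, :]
                g_xi[:, :, t - 1, :] = lam * (1.0 - d_prev)
                g_de[:, :, t - 1, :] = lam * (x[:, :, t - 1, :] - xi[:, :, t - 1, :])
                lam = gd[:, :, t - 1, :] + lam * d_prev
            cache[id(g)] = (g_xi, g_de, lam.sum(axis=1))
        return cache[id(g)]

    return Tensor(
        x,
        parents=(xinf, decay, x0),
        vjps=(
            lambda g: Tensor(adjoint(g)[0]),
            lambda g: Tensor(adjoint(g)[1]),
            lambda g: Tensor(adjoint(g)[2]),
        ),
    )


class DifferentiableHH:
    """Autodiff-ready evaluation of the membrane model for a parameter batch.

    Precomputes, from a :class:`ParameterSpace`, the index maps that turn a
    normalized trainable-parameter tensor into the full parameter vector and
    the per-gate kinetic constants (frozen entries become constants in the
    graph; calcium-coupled gates read their paired CaV activation curve).
    """

    def __init__(self, space: ParameterSpace):
        from .hh_core import SS_TEMPLATES, TAU_TEMPLATES

        self.space = space
        reg = space.registry
        n = len(space)
        t_idx = np.nonzero(space.trainable)[0]
        self.n_train = t_idx.size
        # scatter matrix: full = p_train @ S + d0
        S = np.zeros((self.n_train, n))
        S[np.arange(self.n_train), t_idx] = 1.0
        d0 = space.defaults.copy()
        d0[t_idx] = 0.0
        self._S, self._d0 = S, d0
        self._lo_t = space.lower[t_idx]
        self._hi_t = space.upper[t_idx]

        def source(channel, gate, which):
            """[(col or -1, const)] per slot, coupling resolved for ss."""
            if which == "ss" and gate.ss_template == "cav_coupled":
                src_ch = reg.channel(gate.coupled_to)
                src = reg.activation_gate(gate.coupled_to)
                return src.ss_template, source(src_ch, src, "ss")[1]
            tmpl = gate.ss_template if which == "ss" else gate.tau_template
            slots = (SS_TEMPLATES if which == "ss" else TAU_TEMPLATES)[tmpl]
            frozen = gate.ss_params if which == "ss" else gate.tau_params
            out = []
            for s in slots:
                if gate.trainable:
                    out.append((space.index(f"{channel.name}_{gate.name}_{s}"), 0.0))
                else:
                    out.append((-1, float(frozen[s])))
            return tmpl, out

        ss_info, tau_info = [], []
        self.exps, ch_of_gate = [], []
        self.idx_x0 = []
        self.ch_g_idx, self.ch_E_idx, self.ch_gates = [], [], []
        gi = 0
        for ci, c in enumerate(reg.channels):
            self.ch_g_idx.append(space.index(f"{c.name}_g"))
            self.ch_E_idx.append(space.index(c.reversal))
            gl = []
            for gate in c.gates:
                ss_info.append(source(c, gate, "ss"))
                tau_info.append((gate.tau_template, source(c, gate, "tau")[1]))
                self.exps.append(float(gate.exponent))
                self.idx_x0.append(space.index(f"{c.name}_{gate.name}_0"))
                ch_of_gate.append(ci)
                gl.append(gi)
                gi += 1
            self.ch_gates.append(gl)
        self.n_gates = gi
        self.idx_C = space.index("C_m")
        self.idx_V0 = space.index("V_0")
        self.iv_voltages = IV_VOLTAGES.copy()

        def group(info):
            by = {}
            for i, (tmpl, slots) in enumerate(info):
                by.setdefault(tmpl, []).append((i, slots))
            out = {}
            for tmpl, items in by.items():
                gates = np.array([i for i, _ in items])
                n_slots = len(items[0][1])
                cols = np.zeros((n_slots, len(items)), dtype=np.int64)
                mask = np.zeros((n_slots, len(items)))
                const = np.zeros((n_slots, len(items)))
                for j, (_, slots) in enumerate(items):
                    for s, (col, cv) in enumerate(slots):
                        if col >= 0:
                            cols[s, j], mask[s, j] = col, 1.0
                        else:
                            const[s, j] = cv
                out[tmpl] = (gates, cols, mask, const)
            return out

        self._ss_groups = group(ss_info)
        self._tau_groups = group(tau_info)

    # -- helpers ------------------------------------------------------------
    def full_params(self, p_norm: Tensor) -> Tensor:
        """(B, n_trainable) in [-1, 1] -> (B, n_entries) in raw units."""
        raw = self._lo_t + (p_norm + 1.0) * 0.5 * (self._hi_t - self._lo_t)
        return ad.matmul(raw, Tensor(self._S)) + Tensor(self._d0)

    def _slot(self, P: Tensor, cols, mask, const, shape) -> Tensor:
        v = P[:, cols] * Tensor(mask) + Tensor(const)
        return v.reshape(shape)

    def _curves(self, P: Tensor, V_nd: np.ndarray, want_tau: bool):
        """x_inf (and tau) tensors of shape (B, *V_mid_dims, n_gates)."""
        B = P.shape[0]
        mid = V_nd.shape[1:]
        slot_shape = (B,) + (1,) * len(mid) + (-1,)
        Vt = Tensor(V_nd[..., None])  # (B|1, *mid, 1)

        def assemble(groups, eval_one):
            parts, order = [], []
            for tmpl, (gates, cols, mask, const) in groups.items():
                slots = [
                    self._slot(P, cols[s], mask[s], const[s], slot_shape)
                    for s in range(cols.shape[0])
                ]
                parts.append(eval_one(tmpl, slots, Vt))
                order.append(gates)
            perm = np.concatenate(order)
            inv = np.argsort(perm)
            return ad.concatenate(parts, axis=-1)[..., inv]

        def ss_eval(tmpl, p, Vt):
            if tmpl == "boltzmann":
                return ad.sigmoid((Vt - p[0]) / p[1])
            if tmpl == "boltzmann_floor":
                return p[2] + (1.0 - p[2]) * ad.sigmoid((Vt - p[0]) / p[1])
            if tmpl == "const":
                return p[0] + Vt * 0.0
            raise AssertionError(tmpl)

        def tau_eval(tmpl, p, Vt):
            if tmpl == "const":
                return p[0] + Vt * 0.0
            if tmpl == "bell":
                z = (Vt - p[2]) / p[3]
                return p[0] + p[1] * ad.exp(-(z * z))
            if tmpl == "bell_skew":
                cond = np.broadcast_to(Vt.data < p[2].data, np.broadcast_shapes(
                    Vt.data.shape, p[2].data.shape))
                w = ad.where_const(cond, ad.broadcast_to(p[3], cond.shape),
                                   ad.broadcast_to(p[4], cond.shape))
                z = (Vt - p[2]) / w
                return p[0] + p[1] * ad.exp(-(z * z))
            if tmpl == "bell2":
                z1 = (Vt - p[2]) / p[3]
                z2 = (Vt - p[5]) / p[6]
                return p[0] + p[1] * ad.exp(-(z1 * z1)) + p[4] * ad.exp(-(z2 * z2))
            raise AssertionError(tmpl)

        xinf = assemble(self._ss_groups, ss_eval)
        tau = assemble(self._tau_groups, tau_eval) if want_tau else None
        return xinf, tau

    def _ionic(self, P: Tensor, x: Tensor, V_nd: np.ndarray) -> Tensor:
        """Summed ionic current (B, *mid) from gate values x (B, *mid, G)."""
        B = P.shape[0]
        mid = V_nd.shape[1:]
        scal = (B,) + (1,) * len(mid)
        Vt = Tensor(V_nd)
        total = None
        for ci in range(len(self.ch_g_idx)):
            g = P[:, self.ch_g_idx[ci]].reshape(scal)
            E = P[:, self.ch_E_idx[ci]].reshape(scal)
            open_frac = None
            for gi in self.ch_gates[ci]:
                xg = x[..., gi]
                if self.exps[gi] != 1.0:
                    xg = xg ** self.exps[gi]
                open_frac = xg if open_frac is None else open_frac * xg
            I = g * (Vt - E) if open_frac is None else g * open_frac * (Vt - E)
            total = I if total is None else total + I
        return total

    # -- static fast path ----------------------------------------------------
    # With frozen kinetics (small mode) and steady gate initialization, the
    # teacher-forced gate trajectories do not depend on the generated
    # parameters at all, so the per-channel open fractions can be computed
    # once per record outside the autodiff graph.
    @property
    def kinetics_static(self) -> bool:
        kin = [e.group == "kinetics" for e in self.space.entries]
        return not np.any(self.space.trainable & np.array(kin))

    def static_open_fractions(self, v_nd: np.ndarray, h: float | None = None,
                              dtype=np.float32) -> np.ndarray:
        """Per-channel open fractions (..., 16) at frozen kinetics.

        With ``h`` given, gates are co-integrated under the teacher voltage
        on the h-grid from their steady state; without it they sit at x_inf
        (the steady-state I-V case).
        """
        P1 = Tensor(self.space.defaults[None, :])
        xinf_t, tau_t = self._curves(P1, v_nd, want_tau=h is not None)
        xinf = xinf_t.data
        if h is None:
            x = xinf
        else:
            decay = np.exp(-(h / tau_t.data))
            x = np.empty_like(xinf)
            x[..., 0, :] = xinf[..., 0, :]
            for t in range(1, x.shape[-2]):
                x[..., t, :] = (
                    xinf[..., t - 1, :]
                    + (x[..., t - 1, :] - xinf[..., t - 1, :]) * decay[..., t - 1, :]
                )
        out = np.ones(x.shape[:-1] + (len(self.ch_g_idx),), dtype=dtype)
        for ci, gates in enumerate(self.ch_gates):
            for gi in gates:
                out[..., ci] *= x[..., gi] ** self.exps[gi]
        return out

    def _ionic_static(self, P: Tensor, open_arr: np.ndarray, V_nd: np.ndarray) -> Tensor:
        B = P.shape[0]
        mid = V_nd.shape[1:]
        scal = (B,) + (1,) * len(mid)
        Vt = Tensor(V_nd)
        total = None
        for ci in range(len(self.ch_g_idx)):
            g = P[:, self.ch_g_idx[ci]].reshape(scal)
            E = P[:, self.ch_E_idx[ci]].reshape(scal)
            I = g * Tensor(np.asarray(open_arr[..., ci], dtype=np.float64)) * (Vt - E)
            total = I if total is None else total + I
        return total

    # -- public evaluation --------------------------------------------------
    def reconstruct(self, P: Tensor, v_truth: np.ndarray, stim: np.ndarray,
                    h: float, anchor_every: int | None = None,
                    gate_init: str = "steady",
                    open_static: np.ndarray | None = None) -> Tensor:
        """Teacher-forced Euler reconstruction of V on the 350-point grid.

        The derivative is evaluated at the ground-truth V at every step
        (gates co-integrated under the ground-truth voltage) and V is rebuilt
        by forward Euler from the ground-truth value at each anchor:
        ``anchor_every=None`` uses a single segment from the window start,
        ``anchor_every=k`` re-anchors at every k-th sample (k=1 is one-step-
        ahead prediction, which keeps truncation error local instead of
        accumulating it over the window).  ``gate_init='steady'`` starts the
        co-integrated gates at x_inf of the first teacher sample — the state
        the true gates have relaxed to after the pre-stimulus stabilization
        period — while ``'params'`` starts them at the generated initial
        conditions.  Fully differentiable in P.
        """
        B, L, T = v_truth.shape
        if open_static is not None:
            if not (self.kinetics_static and gate_init == "steady"):
                raise ValueError(
                    "static open fractions require frozen kinetics and steady init"
                )
            I_ion = self._ionic_static(P, open_static, v_truth)
        else:
            xinf, tau = self._curves(P, v_truth, want_tau=True)
            decay = ad.exp(-(h / tau))
            if gate_init == "steady":
                x = _exp_relax_scan(xinf, decay, xinf[:, :, 0, :].mean(axis=1))
                # xinf at t=0 is level-independent (same V at window start),
                # so the mean over levels equals each level's value
            elif gate_init == "params":
                x = _exp_relax_scan(xinf, decay, P[:, np.asarray(self.idx_x0)])
            else:
                raise ValueError("gate_init must be 'steady' or 'params'")
            I_ion = self._ionic(P, x, v_truth)
        C = P[:, self.idx_C].reshape((B, 1, 1))
        dVdt = (Tensor(stim) - I_ion) / C  # mV/ms
        cum = ad.concatenate(
            [Tensor(np.zeros((B, L, 1))), ad.cumsum(dVdt[:, :, :-1] * h, axis=2)],
            axis=2,
        )
        k = T if anchor_every is None else int(anchor_every)
        if k < 1:
            raise ValueError("anchor_every must be >= 1")
        # sample t belongs to the segment anchored at the k-multiple below t-1,
        # so k=1 is one-step-ahead prediction and k=T one segment per window
        a_idx = np.zeros(T, dtype=int)
        a_idx[1:] = ((np.arange(1, T) - 1) // k) * k
        anchors_v = Tensor(np.ascontiguousarray(v_truth[:, :, a_idx]))
        return anchors_v + cum - cum[:, :, a_idx]

    def steady_iv(self, P: Tensor, voltages: np.ndarray | None = None) -> Tensor:
        """Analytic steady-state currents (B, n_voltages); differentiable."""
        V = self.iv_voltages if voltages is None else np.asarray(voltages, float)
        V_nd = V[None, :]
        if self.kinetics_static:
            key = V.tobytes()
            if getattr(self, "_iv_open_key", None) != key:
                self._iv_open = self.static_open_fractions(V_nd, dtype=np.float64)
                self._iv_open_key = key
            return self._ionic_static(P, self._iv_open, V_nd)
        xinf, _ = self._curves(P, V_nd, want_tau=False)
        return self._ionic(P, xinf, V_nd)


def reconstruct_voltage(params: ParameterVector, truth: WindowedInput,
                        h: float = 20.0, anchor_every: int | None = None,
                        gate_init: str = "steady") -> np.ndarray:
    """Convenience wrapper: teacher-forced reconstruction for one neuron."""
    diff = DifferentiableHH(params.space)
    p_norm = Tensor(params.normalized()[params.space.trainable][None, :])
    P = diff.full_params(p_norm)
    out = diff.reconstruct(P, truth.V[None, ...], truth.stim[None, ...], h,
                           anchor_every=anchor_every, gate_init=gate_init)
    return out.data[0]


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def discriminator_loss(critic: Critic, cond: Tensor, real_norm: np.ndarray,
                       fake_norm: np.ndarray, lam: float,
                       rng: np.random.Generator):
    """WGAN-GP critic loss with per-sample random interpolates.

    Returns (loss, parts).  The penalty gradient is taken with respect to the
    interpolated parameter vectors (second-order graph).
    """
    real = Tensor(real_norm)
    fake = Tensor(fake_norm)
    B = real_norm.shape[0]
    w_dist = ad.tmean(critic(cond, fake)) - ad.tmean(critic(cond, real))
    t = rng.uniform(size=(B, 1))
    p_hat = Tensor(t * fake_norm + (1.0 - t) * real_norm, requires_grad=True)
    d_hat = critic(cond, p_hat)
    g_hat = grad(ad.tsum(d_hat), p_hat, create_graph=True)
    norm = ad.sqrt(ad.tsum(g_hat * g_hat, axis=1) + 1e-12)
    penalty = ad.tmean((norm - 1.0) ** 2)
    loss = w_dist + lam * penalty
    return loss, {
        "wasserstein": float(w_dist.data),
        "penalty": float(penalty.data),
    }


def generator_loss(critic: Critic, cond: Tensor, fake: Tensor,
                   diff: DifferentiableHH, v_clean: np.ndarray,
                   stim: np.ndarray, iv_true: np.ndarray, cfg: TrainConfig,
                   logits: Tensor | None = None,
                   open_static: np.ndarray | None = None):
    """Adversarial + V-reconstruction + I-V reconstruction losses.

    J_V and J_IV are L1 sums over samples (per trace set / profile), averaged
    over the batch.  Returns (total, parts).
    """
    adv = -ad.tmean(critic(cond, fake))
    P = diff.full_params(fake)
    v_rec = diff.reconstruct(P, v_clean, stim, cfg.h, anchor_every=cfg.anchor_every,
                             open_static=open_static)
    j_v = ad.tmean(ad.tsum(ad.absolute(Tensor(v_clean) - v_rec), axis=(1, 2)))
    iv_pred = diff.steady_iv(P)
    j_iv = ad.tmean(ad.tsum(ad.absolute(Tensor(iv_true) - iv_pred), axis=1))
    total = cfg.w_adv * adv + cfg.w_v * j_v + cfg.w_iv * j_iv
    if cfg.w_logit and logits is not None:
        total = total + cfg.w_logit * ad.tmean(logits * logits)
    return total, {
        "j_adv": float(adv.data),
        "j_v": float(j_v.data),
        "j_iv": float(j_iv.data),
    }


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class EPGAN(BaseEstimator):
    """Generative parameter-inference network, sklearn-style.

    fit(records) trains on a corpus of :class:`~epgan.datagen.DatasetRecord`;
    predict(inputs) maps windowed recordings to in-bounds
    :class:`~epgan.hh_core.ParameterVector` in one batched forward pass.

    Fitted attributes: ``space_``, ``encoder_``, ``generator_``, ``critic_``,
    ``history_`` (per-epoch losses) and ``candidates_`` (per-cadence
    generated parameter sets for the registered evaluation inputs).
    """

    def __init__(self, mode="small", epochs=20, batch_size=16, critic_steps=5,
                 lam=10.0, lr=1e-4, h=20.0, anchor_every=1, eval_cadence=1,
                 mask_initial=0.75,
                 w_adv=1.0, w_v=1.0, w_iv=20.0, w_logit=1.0, latent_size=1024,
                 gen_widths=(1024, 1024, 512), critic_widths=(512, 256, 128),
                 v_scale=100.0, stim_scale=35.0, iv_scale=100.0, seed=0,
                 registry=None, verbose=0):
        self.mode = mode
        self.epochs = epochs
        self.batch_size = batch_size
        self.critic_steps = critic_steps
        self.lam = lam
        self.lr = lr
        self.h = h
        self.anchor_every = anchor_every
        self.eval_cadence = eval_cadence
        self.mask_initial = mask_initial
        self.w_adv = w_adv
        self.w_v = w_v
        self.w_iv = w_iv
        self.w_logit = w_logit
        self.latent_size = latent_size
        self.gen_widths = gen_widths
        self.critic_widths = critic_widths
        self.v_scale = v_scale
        self.stim_scale = stim_scale
        self.iv_scale = iv_scale
        self.seed = seed
        self.registry = registry
        self.verbose = verbose

    # -- internal -----------------------------------------------------------
    def _config(self) -> TrainConfig:
        return TrainConfig(
            mode=self.mode, epochs=self.epochs, batch_size=self.batch_size,
            critic_steps=self.critic_steps, lam=self.lam, lr=self.lr, h=self.h,
            anchor_every=self.anchor_every, eval_cadence=self.eval_cadence,
            mask_initial=self.mask_initial,
            w_adv=self.w_adv, w_v=self.w_v, w_iv=self.w_iv, w_logit=self.w_logit,
            latent_size=self.latent_size, gen_widths=tuple(self.gen_widths),
            critic_widths=tuple(self.critic_widths), v_scale=self.v_scale,
            stim_scale=self.stim_scale, iv_scale=self.iv_scale, seed=self.seed,
        )

    def _norm_inputs(self, V, stim, iv):
        return V / self.v_scale, stim / self.stim_scale, iv / self.iv_scale

    def _encode_windowed(self, inputs: list[WindowedInput], keep=None) -> Tensor:
        V = np.stack([w.V for w in inputs])
        stim = np.stack([w.stim for w in inputs])
        iv = np.stack([w.iv.currents for w in inputs])
        vn, sn, ivn = self._norm_inputs(V, stim, iv)
        return self.encoder_(vn, sn, ivn, keep=keep)

    def _check_fitted(self):
        if not hasattr(self, "generator_"):
            raise NotFittedError("this EPGAN instance is not fitted yet")

    # -- API ----------------------------------------------------------------
    def fit(self, records, eval_inputs: list[WindowedInput] | None = None):
        """Train encoder, generator and critic on a generated corpus."""
        if len(records) == 0:
            raise ValueError("empty training corpus")
        cfg = self._config()
        rng = np.random.default_rng(cfg.seed)
        self.space_ = records[0].params.space
        if self.space_.mode != cfg.mode:
            raise ValueError(
                f"records were generated in {self.space_.mode!r} mode, "
                f"estimator configured for {cfg.mode!r}"
            )
        self.diff_ = DifferentiableHH(self.space_)
        n_out = self.diff_.n_train
        n_cond = cfg.latent_size + IV_VOLTAGES.size
        self.encoder_ = Encoder(cfg.latent_size, rng)
        self.generator_ = Generator(n_cond, n_out, rng, widths=cfg.gen_widths)
        self.critic_ = Critic(n_cond, n_out, rng, widths=cfg.critic_widths)

        # corpus arrays
        v_noisy = np.stack([r.v_noisy for r in records])  # (N, L, 350)
        v_clean = np.stack([r.windowed.V for r in records])
        stim = np.stack([r.windowed.stim for r in records])
        iv = np.stack([r.iv.currents for r in records])  # (N, 18)
        p_norm = np.stack(
            [r.params.normalized()[self.space_.trainable] for r in records]
        )
        vn, sn, ivn = self._norm_inputs(v_noisy, stim, iv)
        N, L, _ = v_noisy.shape

        # frozen kinetics: teacher-forced gate trajectories are parameter-
        # independent, so precompute per-record channel open fractions once
        open_cc = None
        if self.diff_.kinetics_static:
            open_cc = np.concatenate(
                [
                    self.diff_.static_open_fractions(v_clean[i : i + 8], h=cfg.h)
                    for i in range(0, N, 8)
                ],
                axis=0,
            )

        gen_params = self.encoder_.parameters() + self.generator_.parameters()
        opt_g = Adam(gen_params, lr=cfg.lr)
        opt_d = Adam(self.critic_.parameters(), lr=cfg.lr)
        schedule = MaskSchedule(total_epochs=cfg.epochs, initial_rate=cfg.mask_initial)
        self.history_ = []
        self.candidates_ = []

        for epoch in range(cfg.epochs):
            rate = mask_rate(epoch, schedule)
            n_keep = max(1, L - int(np.floor(rate * L)))
            perm = rng.permutation(N)
            ep = {"j_d": 0.0, "j_adv": 0.0, "j_v": 0.0, "j_iv": 0.0}
            n_batches = 0
            for start in range(0, N, cfg.batch_size):
                b = perm[start : start + cfg.batch_size]
                if b.size < 2:
                    continue
                keep = np.sort(rng.choice(L, size=n_keep, replace=False))
                cond = self.encoder_(vn[b], sn[b], ivn[b], keep=keep)
                cond_const = cond.detach()

                # critic updates (encoder held fixed)
                for _ in range(cfg.critic_steps):
                    fake = self.generator_(cond_const)
                    d_loss, _parts = discriminator_loss(
                        self.critic_, cond_const, p_norm[b], fake.data, cfg.lam, rng
                    )
                    d_grads = grad(d_loss, self.critic_.parameters())
                    opt_d.step(d_grads)
                ep["j_d"] += float(d_loss.data)

                # generator + encoder update
                fake = self.generator_(cond)
                g_loss, parts = generator_loss(
                    self.critic_, cond, fake, self.diff_,
                    v_clean[b], stim[b], iv[b], cfg,
                    logits=self.generator_.last_logits,
                    open_static=None if open_cc is None else open_cc[b],
                )
                if not np.isfinite(g_loss.data):
                    raise RuntimeError(
                        f"non-finite generator loss at epoch {epoch}, batch {n_batches}"
                    )
                g_grads = grad(g_loss, gen_params)
                opt_g.step(g_grads)
                for k in ("j_adv", "j_v", "j_iv"):
                    ep[k] += parts[k]
                n_batches += 1
            for k in ep:
                ep[k] /= max(n_batches, 1)
            if not all(np.isfinite(v) for v in ep.values()):
                raise RuntimeError(f"non-finite loss history at epoch {epoch}")
            ep.update(epoch=epoch, mask_rate=rate)
            self.history_.append(ep)
            if self.verbose:
                print(
                    f"epoch {epoch:3d}  J_D={ep['j_d']:+.3f}  J_adv={ep['j_adv']:+.3f}"
                    f"  J_V={ep['j_v']:.1f}  J_IV={ep['j_iv']:.1f}  mask={rate:.2f}"
                )
            if eval_inputs and (epoch % cfg.eval_cadence == 0 or epoch == cfg.epochs - 1):
                self.candidates_.append((epoch, self.predict(eval_inputs)))
        return self

    def predict(self, inputs: list[WindowedInput]) -> list[ParameterVector]:
        """Batched forward pass: windowed recordings -> parameter vectors."""
        self._check_fitted()
        if len(inputs) == 0:
            return []
        # group by trace count so each group forms one rectangular batch
        by_L: dict[int, list[int]] = {}
        for i, w in enumerate(inputs):
            by_L.setdefault(w.V.shape[0], []).append(i)
        out: list[ParameterVector | None] = [None] * len(inputs)
        for idxs in by_L.values():
            cond = self._encode_windowed([inputs[i] for i in idxs])
            z = self.generator_(cond).data
            full = self.diff_.full_params(Tensor(z)).data
            for row, i in enumerate(idxs):
                out[i] = ParameterVector(self.space_, full[row])
        return out


def train(records, config: TrainConfig | None = None,
          eval_inputs: list[WindowedInput] | None = None, **overrides) -> EPGAN:
    """Functional wrapper: build an :class:`EPGAN` from a config and fit it."""
    cfg = config if config is not None else TrainConfig()
    kw = asdict(cfg)
    kw.update(overrides)
    model = EPGAN(**kw)
    model.fit(records, eval_inputs=eval_inputs)
    return model


def infer(model: EPGAN, inputs: list[WindowedInput]) -> list[ParameterVector]:
    """Batched inference (single forward pass across all inputs)."""
    return model.predict(inputs)


def select_best_candidate(candidates, truth: WindowedInput,
                          protocol: ClampProtocol | None = None,
                          dt: float = 0.1, return_details: bool = False):
    """Pick the candidate whose simulated response best matches the truth.

    Each candidate is simulated under the truth's current-clamp protocol and
    scored by the pre/mid/post-averaged V RMSE; the argmin wins, ties broken
    by earliest candidate.  Candidates may be ParameterVector or
    (tag, ParameterVector) pairs.
    """
    items = []
    for c in candidates:
        if isinstance(c, ParameterVector):
            items.append(c)
        else:
            items.append(c[1])
    if not items:
        raise ValueError("no candidates supplied")
    protocol = protocol if protocol is not None else get_preset("simulated_cc")
    scores = []
    for pv in items:
        rep = evaluate_candidate(pv, truth, protocol, dt=dt)
        scores.append(rep.mean)
    scores = np.asarray(scores)
    if not np.isfinite(scores).any():
        raise RuntimeError("all candidate simulations diverged")
    best = int(np.argmin(scores))
    if return_details:
        return items[best], scores
    return items[best]
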