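"""Restricted Boltzmann machine with Gaussian or Bernoulli visible units.

The building block of the deep belief network.  Energy of a joint state
(v, h), all-negative sign convention:

    Bernoulli visible:  E(v, h) = - sum_i b_i v_i - sum_j c_j h_j
                                  - sum_ij v_i h_j w_ij
    Gaussian visible:   E(v, h) = sum_i (v_i - b_i)^2 / 2 - sum_j c_j h_j
                                  - sum_ij v_i h_j w_ij

(unit-variance convention for the Gaussian case, appropriate because the
fMRI inputs are z-scored per voxel).  Conditionals follow from the energy:
hidden units are always Bernoulli with p(h_j=1|v) = sigmoid(c_j + v·W_:j);
the visible conditional mean is b + W h (Gaussian) or its sigmoid
(Bernoulli).

Training is k-step contrastive divergence with an optional sparsity
regularizer pulling each hidden unit's mean activation toward a small
target rate, which is what makes individual units specialize to distinct
brain networks instead of sharing them.  The regularizer acts on hidden
biases only, using an exponential moving average of each unit's activity;
keeping it out of the weight matrix preserves the temporal interpretation
of weight columns (a weight-gradient sparsity term measurably drags units
toward multi-network mixtures).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RBMParams",
    "TrainConfig",
    "init_params",
    "energy",
    "hidden_given_visible",
    "visible_given_hidden",
    "cd_update",
    "train_rbm",
    "reconstruction_error",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class RBMParams:
    """Weights/biases of one RBM. ``W`` is n_visible x n_hidden."""

    W: np.ndarray
    b_vis: np.ndarray
    b_hid: np.ndarray
    visible_kind: str = "gaussian"  # "gaussian" | "bernoulli"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b_vis = np.asarray(self.b_vis, dtype=float)
        self.b_hid = np.asarray(self.b_hid, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D (n_visible x n_hidden)")
        if self.b_vis.shape != (self.W.shape[0],):
            raise ValueError("b_vis length must equal n_visible")
        if self.b_hid.shape != (self.W.shape[1],):
            raise ValueError("b_hid length must equal n_hidden")
        if self.visible_kind not in ("gaussian", "bernoulli"):
            raise ValueError(f"unknown visible_kind {self.visible_kind!r}")
        if not (np.isfinite(self.W).all() and np.isfinite(self.b_vis).all()
                and np.isfinite(self.b_hid).all()):
            raise ValueError("RBM parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "RBMParams":
        return RBMParams(self.W.copy(), self.b_vis.copy(), self.b_hid.copy(),
                         self.visible_kind)


@dataclass
class TrainConfig:
    """Contrastive-divergence settings for one RBM layer.

    Defaults follow the target study configuration: learning rate 1e-3,
    batch size 10, ~50 epochs to convergence, sparsity target 0.01 for the
    first hidden layer (use 0.05 for deeper layers).  ``cd_steps`` and the
    sparsity penalty weight are free choices; CD-1 is standard.
    """

    learning_rate: float = 0.001
    batch_size: int = 10
    epochs: int = 50
    cd_steps: int = 1
    sparsity_target: float = 0.01
    sparsity_weight: float = 10.0
    sparsity_ema_decay: float = 0.95
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.batch_size < 1 or self.epochs < 0 or self.cd_steps < 1:
            raise ValueError("batch_size/cd_steps must be >= 1, epochs >= 0")
        if not (0.0 < self.sparsity_target < 1.0):
            raise ValueError("sparsity_target must lie in (0, 1)")
        if self.sparsity_weight < 0:
            raise ValueError("sparsity_weight must be nonnegative")
        if not (0.0 <= self.sparsity_ema_decay < 1.0):
            raise ValueError("sparsity_ema_decay must lie in [0, 1)")


def init_params(
    n_visible: int,
    n_hidden: int,
    visible_kind: str = "gaussian",
    rng: np.random.Generator | None = None,
    weight_scale: float = 0.01,
) -> RBMParams:
    """Small-Gaussian weight init (std ``weight_scale``), zero biases."""
    rng = rng or np.random.default_rng(0)
    return RBMParams(
        W=weight_scale * rng.standard_normal((n_visible, n_hidden)),
        b_vis=np.zeros(n_visible),
        b_hid=np.zeros(n_hidden),
        visible_kind=visible_kind,
    )


def energy(v: np.ndarray, h: np.ndarray, p: RBMParams) -> float:
    """Joint energy E(v, h) under the sign convention in the module docstring."""
    v = np.asarray(v, dtype=float).ravel()
    h = np.asarray(h, dtype=float).ravel()
    if v.size != p.n_visible or h.size != p.n_hidden:
        raise ValueError("dimension mismatch between state and parameters")
    interaction = v @ p.W @ h
    hidden_term = p.b_hid @ h
    if p.visible_kind == "bernoulli":
        return float(-(p.b_vis @ v) - hidden_term - interaction)
    return float(0.5 * np.sum((v - p.b_vis) ** 2) - hidden_term - interaction)


def hidden_given_visible(v: np.ndarray, p: RBMParams) -> np.ndarray:
    """p(h_j = 1 | v) for one vector or a batch (rows = samples)."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != p.n_visible:
        raise ValueError("visible dimension mismatch")
    return _sigmoid(v @ p.W + p.b_hid)


def visible_given_hidden(h: np.ndarray, p: RBMParams) -> np.ndarray:
    """Conditional visible mean given hidden state(s)."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != p.n_hidden:
        raise ValueError("hidden dimension mismatch")
    pre = h @ p.W.T + p.b_vis
    if p.visible_kind == "bernoulli":
        return _sigmoid(pre)
    return pre


def _gibbs_chain(v0: np.ndarray, p: RBMParams, k: int, rng: np.random.Generator):
    """k-step CD chain from data. Hidden states are sampled; the final
    visible reconstruction uses the conditional mean (standard CD-k)."""
    ph0 = hidden_given_visible(v0, p)
    h = (rng.random(ph0.shape) < ph0).astype(float)
    v = v0
    for _ in range(k):
        v = visible_given_hidden(h, p)
        ph = hidden_given_visible(v, p)
        h = (rng.random(ph.shape) < ph).astype(float)
    return ph0, v, ph


def cd_update(
    batch: np.ndarray,
    p: RBMParams,
    cfg: TrainConfig,
    rng: np.random.Generator,
    sparsity_state: np.ndarray | None = None,
) -> tuple[RBMParams, dict]:
    """One contrastive-divergence parameter update on a mini-batch.

    Gradient estimate = positive-phase statistics (data) minus
    negative-phase statistics (after ``cd_steps`` Gibbs steps).  The
    sparsity regularizer nudges each hidden bias by

        learning_rate * sparsity_weight * (sparsity_target - q_j)

    where q_j is an exponential moving average (decay
    ``sparsity_ema_decay``) of unit j's mean activation, carried across
    batches via ``sparsity_state``.  When no state is supplied the batch
    mean is used.  Returns the updated parameters plus logging statistics
    (mean hidden activation, batch reconstruction error, updated sparsity
    state).
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[0] == 0:
        raise ValueError("empty batch")
    n = batch.shape[0]
    ph0, v_neg, ph_neg = _gibbs_chain(batch, p, cfg.cd_steps, rng)

    d_w = (batch.T @ ph0 - v_neg.T @ ph_neg) / n
    d_bvis = (batch - v_neg).mean(axis=0)
    d_bhid = (ph0 - ph_neg).mean(axis=0)

    if cfg.weight_decay > 0:
        d_w -= cfg.weight_decay * p.W

    q_batch = ph0.mean(axis=0)
    if sparsity_state is None:
        q = q_batch
    else:
        q = cfg.sparsity_ema_decay * sparsity_state + (1.0 - cfg.sparsity_ema_decay) * q_batch
    sparsity_nudge = cfg.learning_rate * cfg.sparsity_weight * (cfg.sparsity_target - q)

    new_w = p.W + cfg.learning_rate * d_w
    new_bvis = p.b_vis + cfg.learning_rate * d_bvis
    new_bhid = p.b_hid + cfg.learning_rate * d_bhid + sparsity_nudge
    if not (np.isfinite(new_w).all() and np.isfinite(new_bvis).all()
            and np.isfinite(new_bhid).all()):
        raise FloatingPointError(
            "non-finite CD update; reduce learning_rate (current "
            f"{cfg.learning_rate})"
        )
    new = RBMParams(W=new_w, b_vis=new_bvis, b_hid=new_bhid,
                    visible_kind=p.visible_kind)
    recon = float(((batch - v_neg) ** 2).mean())
    return new, {
        "mean_hidden_activation": float(ph0.mean()),
        "recon_error": recon,
        "sparsity_state": q,
    }


def train_rbm(
    data: np.ndarray,
    n_hidden: int,
    cfg: TrainConfig,
    visible_kind: str = "gaussian",
    init: RBMParams | None = None,
) -> tuple[RBMParams, list[dict]]:
    """Mini-batch CD training over ``cfg.epochs`` epochs.

    ``data`` is samples x features.  Rows are shuffled each epoch with the
    seeded RNG, so identical seed/config/data reproduces the run
    bit-for-bit.  Returns final parameters and a per-epoch history of
    mean reconstruction error and hidden activation.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    rng = np.random.default_rng(cfg.seed)
    p = init.copy() if init is not None else init_params(
        data.shape[1], n_hidden, visible_kind, rng
    )
    if p.n_visible != data.shape[1]:
        raise ValueError("init parameter shape does not match data features")
    history: list[dict] = []
    n = data.shape[0]
    sparsity_state = np.full(p.n_hidden, cfg.sparsity_target)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        errs, acts = [], []
        for start in range(0, n, cfg.batch_size):
            batch = data[order[start : start + cfg.batch_size]]
            p, stats = cd_update(batch, p, cfg, rng, sparsity_state=sparsity_state)
            sparsity_state = stats["sparsity_state"]
            errs.append(stats["recon_error"])
            acts.append(stats["mean_hidden_activation"])
        history.append(
            {
                "epoch": epoch,
                "recon_error": float(np.mean(errs)),
                "mean_hidden_activation": float(np.mean(acts)),
            }
        )
    return p, history


def reconstruction_error(data: np.ndarray, p: RBMParams) -> float:
    """Mean squared error of the deterministic one-step reconstruction.

    Up-pass uses hidden probabilities (no sampling), down-pass the visible
    conditional mean; the error is averaged over all matrix entries, so it
    is invariant to row order.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] == 0:
        raise ValueError("empty data")
    ph = hidden_given_visible(data, p)
    rec = visible_given_hidden(ph, p)
    return float(((data - rec) ** 2).mean())
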