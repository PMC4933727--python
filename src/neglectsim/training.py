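"""Batch backpropagation with momentum, written against the dual-hemisphere net.

The loss is mean squared error between the linear activator output and
the one-hot trunk-centered teacher; gradients pass through the linear
activator, the sigmoid (or tanh) cognition layers and the softmax
attention layers using the full softmax Jacobian (the cross-entropy
shortcut does not apply to an MSE loss).  Every epoch is a full-batch
update:

    dw <- momentum * dw_prev - lr * dMSE/dw        (all examples summed)

Used both for initial learning and, by the rehabilitation module, for
post-lesion retraining.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .network import (
    HEMIS,
    ACTIVATION_THRESHOLD,
    DualHemisphereNetwork,
    LayerActivation,
    forward,
)
from .stimuli import StimulusBatch

__all__ = [
    "TrainingConfig",
    "TrainingTrace",
    "mse_loss",
    "gradients",
    "backprop_epoch",
    "train_to_convergence",
    "correct_target_outputs",
]


@dataclass
class TrainingConfig:
    """Hyperparameters of the gradient-descent-with-momentum optimizer.

    ``success_criterion``:
      * ``all_targets_active`` (default): stop once every training
        example's correct-area output exceeds 0.5 AND the epoch MSE is at
        or below ``target_mse`` — the behavioural "perfect execution"
        notion of convergence.
      * ``mse_only``: stop on the MSE threshold alone.
    """

    learning_rate: float = 1.0
    momentum: float = 0.9
    max_epochs: int = 150000
    target_mse: float = 3e-5
    success_criterion: str = "all_targets_active"
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.max_epochs < 1 or self.target_mse <= 0:
            raise ValueError("max_epochs >= 1 and target_mse > 0 required")
        if self.success_criterion not in ("mse_only", "all_targets_active"):
            raise ValueError(f"unknown success criterion {self.success_criterion!r}")


@dataclass
class TrainingTrace:
    epochs_run: int
    mse_per_epoch: np.ndarray
    converged: bool
    final_mean_likelihood: float  # mean correct-area activator output over the set

    def to_frame(self):
        """Loss curve as a (epoch, mse) DataFrame, ready for CSV export."""
        import pandas as pd

        return pd.DataFrame({"epoch": np.arange(self.epochs_run), "mse": self.mse_per_epoch})


def mse_loss(activator_outputs: np.ndarray, teacher_one_hots: np.ndarray) -> float:
    """Mean over examples and output units of the squared error."""
    y = np.asarray(activator_outputs, float)
    t = np.asarray(teacher_one_hots, float)
    if y.shape != t.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {t.shape}")
    return float(np.mean((y - t) ** 2))


def correct_target_outputs(act: LayerActivation, batch: StimulusBatch) -> np.ndarray:
    """Activator output at each example's correct area: the per-trial likelihood."""
    return act.activator[np.arange(len(batch)), batch.area_ids]


def gradients(
    net: DualHemisphereNetwork, batch: StimulusBatch, act: LayerActivation | None = None
) -> tuple[dict[str, np.ndarray], LayerActivation, float]:
    """Analytic dMSE/dw for every weight block; returns (grads, activations, mse)."""
    w = net.weights
    x = {"L": batch.x_left, "R": batch.x_right}
    if act is None:
        act = forward(net, batch.x_left, batch.x_right)
    y, t = act.activator, batch.teachers
    B, n_out = y.shape
    g: dict[str, np.ndarray] = {}

    d_y = 2.0 * (y - t) / (B * n_out)  # (B, 16)
    g["b_out"] = d_y.sum(axis=0)
    d_cog = {}
    for h in HEMIS:
        g[f"{h}.w_cog_out"] = d_y.T @ act.cognition[h]
        d_cog[h] = d_y @ w[f"{h}.w_cog_out"]
    d_z = {}
    for h in HEMIS:
        c = act.cognition[h]
        deriv = c * (1.0 - c) if net.spec.cognition_transfer == "sigmoid" else 1.0 - c**2
        d_z[h] = d_cog[h] * deriv
        g[f"{h}.b_cog"] = d_z[h].sum(axis=0)
        g[f"{h}.w_att_cog"] = d_z[h].T @ act.attention[h]
    if net.spec.cross_links:
        # source-named cross blocks: h's attention into the other cognition
        g["L.w_cross"] = d_z["R"].T @ act.attention["L"]
        g["R.w_cross"] = d_z["L"].T @ act.attention["R"]
    for h, other in (("L", "R"), ("R", "L")):
        d_att = d_z[h] @ w[f"{h}.w_att_cog"]
        if net.spec.cross_links:
            d_att = d_att + d_z[other] @ w[f"{h}.w_cross"]
        a = act.attention[h]
        # full softmax Jacobian: da_i = a_i * (g_i - sum_j g_j a_j)
        d_q = a * (d_att - np.sum(d_att * a, axis=1, keepdims=True))
        g[f"{h}.b_att"] = d_q.sum(axis=0)
        g[f"{h}.w_in_att"] = d_q.T @ x[h]
    return g, act, mse_loss(y, t)


def make_velocity(net: DualHemisphereNetwork) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in net.weights.items()}


def backprop_epoch(
    net: DualHemisphereNetwork,
    batch: StimulusBatch,
    config: TrainingConfig,
    velocity: dict[str, np.ndarray] | None = None,
    frozen_blocks: Iterable[str] = (),
) -> tuple[DualHemisphereNetwork, dict[str, np.ndarray], float]:
    """One full-batch momentum update, in place.

    Returns (net, velocity, mse) where ``mse`` is the loss *before* the
    update (the quantity the stopping rules inspect).  Blocks listed in
    ``frozen_blocks`` are skipped entirely.
    """
    if velocity is None:
        velocity = make_velocity(net)
    frozen = set(frozen_blocks)
    unknown = frozen - set(net.weights)
    if unknown:
        raise ValueError(f"unknown frozen blocks {sorted(unknown)}")
    g, _, epoch_mse = gradients(net, batch)
    if not all(np.all(np.isfinite(v)) for v in g.values()):
        raise FloatingPointError("non-finite gradient encountered; reduce the learning rate")
    for name, grad in g.items():
        if name in frozen:
            continue
        v = velocity[name]
        v *= config.momentum
        v -= config.learning_rate * grad
        net.weights[name] += v
    return net, velocity, epoch_mse


def _success(config: TrainingConfig, mse: float, correct_outputs: np.ndarray) -> bool:
    if config.success_criterion == "mse_only":
        return mse <= config.target_mse
    return mse <= config.target_mse and bool(np.all(correct_outputs > ACTIVATION_THRESHOLD))


def train_to_convergence(
    net: DualHemisphereNetwork,
    batch: StimulusBatch,
    config: TrainingConfig,
    frozen_blocks: Iterable[str] = (),
) -> tuple[DualHemisphereNetwork, TrainingTrace]:
    """Run batch backprop epochs until the success criterion or max_epochs.

    Non-convergence is not an error: the trace comes back with
    ``converged=False`` and the caller decides.
    """
    config.validate()
    mses: list[float] = []
    velocity = make_velocity(net)
    converged = False
    for _ in range(config.max_epochs):
        act = forward(net, batch.x_left, batch.x_right)
        correct = correct_target_outputs(act, batch)
        mse = mse_loss(act.activator, batch.teachers)
        if _success(config, mse, correct):
            converged = True
            break
        g, _, _ = gradients(net, batch, act)
        if not all(np.all(np.isfinite(v)) for v in g.values()):
            raise FloatingPointError("non-finite gradient encountered; reduce the learning rate")
        frozen = set(frozen_blocks)
        for name, grad in g.items():
            if name in frozen:
                continue
            v = velocity[name]
            v *= config.momentum
            v -= config.learning_rate * grad
            net.weights[name] += v
        mses.append(mse)
    act = forward(net, batch.x_left, batch.x_right)
    final_mean = float(np.mean(correct_target_outputs(act, batch)))
    return net, TrainingTrace(
        epochs_run=len(mses),
        mse_per_epoch=np.asarray(mses),
        converged=converged,
        final_mean_likelihood=final_mean,
    )
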