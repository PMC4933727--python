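"""Dual-hemisphere attention network.

Each hemisphere is a feedforward column: a softmax *Attention Bias* layer
(a normalized spatial salience distribution over that hemisphere's
inputs), a sigmoid *Cognition* layer, and projections into a shared
linear *Activator* of 16 units — one per table area.  The activator
output is the "likelihood" of exploring each area; being a plain sum of
both hemispheres' contributions it may exceed 1 or go negative.

Hemispheric specialization is induced purely at initialization: the
specialized configuration gives the right hemisphere four extra units in
both hidden layers and initializes its weights in [-1, 1] while the left
hemisphere starts in [-0.1, 0.1]; inter-hemispheric links (each
hemisphere's attention layer feeding the contralateral cognition layer)
exist only in this configuration.  The control configuration is fully
symmetric (8 units per layer, [-1, 1]) with no cross links.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .stimuli import StimulusEncoding, EncoderConfig, hemisphere_inputs

__all__ = [
    "HemisphereSpec",
    "NetworkSpec",
    "DualHemisphereNetwork",
    "LayerActivation",
    "TrialOutcome",
    "init_network",
    "softmax",
    "sigmoid",
    "forward",
    "forward_stimulus",
    "classify",
    "HEMIS",
]

HEMIS = ("L", "R")
ACTIVATION_THRESHOLD = 0.5  # strict: a unit is active iff output > 0.5


@dataclass(frozen=True)
class HemisphereSpec:
    n_attention: int
    n_cognition: int
    init_range: tuple[float, float]

    def validate(self) -> None:
        if self.n_attention < 1 or self.n_cognition < 1:
            raise ValueError("hemisphere layers need at least one unit")
        lo, hi = self.init_range
        if not lo < hi:
            raise ValueError(f"inverted init range {self.init_range}")


@dataclass(frozen=True)
class NetworkSpec:
    lh: HemisphereSpec
    rh: HemisphereSpec
    cross_links: bool
    n_inputs_per_hemisphere: int = 17  # 16 retina cells + 1 muscle input
    n_outputs: int = 16
    cognition_transfer: str = "sigmoid"  # or "tanh"

    def validate(self) -> None:
        self.lh.validate()
        self.rh.validate()
        if self.n_inputs_per_hemisphere < 1 or self.n_outputs < 1:
            raise ValueError("invalid input/output sizes")
        if self.cognition_transfer not in ("sigmoid", "tanh"):
            raise ValueError(f"unknown cognition transfer {self.cognition_transfer!r}")

    def hemi(self, h: str) -> HemisphereSpec:
        return self.lh if h == "L" else self.rh

    @classmethod
    def control(cls, n_units: int = 8, init_range: tuple[float, float] = (-1.0, 1.0)) -> "NetworkSpec":
        """Symmetric hemispheres, no cross links: the no-specialization model."""
        h = HemisphereSpec(n_units, n_units, init_range)
        return cls(lh=h, rh=h, cross_links=False)

    @classmethod
    def specialized(
        cls,
        n_lh_units: int = 8,
        extra_rh_units: int = 4,
        lh_init_range: tuple[float, float] = (-0.1, 0.1),
        rh_init_range: tuple[float, float] = (-1.0, 1.0),
    ) -> "NetworkSpec":
        """RH-plastic model: extra RH units, stronger RH init, cross links on."""
        n_rh = n_lh_units + extra_rh_units
        return cls(
            lh=HemisphereSpec(n_lh_units, n_lh_units, lh_init_range),
            rh=HemisphereSpec(n_rh, n_rh, rh_init_range),
            cross_links=True,
        )


def _block_shapes(spec: NetworkSpec) -> dict[str, tuple[int, ...]]:
    """Canonical (ordered) weight blocks; cross blocks named by source hemisphere."""
    shapes: dict[str, tuple[int, ...]] = {}
    for h in HEMIS:
        hs = spec.hemi(h)
        shapes[f"{h}.w_in_att"] = (hs.n_attention, spec.n_inputs_per_hemisphere)
        shapes[f"{h}.b_att"] = (hs.n_attention,)
        shapes[f"{h}.w_att_cog"] = (hs.n_cognition, hs.n_attention)
        shapes[f"{h}.b_cog"] = (hs.n_cognition,)
        shapes[f"{h}.w_cog_out"] = (spec.n_outputs, hs.n_cognition)
    if spec.cross_links:
        # "L.w_cross" carries LH attention into RH cognition, and vice versa.
        shapes["L.w_cross"] = (spec.rh.n_cognition, spec.lh.n_attention)
        shapes["R.w_cross"] = (spec.lh.n_cognition, spec.rh.n_attention)
    shapes["b_out"] = (spec.n_outputs,)
    return shapes


@dataclass
class DualHemisphereNetwork:
    """All weight blocks plus structural metadata.

    Weight blocks live in ``weights`` keyed by canonical names
    (``L.w_in_att``, ``L.b_att``, ``L.w_att_cog``, ``L.b_cog``,
    ``L.w_cog_out``, mirrored for R, plus ``L.w_cross``/``R.w_cross`` when
    cross links exist, and the shared ``b_out``).
    """

    spec: NetworkSpec
    weights: dict[str, np.ndarray]
    rng_seed: int

    def copy(self) -> "DualHemisphereNetwork":
        return DualHemisphereNetwork(
            spec=self.spec, weights={k: v.copy() for k, v in self.weights.items()}, rng_seed=self.rng_seed
        )

    def block_names(self) -> list[str]:
        return list(self.weights)

    # --- serialization (bit-exact round trip through JSON floats) ---
    def to_dict(self) -> dict:
        return {
            "spec": {
                "lh": {"n_attention": self.spec.lh.n_attention, "n_cognition": self.spec.lh.n_cognition,
                       "init_range": list(self.spec.lh.init_range)},
                "rh": {"n_attention": self.spec.rh.n_attention, "n_cognition": self.spec.rh.n_cognition,
                       "init_range": list(self.spec.rh.init_range)},
                "cross_links": self.spec.cross_links,
                "n_inputs_per_hemisphere": self.spec.n_inputs_per_hemisphere,
                "n_outputs": self.spec.n_outputs,
                "cognition_transfer": self.spec.cognition_transfer,
            },
            "rng_seed": self.rng_seed,
            "weights": {k: v.tolist() for k, v in self.weights.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DualHemisphereNetwork":
        s = d["spec"]
        spec = NetworkSpec(
            lh=HemisphereSpec(s["lh"]["n_attention"], s["lh"]["n_cognition"], tuple(s["lh"]["init_range"])),
            rh=HemisphereSpec(s["rh"]["n_attention"], s["rh"]["n_cognition"], tuple(s["rh"]["init_range"])),
            cross_links=s["cross_links"],
            n_inputs_per_hemisphere=s["n_inputs_per_hemisphere"],
            n_outputs=s["n_outputs"],
            cognition_transfer=s.get("cognition_transfer", "sigmoid"),
        )
        weights = {k: np.asarray(v, dtype=float) for k, v in d["weights"].items()}
        return cls(spec=spec, weights=weights, rng_seed=int(d["rng_seed"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "DualHemisphereNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def init_network(spec: NetworkSpec, seed: int) -> DualHemisphereNetwork:
    """Draw every block uniformly from its hemisphere's init range.

    Blocks are drawn in canonical order from one seeded generator, so the
    result is a deterministic function of (spec, seed).  Cross blocks
    inherit the range of their *source* hemisphere; the shared activator
    bias uses the union range midpointed at zero (the wider of the two).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    weights: dict[str, np.ndarray] = {}
    wide = max(spec.lh.init_range[1] - spec.lh.init_range[0],
               spec.rh.init_range[1] - spec.rh.init_range[0])
    for name, shape in _block_shapes(spec).items():
        if name == "b_out":
            lo, hi = -wide / 2.0, wide / 2.0
        else:
            lo, hi = spec.hemi(name[0]).init_range
        weights[name] = rng.uniform(lo, hi, size=shape)
    return DualHemisphereNetwork(spec=spec, weights=weights, rng_seed=int(seed))


def softmax(q: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stabilized softmax along ``axis``."""
    q = np.asarray(q, dtype=float)
    if q.size == 0:
        raise ValueError("softmax of an empty vector")
    if not np.all(np.isfinite(q)):
        raise ValueError("softmax requires finite inputs")
    z = q - np.max(q, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LayerActivation:
    """Every intermediate activation of one forward pass (batch-first)."""

    q_attention: dict[str, np.ndarray]  # net input to each softmax layer
    attention: dict[str, np.ndarray]  # softmax outputs, rows sum to 1
    z_cognition: dict[str, np.ndarray]
    cognition: dict[str, np.ndarray]
    activator: np.ndarray  # (B, 16) likelihoods; may be <0 or >1

    @property
    def n(self) -> dict[str, int]:
        return {h: a.shape[-1] for h, a in self.attention.items()}


def _cog_transfer(spec: NetworkSpec, z: np.ndarray) -> np.ndarray:
    return sigmoid(z) if spec.cognition_transfer == "sigmoid" else np.tanh(z)


def forward(net: DualHemisphereNetwork, x_left: np.ndarray, x_right: np.ndarray) -> LayerActivation:
    """Batch forward pass.  ``x_left``/``x_right`` are (B, 17) hemisphere inputs."""
    x = {"L": np.atleast_2d(np.asarray(x_left, float)), "R": np.atleast_2d(np.asarray(x_right, float))}
    n_in = net.spec.n_inputs_per_hemisphere
    for h in HEMIS:
        if x[h].shape[1] != n_in:
            raise ValueError(f"{h} input has {x[h].shape[1]} features, spec requires {n_in}")
    w = net.weights
    q_att, att, z_cog, cog = {}, {}, {}, {}
    for h in HEMIS:
        q_att[h] = x[h] @ w[f"{h}.w_in_att"].T + w[f"{h}.b_att"]
        att[h] = softmax(q_att[h], axis=1)
    for h, other in (("L", "R"), ("R", "L")):
        z = att[h] @ w[f"{h}.w_att_cog"].T + w[f"{h}.b_cog"]
        if net.spec.cross_links:
            z = z + att[other] @ w[f"{other}.w_cross"].T
        z_cog[h] = z
        cog[h] = _cog_transfer(net.spec, z)
    y = cog["L"] @ w["L.w_cog_out"].T + cog["R"] @ w["R.w_cog_out"].T + w["b_out"]
    return LayerActivation(q_attention=q_att, attention=att, z_cognition=z_cog, cognition=cog, activator=y)


def forward_stimulus(
    net: DualHemisphereNetwork, stim: StimulusEncoding, config: EncoderConfig | None = None
) -> LayerActivation:
    """Forward pass on a single encoded stimulus (convenience wrapper)."""
    config = config or EncoderConfig()
    x_l, x_r = hemisphere_inputs(stim, config)
    return forward(net, x_l[None, :], x_r[None, :])


@dataclass(frozen=True)
class TrialOutcome:
    likelihood: float
    active: bool  # False => the trial is an omission


def classify(activation: LayerActivation, teacher_area_id: int) -> TrialOutcome:
    """Score one trial: the activator value at the correct area vs the >0.5 rule.

    The threshold is strict: a likelihood of exactly 0.5 is an omission.
    """
    y = activation.activator
    if not 0 <= teacher_area_id < y.shape[-1]:
        raise ValueError(f"teacher area id {teacher_area_id} out of range 0..{y.shape[-1] - 1}")
    lik = float(y[0, teacher_area_id] if y.ndim == 2 else y[teacher_area_id])
    return TrialOutcome(likelihood=lik, active=lik > ACTIVATION_THRESHOLD)
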