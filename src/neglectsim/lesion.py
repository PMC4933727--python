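"""Simulated hemispheric damage: zeroing attention→cognition weight blocks.

A lesion disconnects one hemisphere's Attention Bias layer from its
Cognition layer by assigning 0 to the connection weights — an
intra-hemispheric anterior/posterior disconnection.  The record keeps the
pre-lesion Euclidean norm of the cut blocks so that recovery can be
expressed as a percentage of the original connection strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import DualHemisphereNetwork

__all__ = ["LesionSpec", "LesionRecord", "apply_lesion", "weight_strength", "default_blocks"]


@dataclass(frozen=True)
class LesionSpec:
    """Which hemisphere is damaged and which link blocks are cut.

    By default only the ipsilateral Attention-Bias→Cognition block is
    zeroed; ``include_cross=True`` extends the cut to the hemisphere's
    outgoing inter-hemispheric block (when the architecture has one),
    severing that hemisphere's attention output entirely.  Biases are
    never touched — only connection weights are damaged.
    """

    hemisphere: str  # "LH" or "RH"
    link_blocks: tuple[str, ...] | None = None  # explicit override
    include_cross: bool = False
    trainable_after_lesion: bool = True

    def validate(self) -> None:
        if self.hemisphere not in ("LH", "RH"):
            raise ValueError(f"hemisphere must be 'LH' or 'RH', got {self.hemisphere!r}")
        if self.link_blocks is not None and len(self.link_blocks) == 0:
            raise ValueError("link_blocks must be non-empty when given")


def default_blocks(net: DualHemisphereNetwork, spec: LesionSpec) -> tuple[str, ...]:
    h = spec.hemisphere[0]  # "L" / "R"
    blocks = [f"{h}.w_att_cog"]
    if spec.include_cross and f"{h}.w_cross" in net.weights:
        blocks.append(f"{h}.w_cross")
    return tuple(blocks)


@dataclass
class LesionRecord:
    spec: LesionSpec
    blocks: tuple[str, ...]
    pre_lesion_strength: float  # Euclidean norm of the cut blocks before zeroing

    def to_dict(self) -> dict:
        return {
            "hemisphere": self.spec.hemisphere,
            "blocks": list(self.blocks),
            "include_cross": self.spec.include_cross,
            "trainable_after_lesion": self.spec.trainable_after_lesion,
            "pre_lesion_strength": self.pre_lesion_strength,
        }


def _masked_norm(net: DualHemisphereNetwork, blocks: Sequence[str]) -> float:
    return float(np.sqrt(sum(float(np.sum(net.weights[b] ** 2)) for b in blocks)))


def apply_lesion(net: DualHemisphereNetwork, spec: LesionSpec) -> tuple[DualHemisphereNetwork, LesionRecord]:
    """Zero the designated blocks in place; returns the net and a LesionRecord.

    Warns (does not fail) when the target blocks look untrained, i.e.
    their norm is already ~0 — lesioning a fresh or already-lesioned
    network is usually a protocol mistake.
    """
    spec.validate()
    blocks = tuple(spec.link_blocks) if spec.link_blocks is not None else default_blocks(net, spec)
    unknown = [b for b in blocks if b not in net.weights]
    if unknown:
        raise ValueError(f"unknown weight blocks {unknown}; available: {sorted(net.weights)}")
    pre = _masked_norm(net, blocks)
    if pre == 0.0:
        warnings.warn("lesioned blocks already have zero norm (untrained or re-lesioned network)")
    for b in blocks:
        net.weights[b][...] = 0.0
    return net, LesionRecord(spec=spec, blocks=blocks, pre_lesion_strength=pre)


def weight_strength(net: DualHemisphereNetwork, record: LesionRecord) -> tuple[float, float]:
    """Euclidean norm of the lesioned blocks and its percentage of pre-lesion.

    The norm is the Euclidean distance of the cut weights from the
    all-zero post-lesion state, so it is 0 right after the lesion and
    grows as retraining rebuilds the connections.
    """
    norm = _masked_norm(net, record.blocks)
    pct = 100.0 * norm / record.pre_lesion_strength if record.pre_lesion_strength > 0 else float("nan")
    return norm, pct
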