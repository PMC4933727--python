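"""Post-lesion therapy: repeated retraining sessions and recovery curves.

A rehabilitation session is 100 epochs of supervised batch backprop on
the full training set — the model analogue of a therapist guiding the
robot through the space.  After each session the four-condition battery
is re-run and the Euclidean strength of the lesioned weight block is
measured as a percentage of its pre-lesion value.  Recovery is declared
at the first session with zero omissions across all 32 battery trials.

By default the whole network retrains (plain backprop re-applied);
``lesioned_only=True`` freezes every non-lesioned block, an ablation
mode for isolating the damaged pathway's contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import run_battery
from .lesion import LesionRecord, weight_strength
from .network import DualHemisphereNetwork
from .stimuli import EncoderConfig, StimulusBatch, batch_encode, make_training_set
from .training import TrainingConfig, backprop_epoch, make_velocity

__all__ = ["RehabConfig", "RecoveryCurve", "run_rehabilitation", "recovery_summary"]


@dataclass
class RehabConfig:
    epochs_per_session: int = 100
    max_sessions: int = 200
    training: TrainingConfig = field(default_factory=TrainingConfig)
    lesioned_only: bool = False  # train only the lesioned blocks (ablation mode)

    def validate(self) -> None:
        if self.epochs_per_session < 1 or self.max_sessions < 1:
            raise ValueError("epochs_per_session and max_sessions must be >= 1")
        self.training.validate()


@dataclass
class RecoveryCurve:
    """Per-session omission counts and lesioned-block strength.

    Row 0 is the pre-therapy state (session 0: strength 0 %, the acute
    deficit).  ``sessions_to_recovery`` is the first session index with a
    clean battery, or None if therapy ran out of sessions.
    """

    session_index: np.ndarray
    n_omissions: np.ndarray  # out of 32 battery trials
    strength_pct: np.ndarray
    sessions_to_recovery: int | None
    recovered: bool
    lesion_label: str = ""
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "session": self.session_index,
                "n_omissions": self.n_omissions,
                "strength_pct": self.strength_pct,
            }
        )

    @property
    def final_strength_pct(self) -> float:
        return float(self.strength_pct[-1])


def run_rehabilitation(
    net: DualHemisphereNetwork,
    record: LesionRecord,
    config: RehabConfig | None = None,
    enc_config: EncoderConfig | None = None,
    batch: StimulusBatch | None = None,
    lesion_label: str = "",
    seed: int | None = None,
) -> tuple[DualHemisphereNetwork, RecoveryCurve]:
    """Retrain a lesioned network session by session until the battery is clean."""
    config = config or RehabConfig()
    config.validate()
    enc_config = enc_config or EncoderConfig()
    if batch is None:
        batch = batch_encode(make_training_set(enc_config), enc_config)
    frozen: tuple[str, ...] = ()
    if not record.spec.trainable_after_lesion:
        frozen = record.blocks
    elif config.lesioned_only:
        frozen = tuple(b for b in net.weights if b not in record.blocks)

    sessions = [0]
    omissions = [run_battery(net, enc_config).n_omissions]
    strengths = [weight_strength(net, record)[1]]
    velocity = make_velocity(net)
    s = 0
    while omissions[-1] > 0 and s < config.max_sessions:
        s += 1
        for _ in range(config.epochs_per_session):
            net, velocity, _ = backprop_epoch(net, batch, config.training, velocity, frozen)
        sessions.append(s)
        omissions.append(run_battery(net, enc_config).n_omissions)
        strengths.append(weight_strength(net, record)[1])
    recovered = omissions[-1] == 0
    return net, RecoveryCurve(
        session_index=np.asarray(sessions),
        n_omissions=np.asarray(omissions),
        strength_pct=np.asarray(strengths),
        sessions_to_recovery=sessions[-1] if recovered else None,
        recovered=recovered,
        lesion_label=lesion_label,
        seed=seed,
    )


def recovery_summary(curves: list[RecoveryCurve]) -> dict:
    """Across-seed medians of a rehabilitation arm.

    ``monotonicity_violations`` counts session-to-session increases of
    the omission count — recovery is noisy, not guaranteed monotone.
    """
    if not curves:
        raise ValueError("at least one recovery curve required")
    recovered = [c for c in curves if c.recovered]
    sessions = [c.sessions_to_recovery for c in recovered]
    return {
        "n_curves": len(curves),
        "n_recovered": len(recovered),
        "all_recovered": len(recovered) == len(curves),
        "median_sessions_to_recovery": float(np.median(sessions)) if sessions else None,
        "median_final_strength_pct": float(np.median([c.final_strength_pct for c in curves])),
        "monotonicity_violations": int(
            sum(int(np.sum(np.diff(c.n_omissions) > 0)) for c in curves)
        ),
    }
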