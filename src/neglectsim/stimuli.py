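"""Spatial world and stimulus encoding for the desk-scale neglect simulator.

The simulated workspace is a table in front of a seated humanoid torso.
Sixteen target areas are laid out in two depth rows of eight columns,
labelled in a trunk-centered frame (azimuth 0 = the sagittal mid-plane of
the trunk, positive to the robot's right).  A target/posture pair is
encoded into what the network "senses": a per-eye retinotopic activation
map in the *camera* frame (which rotates with the neck) and an antagonist
pair of neck-muscle inputs.  The teacher signal is always the
trunk-centered area label, so the network must solve a sensorimotor
coordinate transformation whenever the head is turned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TargetArea",
    "TargetLayout",
    "PostureState",
    "StimulusEncoding",
    "StimulusBatch",
    "EncoderConfig",
    "make_training_grid",
    "make_condition",
    "encode_motor",
    "camera_azimuth",
    "encode_stimulus",
    "make_training_set",
    "hemisphere_inputs",
    "batch_encode",
    "layout_to_frame",
    "CONDITIONS",
]

CONDITIONS = ("A", "B", "C", "D")

N_ROWS = 2
N_COLUMNS = 8
N_AREAS = N_ROWS * N_COLUMNS


@dataclass(frozen=True)
class TargetArea:
    """One of the 16 trainable table positions, in the trunk frame."""

    area_id: int
    row: int  # 0 = near row, 1 = far row
    column: int  # 0 = leftmost
    azimuth_deg: float
    side: Literal["left", "right"]


@dataclass(frozen=True)
class TargetLayout:
    """The 8 test targets and head posture of one experimental condition."""

    condition: str
    target_area_ids: tuple[int, ...]  # far row left→right, then near row
    neck_angle_deg: float


@dataclass(frozen=True)
class PostureState:
    """Neck angle plus the derived antagonist muscle inputs.

    The two muscle inputs always sum to zero: turning the head right
    flexes the right muscle (negative input) and stretches the left one
    (positive input) by the same amount.
    """

    neck_angle_deg: float
    right_motor_input: float
    left_motor_input: float

    @classmethod
    def from_angle(cls, neck_angle_deg: float, motor_scale_deg: float = 40.0) -> "PostureState":
        right, left = encode_motor(neck_angle_deg, motor_scale_deg)
        return cls(neck_angle_deg=float(neck_angle_deg), right_motor_input=right, left_motor_input=left)


@dataclass(frozen=True)
class StimulusEncoding:
    """Per-eye retinal maps + muscle inputs for a single target/posture."""

    left_visual: np.ndarray  # (16,) retinotopic activations, left eye
    right_visual: np.ndarray  # (16,) right eye
    left_motor: float
    right_motor: float
    teacher_area_id: int

    def teacher_one_hot(self, n: int = N_AREAS) -> np.ndarray:
        t = np.zeros(n)
        t[self.teacher_area_id] = 1.0
        return t


@dataclass
class EncoderConfig:
    """Geometry and coding choices of the stimulus encoder.

    column_spacing_deg : angular pitch of the table grid (and retina).
    sigma_deg          : width of the Gaussian retinal bump; half the
                         column spacing by default so neighbouring cells
                         see a graded, partially overlapping code.
    field_of_view_deg  : half-width of the camera field of view; targets
                         beyond it cannot be encoded.
    interocular_offset_deg : horizontal angle between the two eye cameras
                         (0 = both share the head frame).
    motor_scale_deg    : degrees mapped to one unit of muscle input.
    visual_code        : "gaussian" bump or "one_hot" nearest cell.
    hemifield_crossing : route each camera hemifield preferentially to the
                         contralateral hemisphere (optic-chiasm style).
                         Required for lesions to produce spatially
                         lateralized deficits.
    ipsilateral_gain   : relative gain of the ipsilateral hemifield when
                         crossing is on.  0 is an absolute split; the
                         default 0.125 gives each hemisphere a weak
                         representation of its own side, a contralateral
                         *gradient* rather than a hard partition.
    training_postures_deg : neck angles crossed with the table grid when
                         building the training set.
    """

    column_spacing_deg: float = 15.0
    sigma_deg: float = 7.5
    field_of_view_deg: float = 67.5
    interocular_offset_deg: float = 0.0
    motor_scale_deg: float = 40.0
    visual_code: str = "gaussian"
    hemifield_crossing: bool = True
    ipsilateral_gain: float = 0.125
    training_postures_deg: tuple[float, ...] = (0.0, 40.0)

    @property
    def column_azimuths(self) -> np.ndarray:
        """Trunk-frame azimuths of the 8 columns (also the retina cell centers)."""
        half = N_COLUMNS / 2.0
        return (np.arange(N_COLUMNS) - half + 0.5) * self.column_spacing_deg

    def validate(self) -> None:
        if self.column_spacing_deg <= 0 or self.sigma_deg <= 0:
            raise ValueError("column spacing and sigma must be positive")
        if self.visual_code not in ("gaussian", "one_hot"):
            raise ValueError(f"unknown visual_code {self.visual_code!r}")
        if self.field_of_view_deg <= 0:
            raise ValueError("field of view must be positive")
        if not 0.0 <= self.ipsilateral_gain <= 1.0:
            raise ValueError("ipsilateral_gain must be in [0, 1]")


def make_training_grid(config: EncoderConfig | None = None) -> list[TargetArea]:
    """The 16 canonical table areas: 2 rows x 8 columns, symmetric about the midline."""
    config = config or EncoderConfig()
    azimuths = config.column_azimuths
    areas = []
    for row in range(N_ROWS):
        for col in range(N_COLUMNS):
            az = float(azimuths[col])
            areas.append(
                TargetArea(
                    area_id=row * N_COLUMNS + col,
                    row=row,
                    column=col,
                    azimuth_deg=az,
                    side="left" if az < 0 else "right",
                )
            )
    return sorted(areas, key=lambda a: a.area_id)


# Columns used by each condition: A and D straddle the midline, B and C are
# the right-hemispace columns; C and D add the 40-degree rightward head turn.
_CONDITION_COLUMNS = {
    "A": (2, 3, 4, 5),
    "B": (4, 5, 6, 7),
    "C": (4, 5, 6, 7),
    "D": (2, 3, 4, 5),
}
_CONDITION_NECK = {"A": 0.0, "B": 0.0, "C": 40.0, "D": 40.0}


def make_condition(condition: str, config: EncoderConfig | None = None) -> TargetLayout:
    """Target layout + posture for one of the four test conditions A-D."""
    if condition not in _CONDITION_COLUMNS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    cols = _CONDITION_COLUMNS[condition]
    # far row (row 1) first, matching the printed table orientation
    ids = tuple(1 * N_COLUMNS + c for c in cols) + tuple(0 * N_COLUMNS + c for c in cols)
    return TargetLayout(condition=condition, target_area_ids=ids, neck_angle_deg=_CONDITION_NECK[condition])


def encode_motor(neck_angle_deg: float, motor_scale_deg: float = 40.0) -> tuple[float, float]:
    """Antagonist neck-muscle coding: (right_input, left_input).

    Turning the head theta degrees to the right flexes the right muscle,
    coded as -theta (normalized by ``motor_scale_deg``), and stretches the
    left one, coded as +theta.
    """
    if abs(neck_angle_deg) > 60:
        raise ValueError(f"neck angle {neck_angle_deg} out of the +/-60 degree range")
    right = -neck_angle_deg / motor_scale_deg
    return right, -right


def camera_azimuth(
    trunk_azimuth_deg: float,
    neck_angle_deg: float,
    eye: Literal["left", "right"] = "left",
    interocular_offset_deg: float = 0.0,
) -> float:
    """Target azimuth in an eye-camera frame.

    The camera frame rotates with the head, so a rightward head turn
    shifts every target leftward on the retina.  A nonzero interocular
    offset splits the two cameras symmetrically about the head axis.
    """
    if eye not in ("left", "right"):
        raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")
    eye_offset = (-0.5 if eye == "left" else 0.5) * interocular_offset_deg
    return trunk_azimuth_deg - neck_angle_deg - eye_offset


def _retina_map(cam_az: float, row: int, config: EncoderConfig) -> np.ndarray:
    """Retinal activation pattern (16,) for a target at camera azimuth ``cam_az``."""
    centers = config.column_azimuths
    vis = np.zeros(N_AREAS)
    sl = slice(row * N_COLUMNS, (row + 1) * N_COLUMNS)
    if config.visual_code == "gaussian":
        vis[sl] = np.exp(-((cam_az - centers) ** 2) / (2.0 * config.sigma_deg**2))
    else:  # one_hot
        vis[sl][int(np.argmin(np.abs(centers - cam_az)))] = 1.0
    return vis


def encode_stimulus(
    area: TargetArea, posture: PostureState, config: EncoderConfig | None = None
) -> StimulusEncoding:
    """Encode one target/posture pair into per-eye retinal maps + motor inputs.

    Raises ValueError if the target falls outside the camera field of view
    for either eye (a geometry misconfiguration, not a soft failure).
    """
    config = config or EncoderConfig()
    config.validate()
    maps = {}
    for eye in ("left", "right"):
        cam = camera_azimuth(area.azimuth_deg, posture.neck_angle_deg, eye, config.interocular_offset_deg)
        if abs(cam) > config.field_of_view_deg:
            raise ValueError(
                f"target at trunk azimuth {area.azimuth_deg} with neck {posture.neck_angle_deg} "
                f"falls at camera azimuth {cam} ({eye} eye), outside the "
                f"+/-{config.field_of_view_deg} degree field of view"
            )
        maps[eye] = _retina_map(cam, area.row, config)
    return StimulusEncoding(
        left_visual=maps["left"],
        right_visual=maps["right"],
        left_motor=posture.left_motor_input,
        right_motor=posture.right_motor_input,
        teacher_area_id=area.area_id,
    )


def in_view(area: TargetArea, neck_angle_deg: float, config: EncoderConfig) -> bool:
    """True if the target is inside the field of view of both eye cameras."""
    return all(
        abs(camera_azimuth(area.azimuth_deg, neck_angle_deg, eye, config.interocular_offset_deg))
        <= config.field_of_view_deg
        for eye in ("left", "right")
    )


def make_training_set(config: EncoderConfig | None = None) -> list[StimulusEncoding]:
    """All visible (area, posture) pairs: the supervised training set.

    The table grid is crossed with the configured training postures and
    every pair whose target stays inside the camera field of view is kept
    (with the default +/-67.5 degree field, 16 areas at 0 degrees plus the
    12 in-view areas at 40 degrees: 28 examples).  Teachers are one-hot
    trunk-centered area labels, unaffected by posture.
    """
    config = config or EncoderConfig()
    out = []
    for angle in config.training_postures_deg:
        posture = PostureState.from_angle(angle, config.motor_scale_deg)
        for area in make_training_grid(config):
            if in_view(area, angle, config):
                out.append(encode_stimulus(area, posture, config))
    return out


def _hemifield_masks(config: EncoderConfig) -> tuple[np.ndarray, np.ndarray]:
    """(gain profile for LH input, for RH input) over the 16 retina cells.

    The contralateral hemifield passes at unit gain, the ipsilateral one
    at ``ipsilateral_gain`` — a lateralized gradient, not a hard cut.
    """
    centers = np.tile(config.column_azimuths, N_ROWS)
    g = config.ipsilateral_gain
    lh = np.where(centers > 0, 1.0, g)
    rh = np.where(centers < 0, 1.0, g)
    return lh, rh


def hemisphere_inputs(stim: StimulusEncoding, config: EncoderConfig) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the 17-element input vector of each hemisphere.

    The left hemisphere receives the left eye's image and the left muscle
    input; the right hemisphere the right eye's image and right muscle
    input.  With ``hemifield_crossing`` (default) each hemisphere sees the
    contralateral half of the camera frame at full gain and its own half
    at ``ipsilateral_gain`` — the lateralized gradient left by the optic
    chiasm.
    """
    lv, rv = np.asarray(stim.left_visual, float), np.asarray(stim.right_visual, float)
    if config.hemifield_crossing:
        mask_l, mask_r = _hemifield_masks(config)
        lv, rv = lv * mask_l, rv * mask_r
    x_l = np.concatenate([lv, [stim.left_motor]])
    x_r = np.concatenate([rv, [stim.right_motor]])
    return x_l, x_r


@dataclass
class StimulusBatch:
    """Vectorized stimulus set: per-hemisphere inputs and one-hot teachers."""

    x_left: np.ndarray  # (B, 17)
    x_right: np.ndarray  # (B, 17)
    teachers: np.ndarray  # (B, 16)
    area_ids: np.ndarray  # (B,)

    def __len__(self) -> int:
        return self.x_left.shape[0]


def batch_encode(stimuli: Sequence[StimulusEncoding], config: EncoderConfig | None = None) -> StimulusBatch:
    config = config or EncoderConfig()
    pairs = [hemisphere_inputs(s, config) for s in stimuli]
    return StimulusBatch(
        x_left=np.stack([p[0] for p in pairs]),
        x_right=np.stack([p[1] for p in pairs]),
        teachers=np.stack([s.teacher_one_hot() for s in stimuli]),
        area_ids=np.array([s.teacher_area_id for s in stimuli], dtype=int),
    )


def layout_to_frame(layout: TargetLayout, config: EncoderConfig | None = None) -> pd.DataFrame:
    """Tabular export of a condition layout (area_id,row,column,azimuth_deg,side)."""
    grid = {a.area_id: a for a in make_training_grid(config)}
    rows = [asdict(grid[i]) | {"condition": layout.condition, "neck_angle_deg": layout.neck_angle_deg}
            for i in layout.target_area_ids]
    return pd.DataFrame(rows)


def layout_to_json(layout: TargetLayout) -> str:
    return json.dumps(asdict(layout), sort_keys=True)
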