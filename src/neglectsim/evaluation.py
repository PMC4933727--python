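"""Four-condition test battery and the derived neglect metrics.

A battery presents the 8 targets of each condition A–D (32 trials), reads
the activator likelihood of the correct trunk-centered area for each, and
applies the strict >0.5 activation rule; a failed trial is an omission —
the model analogue of a neglected target.  Grids are laid out like the
printed result tables: far row on top, columns left→right in increasing
trunk azimuth.  Replicated experiments are aggregated by cell-wise median
across seeds, with the summary metrics recomputed from the median grid.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import ACTIVATION_THRESHOLD, DualHemisphereNetwork, forward
from .stimuli import (
    CONDITIONS,
    EncoderConfig,
    PostureState,
    TargetLayout,
    batch_encode,
    encode_stimulus,
    make_condition,
    make_training_grid,
)

__all__ = [
    "ConditionReport",
    "BatteryReport",
    "run_condition",
    "run_battery",
    "battery_metrics",
    "replicate_median",
    "load_printed_table",
    "battery_from_grids",
    "battery_to_frame",
    "PRINTED_TABLES",
]

N_TRIALS = 32  # 4 conditions x 8 targets
_GRID_SHAPE = (2, 4)


@dataclass
class ConditionReport:
    """Likelihood grid of one condition: 2x4, far row first, azimuth ascending."""

    condition: str
    grid: np.ndarray  # (2, 4) correct-target likelihoods
    azimuths: np.ndarray  # (4,) trunk azimuth of each column
    neck_angle_deg: float

    @property
    def omission_flags(self) -> np.ndarray:
        return ~(self.grid > ACTIVATION_THRESHOLD)

    @property
    def n_omissions(self) -> int:
        return int(self.omission_flags.sum())


@dataclass
class BatteryReport:
    """All four condition grids plus the two headline metrics.

    ``success_rate_pct`` is the percentage of the 32 trials whose correct
    target exceeded the activation threshold; ``mean_likelihood`` averages
    all 32 correct-target likelihoods regardless of success.
    """

    reports: dict[str, ConditionReport]
    success_rate_pct: float
    mean_likelihood: float
    model_label: str = ""
    lesion_label: str = ""
    seed: int | None = None

    @property
    def n_omissions(self) -> int:
        return sum(r.n_omissions for r in self.reports.values())

    def omissions_by_condition(self) -> dict[str, int]:
        return {c: r.n_omissions for c, r in self.reports.items()}


def run_condition(
    net: DualHemisphereNetwork,
    condition: str | TargetLayout,
    config: EncoderConfig | None = None,
) -> ConditionReport:
    """Present a condition's 8 targets and score each against its teacher."""
    config = config or EncoderConfig()
    layout = condition if isinstance(condition, TargetLayout) else make_condition(condition, config)
    grid_areas = {a.area_id: a for a in make_training_grid(config)}
    posture = PostureState.from_angle(layout.neck_angle_deg, config.motor_scale_deg)
    stims = [encode_stimulus(grid_areas[i], posture, config) for i in layout.target_area_ids]
    batch = batch_encode(stims, config)
    act = forward(net, batch.x_left, batch.x_right)
    liks = act.activator[np.arange(len(batch)), batch.area_ids]
    grid = liks.reshape(_GRID_SHAPE)  # layout ids are far row then near row, az ascending
    azimuths = np.array([grid_areas[i].azimuth_deg for i in layout.target_area_ids[:4]])
    return ConditionReport(
        condition=layout.condition, grid=grid, azimuths=azimuths, neck_angle_deg=layout.neck_angle_deg
    )


def battery_metrics(
    reports: Mapping[str, ConditionReport] | Sequence[ConditionReport],
    model_label: str = "",
    lesion_label: str = "",
    seed: int | None = None,
) -> BatteryReport:
    """Success rate (% of 32) and mean likelihood over the four condition grids."""
    if not isinstance(reports, Mapping):
        reports = {r.condition: r for r in reports}
    missing = [c for c in CONDITIONS if c not in reports]
    if missing:
        raise ValueError(f"battery requires all four conditions; missing {missing}")
    cells = np.concatenate([reports[c].grid.ravel() for c in CONDITIONS])
    n_omit = sum(reports[c].n_omissions for c in CONDITIONS)
    return BatteryReport(
        reports={c: reports[c] for c in CONDITIONS},
        success_rate_pct=100.0 * (N_TRIALS - n_omit) / N_TRIALS,
        mean_likelihood=float(np.mean(cells)),
        model_label=model_label,
        lesion_label=lesion_label,
        seed=seed,
    )


def run_battery(
    net: DualHemisphereNetwork,
    config: EncoderConfig | None = None,
    model_label: str = "",
    lesion_label: str = "",
    seed: int | None = None,
) -> BatteryReport:
    reports = {c: run_condition(net, c, config) for c in CONDITIONS}
    return battery_metrics(reports, model_label, lesion_label, seed)


def replicate_median(
    run: Callable[[int], BatteryReport] | Sequence[BatteryReport],
    seeds: Sequence[int] | None = None,
) -> tuple[BatteryReport, list[BatteryReport]]:
    """Cell-wise median over replicate batteries; metrics recomputed on the median grid.

    ``run`` may be a closure mapping seed → BatteryReport (invoked for
    each of ``seeds``) or an already-computed sequence of reports.
    Replicates that fail are skipped with a warning; at least one must
    survive.
    """
    import warnings

    if callable(run):
        if not seeds:
            raise ValueError("seeds required when passing an experiment closure")
        per_seed = []
        for s in seeds:
            try:
                per_seed.append(run(s))
            except Exception as exc:  # noqa: BLE001 - replicate failures are reported, not fatal
                warnings.warn(f"replicate with seed {s} failed: {exc}")
    else:
        per_seed = list(run)
    if not per_seed:
        raise ValueError("no successful replicates to aggregate")
    med_reports = {}
    for c in CONDITIONS:
        stack = np.stack([r.reports[c].grid for r in per_seed])
        med_reports[c] = ConditionReport(
            condition=c,
            grid=np.median(stack, axis=0),
            azimuths=per_seed[0].reports[c].azimuths,
            neck_angle_deg=per_seed[0].reports[c].neck_angle_deg,
        )
    median = battery_metrics(
        med_reports,
        model_label=per_seed[0].model_label,
        lesion_label=per_seed[0].lesion_label,
        seed=None,
    )
    return median, per_seed


# ---------------------------------------------------------------------------
# Printed-table fixtures (the four published median result grids)
# ---------------------------------------------------------------------------

PRINTED_TABLES = {
    "control_lh_lesion": "table1_control_lh_lesion.csv",
    "control_rh_lesion": "table2_control_rh_lesion.csv",
    "specialized_lh_lesion": "table3_specialized_lh_lesion.csv",
    "specialized_rh_lesion": "table4_specialized_rh_lesion.csv",
}


def load_printed_table(key: str) -> dict[str, np.ndarray]:
    """Load one published median likelihood table as {condition: (2,4) grid}."""
    if key not in PRINTED_TABLES:
        raise KeyError(f"unknown table {key!r}; options: {sorted(PRINTED_TABLES)}")
    ref = importlib.resources.files("neglectsim").joinpath("data/tables", PRINTED_TABLES[key])
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, float_precision="round_trip")
    grids = {}
    for c, sub in df.groupby("condition"):
        grid = np.full(_GRID_SHAPE, np.nan)
        for _, r in sub.iterrows():
            grid[int(r["row"]), int(r["col"])] = r["likelihood"]
        grids[c] = grid
    return grids


def battery_from_grids(
    grids: Mapping[str, np.ndarray], model_label: str = "", lesion_label: str = ""
) -> BatteryReport:
    """Wrap externally supplied 2x4 grids (e.g. a printed table) as a battery."""
    reports = {}
    for c in CONDITIONS:
        layout = make_condition(c)
        cols = (2, 3, 4, 5) if c in ("A", "D") else (4, 5, 6, 7)
        azimuths = EncoderConfig().column_azimuths[list(cols)]
        reports[c] = ConditionReport(
            condition=c,
            grid=np.asarray(grids[c], float),
            azimuths=azimuths,
            neck_angle_deg=layout.neck_angle_deg,
        )
    return battery_metrics(reports, model_label=model_label, lesion_label=lesion_label)


def battery_to_frame(report: BatteryReport) -> pd.DataFrame:
    """Flatten a battery into one row per cell (condition,row,col,azimuth,likelihood,omitted)."""
    rows = []
    for c in CONDITIONS:
        r = report.reports[c]
        for i in range(_GRID_SHAPE[0]):
            for j in range(_GRID_SHAPE[1]):
                rows.append(
                    {
                        "condition": c,
                        "row": i,
                        "col": j,
                        "azimuth_deg": float(r.azimuths[j]),
                        "likelihood": float(r.grid[i, j]),
                        "omitted": bool(r.omission_flags[i, j]),
                    }
                )
    return pd.DataFrame(rows)
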