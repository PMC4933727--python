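"""Config-driven experiment runner: train, lesion, test, rehabilitate, report.

Reproduces the full experimental program — the symmetric control model
and the RH-specialized model, either or both lesion arms, the
four-condition battery and optional rehabilitation — across a list of
seeds, writing per-seed and cell-wise-median reports plus a manifest.
All randomness flows from the per-replicate seeds, so a re-run with the
same configuration reproduces every result file byte for byte (the
manifest's wall-clock field is the one exception, and lives only there).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import BatteryReport, battery_to_frame, replicate_median, run_battery
from .lesion import LesionSpec, apply_lesion
from .network import DualHemisphereNetwork, NetworkSpec, init_network
from .rehabilitation import RehabConfig, recovery_summary, run_rehabilitation
from .stimuli import EncoderConfig, batch_encode, make_training_set
from .training import TrainingConfig, train_to_convergence

__all__ = ["ExperimentConfig", "RunManifest", "run_experiment", "render_tables", "load_config"]

_ARMS = {"none": (), "lh": ("LH",), "rh": ("RH",), "both": ("LH", "RH")}


@dataclass
class ExperimentConfig:
    test_case: str = "specialized"  # or "control"
    lesion_arm: str = "both"  # none | lh | rh | both
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5)
    rehab_enabled: bool = False
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    lesion_include_cross: bool = False
    rehab: RehabConfig = field(default_factory=RehabConfig)
    out_dir: str = "results"
    save_networks: bool = False

    def validate(self) -> None:
        if self.test_case not in ("control", "specialized"):
            raise ValueError(f"unknown test case {self.test_case!r}")
        if self.lesion_arm not in _ARMS:
            raise ValueError(f"unknown lesion arm {self.lesion_arm!r}")
        if not self.seeds:
            raise ValueError("at least one seed required")
        self.encoder.validate()
        self.training.validate()
        self.rehab.validate()

    def network_spec(self) -> NetworkSpec:
        return NetworkSpec.control() if self.test_case == "control" else NetworkSpec.specialized()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _subconfig(cls, d: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys {sorted(unknown)}")
    return cls(**d)


def load_config(path: str | Path) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML (or JSON) file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "encoder" in kwargs:
        enc = dict(kwargs["encoder"])
        if "training_postures_deg" in enc:
            enc["training_postures_deg"] = tuple(enc["training_postures_deg"])
        kwargs["encoder"] = _subconfig(EncoderConfig, enc)
    if "training" in kwargs:
        kwargs["training"] = _subconfig(TrainingConfig, dict(kwargs["training"]))
    if "rehab" in kwargs:
        rh = dict(kwargs["rehab"])
        if "training" in rh:
            rh["training"] = _subconfig(TrainingConfig, dict(rh["training"]))
        kwargs["rehab"] = _subconfig(RehabConfig, rh)
    if "seeds" in kwargs:
        kwargs["seeds"] = tuple(int(s) for s in kwargs["seeds"])
    return _subconfig(ExperimentConfig, kwargs)


@dataclass
class RunManifest:
    config: dict
    artifacts: dict[str, str]
    version: str
    wall_clock_s: float
    per_seed: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def _summary_dict(median: BatteryReport, per_seed: list[BatteryReport]) -> dict:
    return {
        "model": median.model_label,
        "lesion": median.lesion_label,
        "success_rate_pct": median.success_rate_pct,
        "mean_likelihood": median.mean_likelihood,
        "omissions_by_condition": median.omissions_by_condition(),
        "n_omissions": median.n_omissions,
        "per_seed": [
            {
                "seed": r.seed,
                "success_rate_pct": r.success_rate_pct,
                "mean_likelihood": r.mean_likelihood,
                "n_omissions": r.n_omissions,
            }
            for r in per_seed
        ],
    }


def train_replicates(config: ExperimentConfig) -> dict[int, tuple[DualHemisphereNetwork, object]]:
    """Train one healthy network per seed; returns {seed: (net, trace)}."""
    batch = batch_encode(make_training_set(config.encoder), config.encoder)
    spec = config.network_spec()
    out = {}
    for seed in config.seeds:
        net = init_network(spec, seed)
        net, trace = train_to_convergence(net, batch, config.training)
        out[seed] = (net, trace)
    return out


def run_experiment(config: ExperimentConfig, progress: bool = False) -> RunManifest:
    """Execute the configured program and write all report files.

    Artifacts written under ``config.out_dir``:
      battery_<case>_<arm>_seed<S>.csv / _median.csv, summary_<case>_<arm>.json,
      recovery_<case>_<arm>_seed<S>.csv / _summary.json (with rehab on),
      and manifest.json.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise ValueError(f"output dir {out} is not writable")
    t0 = time.perf_counter()
    case = config.test_case
    batch = batch_encode(make_training_set(config.encoder), config.encoder)

    trained = train_replicates(config)
    artifacts: dict[str, str] = {}
    per_seed_meta: dict = {
        str(s): {
            "epochs_run": trace.epochs_run,
            "converged": trace.converged,
            "final_mean_likelihood": trace.final_mean_likelihood,
        }
        for s, (net, trace) in trained.items()
    }
    if config.save_networks:
        for s, (net, _) in trained.items():
            p = out / f"network_{case}_healthy_seed{s}.json"
            net.save(p)
            artifacts[f"network_{case}_seed{s}"] = str(p)

    healthy = [
        run_battery(net, config.encoder, model_label=case, lesion_label="none", seed=s)
        for s, (net, _) in trained.items()
    ]
    med_h, _ = replicate_median(healthy)
    p = out / f"summary_{case}_healthy.json"
    with open(p, "w") as fh:
        json.dump(_summary_dict(med_h, healthy), fh, indent=1, sort_keys=True)
    artifacts["summary_healthy"] = str(p)

    for arm in _ARMS[config.lesion_arm]:
        lspec = LesionSpec(hemisphere=arm, include_cross=config.lesion_include_cross)
        reports, curves = [], []
        for s, (net, _) in trained.items():
            lnet, record = apply_lesion(net.copy(), lspec)
            rep = run_battery(lnet, config.encoder, model_label=case, lesion_label=arm, seed=s)
            reports.append(rep)
            p = out / f"battery_{case}_{arm}_seed{s}.csv"
            _write_csv(battery_to_frame(rep), p)
            artifacts[f"battery_{case}_{arm}_seed{s}"] = str(p)
            if config.rehab_enabled:
                _, curve = run_rehabilitation(
                    lnet, record, config.rehab, config.encoder, batch, lesion_label=arm, seed=s
                )
                curves.append(curve)
                p = out / f"recovery_{case}_{arm}_seed{s}.csv"
                _write_csv(curve.to_frame(), p)
                artifacts[f"recovery_{case}_{arm}_seed{s}"] = str(p)
        median, _ = replicate_median(reports)
        p = out / f"battery_{case}_{arm}_median.csv"
        _write_csv(battery_to_frame(median), p)
        artifacts[f"battery_{case}_{arm}_median"] = str(p)
        p = out / f"summary_{case}_{arm}.json"
        with open(p, "w") as fh:
            json.dump(_summary_dict(median, reports), fh, indent=1, sort_keys=True)
        artifacts[f"summary_{case}_{arm}"] = str(p)
        if curves:
            p = out / f"recovery_{case}_{arm}_summary.json"
            with open(p, "w") as fh:
                json.dump(recovery_summary(curves), fh, indent=1, sort_keys=True)
            artifacts[f"recovery_{case}_{arm}_summary"] = str(p)

    manifest = RunManifest(
        config=config.to_dict(),
        artifacts=artifacts,
        version=__version__,
        wall_clock_s=time.perf_counter() - t0,
        per_seed=per_seed_meta,
    )
    manifest.save(out / "manifest.json")
    return manifest


def render_tables(manifest: RunManifest | str | Path, out_dir: str | Path | None = None) -> list[Path]:
    """Re-render median battery CSVs and summaries from a manifest's artifacts.

    Reads the per-seed battery CSVs recorded in the manifest, recomputes
    the cell-wise medians and rewrites the median CSV + JSON summary.
    Recovery CSVs are left untouched (and absent artifacts are simply
    skipped).  Returns the list of files written.
    """
    if not isinstance(manifest, RunManifest):
        with open(Path(manifest)) as fh:
            d = json.load(fh)
        manifest = RunManifest(**d)
    from .evaluation import ConditionReport, battery_metrics

    by_arm: dict[tuple[str, str], list] = {}
    for key, path in manifest.artifacts.items():
        if key.startswith("battery_") and "_seed" in key:
            _, case, arm, seedtag = key.split("_")
            df = pd.read_csv(path, float_precision="round_trip")
            reports = {}
            for c, sub in df.groupby("condition"):
                grid = np.full((2, 4), np.nan)
                az = np.zeros(4)
                for _, r in sub.iterrows():
                    grid[int(r["row"]), int(r["col"])] = r["likelihood"]
                    az[int(r["col"])] = r["azimuth_deg"]
                reports[c] = ConditionReport(c, grid, az, 0.0)
            rep = battery_metrics(reports, model_label=case, lesion_label=arm, seed=int(seedtag[4:]))
            by_arm.setdefault((case, arm), []).append(rep)
    written = []
    base = Path(out_dir) if out_dir is not None else Path(manifest.config["out_dir"])
    base.mkdir(parents=True, exist_ok=True)
    for (case, arm), reps in by_arm.items():
        median, _ = replicate_median(reps)
        p = base / f"battery_{case}_{arm}_median.csv"
        _write_csv(battery_to_frame(median), p)
        written.append(p)
        p = base / f"summary_{case}_{arm}.json"
        with open(p, "w") as fh:
            json.dump(_summary_dict(median, reps), fh, indent=1, sort_keys=True)
        written.append(p)
    return written
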