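"""Run configuration and the end-to-end study pipeline.

A :class:`RunConfig` carries every threshold and seed the stages need and
round-trips losslessly through YAML.  :func:`run_full_pipeline` chains
simulate -> train -> assess -> EEG activity -> analyze into a report
directory with a provenance block (config hash, seed, package version).
Outputs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assessment, cohort, stats
from . import training as tr

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_full_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All pipeline knobs in one serializable block."""

    seed: int = 0
    out_dir: str = "breathloop_report"
    # stage toggles
    run_simulate: bool = True
    run_training_logs: bool = True
    run_assessment: bool = True
    run_eeg_forward_model: bool = False
    run_analyze: bool = True
    # cohort sizes (None -> study defaults)
    n_training: int | None = None
    n_control: int | None = None
    # engine / classifier thresholds
    consistency_cv_threshold: float = 0.25
    tap_count_tolerance: int = 1
    mad_sidedness: str = "two-sided"
    # EEG pipeline
    inverse_lambda: float = 0.1
    alpha_band: tuple[float, float] = (8.0, 12.0)
    epoch_window: tuple[float, float] = (-4.0, 0.0)
    reject_abs: float | None = None
    leakage_correction: bool = True
    eeg_n_subjects: int = 4
    eeg_duration_s: float = 100.0
    eeg_srate: float = 250.0
    # optional external inputs (simulation used when absent)
    outcomes_csv: str | None = None
    activity_csv: str | None = None
    eeg_recordings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["alpha_band"] = list(self.alpha_band)
        d["epoch_window"] = list(self.epoch_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("alpha_band", "epoch_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _write_json(obj, path: Path) -> None:
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default,
                   allow_nan=True)
        + "\n"
    )


def run_full_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the report directory.

    Any stage failure raises :class:`StageError` naming the stage; outputs
    of completed stages are retained in the report directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)
    report: dict = {
        "provenance": {
            "config_sha256": config.digest(),
            "seed": rng_seed,
            "package_version": __version__,
        },
        "stages": {},
    }

    spec = cohort.default_cohort_spec()
    if config.n_training or config.n_control:
        spec = dataclasses.replace(
            spec,
            n_training=config.n_training or spec.n_training,
            n_control=config.n_control or spec.n_control,
        )
    tcfg = tr.TrainingConfig(
        consistency_cv_threshold=config.consistency_cv_threshold,
        tap_count_tolerance=config.tap_count_tolerance,
    )

    # --- simulate / load ---------------------------------------------------
    outcomes = activity = None
    logs: dict = {}
    try:
        if config.outcomes_csv:
            outcomes = pd.read_csv(config.outcomes_csv)
            activity = (
                pd.read_csv(config.activity_csv) if config.activity_csv else None
            )
            report["stages"]["simulate"] = "loaded external tables"
        elif config.run_simulate:
            outcomes, activity, logs = cohort.generate_cohort(
                spec,
                seed=rng_seed,
                include_training_logs=config.run_training_logs,
                training_config=tcfg,
            )
            outcomes.to_csv(out / "outcomes.csv", index=False)
            activity.to_csv(out / "network_activity.csv", index=False)
            report["stages"]["simulate"] = "completed"
        else:
            report["stages"]["simulate"] = "skipped"
    except Exception as err:  # noqa: BLE001 - stage boundary
        _write_json(report, out / "report.json")
        raise StageError("simulate", str(err)) from err

    # --- training logs -----------------------------------------------------
    try:
        if config.run_training_logs and logs:
            rows = []
            for pid, slogs in logs.items():
                for sl in slogs:
                    for b_idx, blk in enumerate(sl.blocks):
                        for t in blk.tap_times:
                            rows.append(
                                (pid, sl.session_index, b_idx, blk.level, t,
                                 blk.consistent, blk.chimes)
                            )
            pd.DataFrame(
                rows,
                columns=[
                    "participant_id", "session_index", "block_index",
                    "level", "tap_time_s", "consistent", "chimes",
                ],
            ).to_csv(out / "session_logs.csv", index=False)
            report["stages"]["train"] = "completed"
        else:
            report["stages"]["train"] = "skipped"
    except Exception as err:  # noqa: BLE001
        _write_json(report, out / "report.json")
        raise StageError("train", str(err)) from err

    # --- interoceptive assessment scoring ----------------------------------
    try:
        if config.run_assessment and outcomes is not None:
            rng = np.random.default_rng(rng_seed + 1)
            rows = []
            pids = outcomes["participant_id"].unique()
            for pid in pids:
                user = assessment.SimulatedUser(
                    breath_period_mean=4.0,
                    lapse_rate=float(rng.uniform(0.0, 0.2)),
                )
                _, series = assessment.simulate_assessment_run(
                    user, seed=rng, sidedness=config.mad_sidedness
                )
                rows.append(
                    (pid, len(series.rts), series.median_rt, series.mad_rt,
                     series.n_attended, series.n_distracted)
                )
            pd.DataFrame(
                rows,
                columns=[
                    "participant_id", "n_trials", "median_rt_s", "mad_rt_s",
                    "n_attended", "n_distracted",
                ],
            ).to_csv(out / "assessment_scores.csv", index=False)
            report["stages"]["assess"] = "completed"
        else:
            report["stages"]["assess"] = "skipped"
    except Exception as err:  # noqa: BLE001
        _write_json(report, out / "report.json")
        raise StageError("assess", str(err)) from err

    # --- EEG activity -------------------------------------------------------
    try:
        if config.eeg_recordings:
            from . import eeg as eegmod

            rows = []
            lf = eegmod.build_toy_leadfield()
            for path in config.eeg_recordings:
                rec = eegmod.read_recording(path)
                table, _ = eegmod.estimate_network_activity(
                    rec, lf, lam=config.inverse_lambda,
                    band=config.alpha_band, window=config.epoch_window,
                    reject_abs=config.reject_abs,
                    sidedness=config.mad_sidedness,
                    leakage_correction=config.leakage_correction,
                )
                table["recording"] = str(path)
                rows.append(table)
            pd.concat(rows).to_csv(out / "eeg_activity.csv", index=False)
            report["stages"]["eeg"] = "completed (external recordings)"
        elif config.run_eeg_forward_model:
            from . import eeg as eegmod

            lf = eegmod.build_toy_leadfield()
            T = eegmod.network_crosstalk_matrix(lf, config.inverse_lambda)
            espec = cohort.EEGCohortSpec(
                n_subjects=config.eeg_n_subjects,
                duration_s=config.eeg_duration_s,
                srate=config.eeg_srate,
            )
            rows = []
            for sid, tp, rec, levels in cohort.generate_eeg_cohort(
                espec, lf, seed=rng_seed + 2
            ):
                table, _ = eegmod.estimate_network_activity(
                    rec, lf, lam=config.inverse_lambda,
                    band=config.alpha_band, window=config.epoch_window,
                    leakage_correction=config.leakage_correction,
                    crosstalk=T,
                )
                table["participant_id"] = sid
                table["timepoint"] = tp
                rows.append(table)
            pd.concat(rows).to_csv(out / "eeg_activity.csv", index=False)
            report["stages"]["eeg"] = "completed (forward-model simulation)"
        else:
            report["stages"]["eeg"] = "skipped"
    except StageError:
        raise
    except Exception as err:  # noqa: BLE001
        _write_json(report, out / "report.json")
        raise StageError("eeg", str(err)) from err

    # --- analysis -----------------------------------------------------------
    try:
        if config.run_analyze and outcomes is not None:
            rep = stats.analyze_trial(outcomes, activity)
            report["analysis"] = rep
            (out / "report.md").write_text(stats.format_report_markdown(rep))
            report["stages"]["analyze"] = "completed"
        else:
            report["stages"]["analyze"] = "skipped"
    except Exception as err:  # noqa: BLE001
        _write_json(report, out / "report.json")
        raise StageError("analyze", str(err)) from err

    _write_json(report, out / "report.json")
    return out
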