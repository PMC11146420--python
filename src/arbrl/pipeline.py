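"""Config-driven orchestration of simulate / fit / compare / recover / export.

A single YAML (or dict) config names the stages to run; every stage's
randomness derives from a master seed through a documented counter scheme
(stage seed = master seed + a fixed per-stage offset), and a run manifest
records the config snapshot, seeds, package version, timestamps and a SHA-256
hash of every file written, so deterministic stages can be verified bit-wise
on a rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dataclass_field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .cohort import (
    CohortSpec,
    block_summaries,
    group_contrast,
    hc_like,
    ocd_like,
    recovery_spec,
    sample_cohort,
    simulate_cohort,
)
from .fitting import FitConfig, compare_models, fit_subject, parameter_recovery
from .io import read_trial_log, write_trial_log
from .regressors import export_modulators, write_events
from .task import TaskConfig

logger = logging.getLogger("arbrl")

STAGES = ("simulate", "fit", "compare", "recover", "export")
#: per-stage seed offsets added to the master seed
STAGE_SEED_OFFSETS = {name: 10_000 * (i + 1) for i, name in enumerate(STAGES)}

_PROFILES = {"hc": hc_like, "ocd": ocd_like, "recovery": recovery_spec}


class RunConfig(BaseModel):
    """Top-level pipeline configuration."""

    stages: list[str] = Field(default_factory=lambda: ["simulate"])
    seed: int = 0
    out_dir: str = "arbrl_run"
    task: TaskConfig = Field(default_factory=TaskConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    profiles: list[str] = Field(default_factory=lambda: ["hc", "ocd"])
    subjects_per_group: int = 10
    fit_variants: list[str] = Field(default_factory=lambda: ["arb", "mb", "mf"])
    recover_subjects: int = 10
    export_glms: list[int] = Field(default_factory=lambda: [2, 3, 4])

    def model_post_init(self, __context) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {STAGES}")


@dataclass
class RunManifest:
    """Record of one pipeline run: inputs, seeds, outputs and their hashes."""

    config: dict
    master_seed: int
    stage_seeds: dict[str, int]
    version: str = __version__
    started: str = ""
    finished: str = ""
    completed_stages: list[str] = dataclass_field(default_factory=list)
    outputs: dict[str, str] = dataclass_field(default_factory=dict)  # path -> sha256
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def run_experiment(config: RunConfig | str | Path) -> RunManifest:
    """Execute the configured stages in dependency order; returns the manifest.

    A stage failure aborts the run but still writes a manifest marking the
    stages that completed.
    """
    if not isinstance(config, RunConfig):
        config = load_config(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_seeds = {s: config.seed + STAGE_SEED_OFFSETS[s] for s in config.stages}
    manifest = RunManifest(
        config=json.loads(config.model_dump_json()),
        master_seed=config.seed,
        stage_seeds=stage_seeds,
        started=datetime.now(timezone.utc).isoformat(),
    )
    written: list[Path] = []

    def save_df(df: pd.DataFrame, rel: str, tsv: bool = False) -> Path:
        path = out_dir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        if tsv:
            write_events(df, path)
        else:
            write_trial_log(df, path)
        written.append(path)
        return path

    logs_by_group: dict[str, list[pd.DataFrame]] = {}
    fits_by_group: dict[str, dict[str, list]] = {}
    try:
        if "simulate" in config.stages:
            seed = stage_seeds["simulate"]
            for g, profile in enumerate(config.profiles):
                spec: CohortSpec = _PROFILES[profile](config.subjects_per_group)
                cohort = sample_cohort(spec, seed=seed + g)
                logs = simulate_cohort(cohort, config.task, seed=seed + 100 * (g + 1),
                                       label=f"{profile}_")
                logs_by_group[profile] = logs
                for log in logs:
                    save_df(log, f"logs/{log['subject'].iloc[0]}.csv")
                logger.info("simulated %d %s-profile subjects", len(logs), profile)
            manifest.completed_stages.append("simulate")

        if "fit" in config.stages:
            if not logs_by_group:
                logs_by_group["loaded"] = [
                    read_trial_log(p) for p in sorted(out_dir.glob("logs/*.csv"))
                ]
            seed = stage_seeds["fit"]
            rows = []
            for profile, logs in logs_by_group.items():
                fits_by_group[profile] = {v: [] for v in config.fit_variants}
                for i, log in enumerate(logs):
                    for variant in config.fit_variants:
                        fit = fit_subject(
                            log, variant=variant,
                            config=config.fit.model_copy(update={"seed": seed + i}),
                        )
                        fits_by_group[profile][variant].append(fit)
                        rows.append(
                            {
                                "group": profile, "subject": fit.subject,
                                "variant": variant, "nll": fit.nll, "aic": fit.aic,
                                "bic": fit.bic, "converged": fit.converged,
                                **{f"param_{k}": v for k, v in fit.params.as_dict().items()
                                   if isinstance(v, (int, float))},
                            }
                        )
            save_df(pd.DataFrame(rows), "fits.csv")
            manifest.completed_stages.append("fit")

        if "compare" in config.stages:
            if not fits_by_group:
                raise RuntimeError("compare requires the fit stage in the same run")
            tables = []
            for profile, fits in fits_by_group.items():
                if len(fits) >= 2:
                    table = compare_models(fits)
                    table.insert(0, "group", profile)
                    tables.append(table)
            save_df(pd.concat(tables, ignore_index=True), "model_comparison.csv")
            if len(logs_by_group) >= 2:
                names = list(logs_by_group)
                summaries = {
                    p: pd.concat([block_summaries(log) for log in logs_by_group[p]],
                                 ignore_index=True)
                    for p in names[:2]
                }
                contrast = group_contrast(summaries[names[0]], summaries[names[1]])
                save_df(contrast.table, "group_contrast.csv")
            manifest.completed_stages.append("compare")

        if "recover" in config.stages:
            seed = stage_seeds["recover"]
            report = parameter_recovery(
                recovery_spec(config.recover_subjects), config.task,
                config.fit.model_copy(update={"seed": seed}), seed=seed,
            )
            save_df(report.correlations, "recovery_correlations.csv")
            save_df(report.pairs, "recovery_pairs.csv")
            manifest.completed_stages.append("recover")

        if "export" in config.stages:
            if not logs_by_group:
                logs_by_group["loaded"] = [
                    read_trial_log(p) for p in sorted(out_dir.glob("logs/*.csv"))
                ]
            for profile, logs in logs_by_group.items():
                for log in logs[:1]:  # one exemplar subject per group
                    for glm in config.export_glms:
                        events = export_modulators(log, glm)
                        save_df(events, f"events/{log['subject'].iloc[0]}_glm{glm}.tsv",
                                tsv=True)
            manifest.completed_stages.append("export")
    except Exception as exc:
        pending = [s for s in config.stages if s not in manifest.completed_stages]
        manifest.failed_stage = pending[0] if pending else None
        manifest.finished = datetime.now(timezone.utc).isoformat()
        manifest.outputs = {str(p.relative_to(out_dir)): _sha256(p) for p in written}
        (out_dir / "manifest.json").write_text(manifest.to_json())
        raise RuntimeError(f"stage {manifest.failed_stage!r} failed: {exc}") from exc

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.outputs = {str(p.relative_to(out_dir)): _sha256(p) for p in written}
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
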