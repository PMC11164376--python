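"""End-to-end orchestration: simulate -> trim -> metrics -> fit -> associate.

A run is a pure function of (config, seeds): every stochastic stage receives
an explicit seed derived from the run seed, all stage outputs are plain CSV
(posterior draws as compressed ``.npz`` with a JSON sidecar), and a manifest
records the config hash, seeds, package version and SHA-256 checksums of
every output so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior_metrics import LEARNER_CUTOFF_PCT, metrics_table, trim_rt
from .race_ddm import RaceDDM, correct_drift_summary
from .synthetic_cohort import (
    CohortConfig,
    OspanConfig,
    sample_cohort,
    save_cohort,
    simulate_cohort_ospan,
    simulate_experiment,
)
from .task_design import SessionDesign
from .wm_association import (
    accuracy_model,
    ddm_parameter_model,
    generalization_model,
    maintenance_model,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    seed: int
    n_participants: int = 10
    output_dir: str = "run"
    tail: float = 0.01
    learner_cutoff_pct: float = LEARNER_CUTOFF_PCT
    sessions_to_fit: tuple = (1, 2, 3)
    learners_only_models: bool = True
    mcmc: dict = field(default_factory=lambda: {"n_iter": 1500, "burn_in": 500, "thin": 2})
    cohort: dict = field(default_factory=dict)
    ospan: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config must provide an explicit seed")
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        CohortConfig(**self.cohort).validate()
        OspanConfig(**self.ospan).validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sessions_to_fit"] = list(d["sessions_to_fit"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must provide an explicit seed")
        if "sessions_to_fit" in raw:
            raw["sessions_to_fit"] = tuple(raw["sessions_to_fit"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": {},
        "status": "running",
    }
    t0 = time.time()
    stage = "simulate"
    try:
        design = SessionDesign(**config.design)
        cohort = sample_cohort(config.n_participants, CohortConfig(**config.cohort),
                               rng_seed=config.seed)
        trials = simulate_experiment(cohort, design, rng_seed=config.seed + 1)
        ospan_trials, ospan_scores_df = simulate_cohort_ospan(
            cohort, OspanConfig(**config.ospan), rng_seed=config.seed + 2
        )
        save_cohort(cohort, out / "cohort_latents.json")
        _write_csv(trials, out / "trials.csv")
        _write_csv(ospan_trials, out / "ospan_trials.csv")
        _write_csv(ospan_scores_df, out / "ospan_scores.csv")
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2),
                                     "n_trials": int(len(trials))}

        stage = "metrics"
        t1 = time.time()
        trimmed = trim_rt(trials, tail=config.tail)
        tables = metrics_table(trials, ospan_scores_df, tail=config.tail,
                               cutoff_pct=config.learner_cutoff_pct)
        _write_csv(trimmed, out / "trials_trimmed.csv")
        for name in ("accuracy", "participants", "maintenance", "generalization"):
            _write_csv(tables[name], out / f"{name}.csv")
        manifest["stages"][stage] = {"seconds": round(time.time() - t1, 2)}

        stage = "fit-ddm"
        t1 = time.time()
        summaries = []
        fit_info = {}
        for session in config.sessions_to_fit:
            sess_trials = trimmed[trimmed["session"] == session]
            model = RaceDDM(random_state=config.seed + 10 + session, **config.mcmc)
            model.fit(sess_trials)
            fit = model.fit_
            summ = correct_drift_summary(fit)
            summaries.append(summ)
            np.savez_compressed(
                out / f"draws_session{session}.npz",
                **{k: v for k, v in fit.draws.items()},
            )
            with open(out / f"draws_session{session}.schema.json", "w") as fh:
                json.dump(
                    {k: list(np.shape(v)) for k, v in fit.draws.items()}
                    | {"participants": fit.participants},
                    fh, indent=1,
                )
            gw = fit.diagnostics["geweke"]
            fit_info[str(session)] = {
                "acceptance": {k: round(v, 3) for k, v in fit.diagnostics["acceptance"].items()},
                "geweke_frac_pass": gw["frac_pass"],
                "n_retained": fit.mcmc_config["n_retained"],
            }
        summary = pd.concat(summaries, ignore_index=True)
        _write_csv(summary, out / "ddm_summaries.csv")
        with open(out / "ddm_diagnostics.json", "w") as fh:
            json.dump(fit_info, fh, indent=1)
        manifest["stages"][stage] = {"seconds": round(time.time() - t1, 2), **fit_info}

        stage = "associate"
        t1 = time.time()
        learners = tables["participants"]
        ospan_df = ospan_scores_df
        results = {
            "accuracy_all": accuracy_model(tables["accuracy"], ospan_df),
            "accuracy_learners": accuracy_model(
                tables["accuracy"], ospan_df, learners, learners_only=True
            ),
            "maintenance": maintenance_model(
                tables["maintenance"], ospan_df,
                learners if config.learners_only_models else None,
            ),
            "generalization": generalization_model(
                tables["generalization"], ospan_df,
                learners if config.learners_only_models else None,
            ),
            "drift": ddm_parameter_model(
                summary, ospan_df, "drift",
                learners if config.learners_only_models else None,
            ),
            "boundary": ddm_parameter_model(
                summary, ospan_df, "boundary",
                learners if config.learners_only_models else None,
            ),
        }
        for name, res in results.items():
            _write_csv(res.to_frame(), out / f"lmm_{name}.csv")
        manifest["stages"][stage] = {"seconds": round(time.time() - t1, 2)}

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed at stage '{stage}': {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    manifest["total_seconds"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("pipeline complete in %.1fs -> %s", manifest["total_seconds"], out)
    return manifest
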