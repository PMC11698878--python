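"""End-to-end pipeline: simulate -> fit -> stats -> report.

Every stage's inputs and outputs are persisted as CSV/JSON under the
output directory, and a manifest records the seed, config hash, file
list and per-stage status.  The run is deterministic given the seed:
cohort sampling, score generation and each subject's trial stream use
substreams spawned from one root ``SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import io as scio
from .cohort import sample_cohort
from .config import PipelineConfig, config_hash
from .learning_curve import fit_learning_curve
from .report import build_report
from .staircase import BlockSeries, run_protocol

__all__ = ["PipelineError", "run_pipeline", "simulate_stage", "fit_stage", "stats_stage"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def simulate_stage(config: PipelineConfig):
    """Sample the cohort and run the staircase protocol for the trained arm."""
    root = np.random.SeedSequence(config.seed)
    cohort_ss, *subject_ss = root.spawn(1 + config.cohort.n_training + config.cohort.n_control)
    rng = np.random.default_rng(cohort_ss)
    observers, scores = sample_cohort(config.cohort, rng=rng)

    n_drop = config.cohort.dropout_training
    trained = [o for o in observers if o.group == "training"]
    if n_drop:
        dropped = {o.subject_id for o in trained[-n_drop:]}
        logger.info("dropout: removing %s from the trained arm", sorted(dropped))
        trained = trained[: len(trained) - n_drop]
        scores = [s for s in scores if s.subject_id not in dropped]

    series_list: list[BlockSeries] = []
    for obs, ss in zip(trained, subject_ss):
        sub_rng = np.random.default_rng(ss)
        logger.info("simulating %s (substream %s)", obs.subject_id, ss.spawn_key)
        series_list.append(run_protocol(obs, config.protocol, sub_rng))
    return observers, scores, series_list


def fit_stage(blocks_df, config: PipelineConfig):
    """Fit the exponential learning curve per subject from the block table."""
    fits = []
    for subject, sub in blocks_df.groupby("subject", sort=True):
        sub = sub.sort_values("block")
        thresholds = sub["threshold"].where(sub["valid"], np.nan).tolist()
        fit = fit_learning_curve(thresholds, config.fit)
        fits.append(dataclasses.replace(fit, subject_id=str(subject)))
    return fits


def stats_stage(scores_df, params_df, config: PipelineConfig):
    return build_report(scores_df, params_df, welch=config.welch)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages, persisting artifacts and a manifest; returns the manifest.

    On a stage failure the manifest is still written with the failed
    stage marked, then a :class:`PipelineError` naming it is raised.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise PipelineError("setup", exc) from exc

    manifest = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": config.to_dict(),
        "stages": {},
        "files": [],
    }

    def _finish_stage(name, files=()):
        manifest["stages"][name] = "ok"
        manifest["files"].extend(str(f) for f in files)

    def _write_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    stage = "simulate"
    try:
        observers, scores, series_list = simulate_stage(config)
        trials_df = scio.trials_frame(series_list)
        blocks_df = scio.blocks_frame(series_list)
        scores_df = scio.scores_frame(scores)
        files = [
            scio.write_table(trials_df, out / "trials.csv", "trials"),
            scio.write_table(blocks_df, out / "blocks.csv", "blocks"),
            scio.write_table(scores_df, out / "scores.csv", "scores"),
        ]
        _finish_stage(stage, files)

        stage = "fit"
        fits = fit_stage(blocks_df, config)
        params_df = scio.params_frame(fits)
        _finish_stage(stage, [scio.write_table(params_df, out / "params.csv", "params")])

        stage = "stats"
        report = stats_stage(scores_df, params_df, config)
        _finish_stage(stage)

        stage = "report"
        _finish_stage(stage, report.write(out / "report"))
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        _write_manifest()
        raise PipelineError(stage, exc) from exc

    _write_manifest()
    return manifest
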