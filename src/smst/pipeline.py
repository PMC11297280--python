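"""End-to-end orchestration: stimuli -> lists -> simulate -> score -> fit.

Each stage writes its artifact to disk before the next one starts, and a
manifest JSON records package/library versions, the seeds in force, and
a SHA-256 hash of every artifact, so a rerun under the same
configuration can be verified byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy
import yaml

import smst
from smst.cohort import (
    ResponseModelParams,
    default_age_assignment,
    save_responses,
    simulate_cohort,
)
from smst.design import (
    DesignConfig,
    generate_all_schedules,
    make_rotation_plan,
    save_schedules,
    validate_schedule,
)
from smst.errors import PipelineError, SmstError
from smst.fixtures import FixtureConfig, generate_fixture_embedding
from smst.inference import fit_probit_similarity_model
from smst.scoring import dprime_scores, response_proportions
from smst.stimuli import FilterCriteria, SimilarityBands, build_stimulus_set, write_lexicon
from smst.embedding import write_embedding

log = logging.getLogger("smst.pipeline")

_STAGES = ("build-stimuli", "make-lists", "simulate", "score", "fit")


def _take(cls, block: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise PipelineError("config", f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**block)


def default_config(seed: int = 0) -> dict[str, Any]:
    """The demo configuration: a full-size build on the synthetic lexicon."""
    return {
        "fixture": {"seed": seed},
        "stimuli": {"n_triplets": 100, "n_foils": 125, "seed": seed},
        "design": {"seed": seed},
        "cohort": {"seed": seed},
    }


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config", f"{path} is not a YAML mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict[str, Any] | str | Path, outdir: str | Path) -> dict[str, Any]:
    """Run every stage, writing artifacts and a manifest under ``outdir``.

    Any stage failure raises :class:`PipelineError` carrying the stage
    name and cause. Returns the manifest dictionary.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fixture_cfg = _take(FixtureConfig, dict(config.get("fixture", {})))
    stim_block = dict(config.get("stimuli", {}))
    design_cfg = _take(DesignConfig, dict(config.get("design", {})))
    cohort_block = dict(config.get("cohort", {}))
    cohort_seed = int(cohort_block.pop("seed", 0))
    cohort_params = _take(ResponseModelParams, cohort_block)

    manifest: dict[str, Any] = {
        "versions": {
            "smst": smst.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "seeds": {
            "fixture": fixture_cfg.seed,
            "stimuli": int(stim_block.get("seed", 0)),
            "design": design_cfg.seed,
            "cohort": cohort_seed,
        },
        "stages": [],
        "artifacts": {},
    }

    def record(stage: str, *paths: Path) -> None:
        for p in paths:
            manifest["artifacts"][p.name] = _sha256(p)
        manifest["stages"].append(stage)
        log.info("stage=%s artifacts=%s", stage, [p.name for p in paths])

    # --- build-stimuli ---------------------------------------------------
    try:
        space, lexicon = generate_fixture_embedding(fixture_cfg)
        emb_path = outdir / "embedding.vec"
        lex_path = outdir / "lexicon.tsv"
        write_embedding(space, emb_path)
        write_lexicon(lexicon, lex_path)
        criteria = _take(FilterCriteria, dict(stim_block.pop("criteria", {})))
        bands = _take(SimilarityBands, dict(stim_block.pop("bands", {})))
        stimulus_set = build_stimulus_set(
            lexicon, space, criteria=criteria, bands=bands,
            n_triplets=int(stim_block.get("n_triplets", 100)),
            n_foils=int(stim_block.get("n_foils", 125)),
            seed=int(stim_block.get("seed", 0)),
        )
        stimulus_set.validate(space, bands)
        trip_path = outdir / "stimuli.tsv"
        foil_path = outdir / "foils.tsv"
        stimulus_set.to_tsv(trip_path, foil_path)
        record("build-stimuli", emb_path, lex_path, trip_path, foil_path)
    except SmstError as exc:
        raise PipelineError("build-stimuli", str(exc)) from exc

    # --- make-lists ------------------------------------------------------
    try:
        plan = make_rotation_plan(design_cfg, stimulus_set)
        schedules = generate_all_schedules(plan, stimulus_set, design_cfg)
        for s in schedules:
            violations = validate_schedule(s, design_cfg)
            if violations:
                raise PipelineError(
                    "make-lists", f"participant {s.participant_id}: {violations}"
                )
        lists_path = outdir / "lists.csv"
        save_schedules(schedules, lists_path)
        record("make-lists", lists_path)
    except SmstError as exc:
        raise PipelineError("make-lists", str(exc)) from exc

    # --- simulate --------------------------------------------------------
    try:
        ages = default_age_assignment(design_cfg.n_participants)
        responses = simulate_cohort(schedules, ages, cohort_params, seed=cohort_seed)
        resp_path = outdir / "responses.csv"
        save_responses(responses, resp_path)
        record("simulate", resp_path)
    except SmstError as exc:
        raise PipelineError("simulate", str(exc)) from exc

    # --- score -----------------------------------------------------------
    try:
        props = response_proportions(responses)
        dps = dprime_scores(responses)
        scores = props.merge(
            dps.drop(columns=["age_group"], errors="ignore"), on="participant_id"
        )
        scores_path = outdir / "scores.csv"
        scores.to_csv(scores_path, index=False)
        record("score", scores_path)
    except SmstError as exc:
        raise PipelineError("score", str(exc)) from exc

    # --- fit -------------------------------------------------------------
    try:
        fit = fit_probit_similarity_model(responses)
        fit_path = outdir / "fit.json"
        with open(fit_path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "coefficients": fit.coefficients,
                    "standard_errors": fit.standard_errors,
                    "exp_estimates": fit.exp_estimates,
                    "ci95": fit.ci95,
                    "n_obs": fit.n_obs,
                    "converged": fit.converged,
                    "iterations": fit.iterations,
                    "log_likelihood": fit.log_likelihood,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        record("fit", fit_path)
    except SmstError as exc:
        raise PipelineError("fit", str(exc)) from exc

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
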