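"""End-to-end orchestration: simulate -> phenotype -> fit -> score ->
transfer -> evaluate, with one global seed and a provenance manifest.

Each enabled stage writes its artifacts into the run directory; the
manifest records the configuration digest, the seed, the package version
and a content hash of every file written, so reruns with the same
configuration are verifiable as identical (bit-identical for the exact
stages, draw-identical for the MCMC stage).

The global seed spawns an independent, stage-name-salted stream per stage,
so toggling one stage never perturbs another stage's randomness.
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

from . import __version__
from .bfmm import (ModelSpec, effect_surface, fit_mcmc,
                   summarize_all_contrasts, summarize_contrast)
from .biosignature import (DEFAULT_SCORE_CONDITIONS, SignatureMask,
                           build_signature_mask, mask_to_frame, score_cohort)
from .containers import CohortDataset
from .evaluation import GroupTestResult, compare_models, group_test
from .phenotyping import classify_cohort
from .synthetic_data import (SimConfig, clbp_default_config,
                             cp_default_config, generate_cohort,
                             generate_outcomes, generate_ratings)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "phenotype", "fit", "score", "transfer",
              "evaluate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, salted by stage name."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    clbp_sim: SimConfig | None = None
    cp_sim: SimConfig | None = None
    model: ModelSpec = field(default_factory=ModelSpec)
    mask_window: tuple[float, float] = (0.4, 0.7)
    mask_pos_band: tuple[float, float] = (1.0, 7.0)
    mask_neg_band: tuple[float, float] = (8.0, 12.0)
    score_conditions: tuple = DEFAULT_SCORE_CONDITIONS
    contrast_column: str = "widespread_hyperalgesia:affected_high"
    credible_level: float = 0.90
    alpha: float = 0.05

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.clbp_sim is None:
            self.clbp_sim = clbp_default_config(
                seed=stage_seed(self.seed, "simulate"))
        if self.cp_sim is None:
            self.cp_sim = cp_default_config(
                seed=stage_seed(self.seed, "transfer"))
        self.model = dataclasses.replace(
            self.model, seed=stage_seed(self.seed, "fit"))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelSpec(**d["model"])
        for key in ("clbp_sim", "cp_sim"):
            if key in d and isinstance(d[key], dict):
                d[key] = SimConfig(**d[key])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def _jsonable(o):
    if isinstance(o, dict):
        return {str(k): _jsonable(v) for k, v in o.items()}
    if isinstance(o, (list, tuple)):
        return [_jsonable(v) for v in o]
    if isinstance(o, np.ndarray):
        return o.round(12).tolist()
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return {f.name: _jsonable(getattr(o, f.name))
                for f in dataclasses.fields(o)}
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    if isinstance(o, (str, int, float, bool)) or o is None:
        return o
    return repr(o)


def _digest(obj) -> str:
    payload = json.dumps(_jsonable(obj), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def transfer_apply(mask: SignatureMask, dataset: CohortDataset,
                   score_conditions=DEFAULT_SCORE_CONDITIONS,
                   alpha: float = 0.05
                   ) -> tuple[pd.DataFrame, GroupTestResult]:
    """Project a new cohort onto a fixed signature and test group
    separation; the mask is never refit."""
    scores = score_cohort(dataset, mask, conditions=score_conditions)
    test = group_test(scores["score_mean"], scores["phenotype"], alpha=alpha)
    return scores, test


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages; returns the provenance manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = dict(version=__version__, seed=config.seed,
                          stages=list(config.stages),
                          config_digest=_digest(config))

    def emit(path: Path):
        written.append(path)

    clbp = truth = None
    mask = build_signature_mask(
        window=config.mask_window, pos_band=config.mask_pos_band,
        neg_band=config.mask_neg_band)
    scores = None

    current_stage = None
    try:
        if "simulate" in config.stages:
            current_stage = "simulate"
            logger.info("stage simulate")
            clbp, truth = generate_cohort(config.clbp_sim)
            clbp.save(out / "clbp")
            emit(out / "clbp" / "cohort.h5")
            emit(out / "clbp" / "subjects.csv")
            gt = dict(
                amplitude_table={f"{g}|{ck}": a for (g, ck), a
                                 in truth.amplitude_table.items()},
                covariate_effects=truth.covariate_effects,
                outcome_model=dataclasses.asdict(truth.outcome_model))
            p = out / "ground_truth.json"
            p.write_text(json.dumps(gt, indent=2, sort_keys=True))
            emit(p)

        if "phenotype" in config.stages:
            current_stage = "phenotype"
            logger.info("stage phenotype")
            clbp = clbp or CohortDataset.load(out / "clbp")
            gen_labels = {s.subject: s.phenotype for s in clbp.subjects}
            ratings = generate_ratings(config.clbp_sim, gen_labels)
            has_pain = {sid: lab != "no_pain"
                        for sid, lab in gen_labels.items()}
            derived = classify_cohort(ratings, has_pain)
            tab = pd.DataFrame({"generative": pd.Series(gen_labels),
                                "derived": derived})
            tab.index.name = "subject"
            ratings.to_csv(out / "ratings.csv", index=False)
            tab.to_csv(out / "phenotypes.csv")
            emit(out / "ratings.csv")
            emit(out / "phenotypes.csv")

        if "fit" in config.stages:
            current_stage = "fit"
            logger.info("stage fit (MCMC)")
            clbp = clbp or CohortDataset.load(out / "clbp")
            draws = fit_mcmc(clbp, config.model)
            summarize_all_contrasts(
                draws, level=config.credible_level).to_csv(
                out / "contrasts.csv", index=False)
            emit(out / "contrasts.csv")
            key = summarize_contrast(draws, config.contrast_column,
                                     level=config.credible_level)
            (out / "key_contrast.json").write_text(
                json.dumps(key.as_dict(), indent=2))
            emit(out / "key_contrast.json")
            surf = effect_surface(draws, config.contrast_column)
            pd.DataFrame(surf, index=draws.basis.grid.times,
                         columns=draws.basis.grid.freqs).to_csv(
                out / "effect_surface.csv")
            emit(out / "effect_surface.csv")

        if "score" in config.stages:
            current_stage = "score"
            logger.info("stage score")
            clbp = clbp or CohortDataset.load(out / "clbp")
            mask_to_frame(mask).to_csv(out / "signature_mask.csv")
            emit(out / "signature_mask.csv")
            scores = score_cohort(clbp, mask,
                                  conditions=config.score_conditions)
            scores.to_csv(out / "clbp_scores.csv", index=False)
            emit(out / "clbp_scores.csv")

        cp_scores = None
        if "transfer" in config.stages:
            current_stage = "transfer"
            logger.info("stage transfer")
            cp, _ = generate_cohort(config.cp_sim)
            cp.save(out / "cp")
            emit(out / "cp" / "cohort.h5")
            emit(out / "cp" / "subjects.csv")
            cp_scores, test = transfer_apply(
                mask, cp, score_conditions=config.score_conditions,
                alpha=config.alpha)
            cp_scores.to_csv(out / "cp_scores.csv", index=False)
            emit(out / "cp_scores.csv")
            (out / "cp_group_test.json").write_text(
                json.dumps(test.as_dict(), indent=2))
            emit(out / "cp_group_test.json")

        if "evaluate" in config.stages:
            current_stage = "evaluate"
            logger.info("stage evaluate")
            if cp_scores is None:
                cp_scores = pd.read_csv(out / "cp_scores.csv")
            outcomes = generate_outcomes(
                config.cp_sim,
                cp_scores.set_index("subject")["score_mean"],
                cp_scores.set_index("subject")["phenotype"])
            outcomes.to_csv(out / "cp_outcomes.csv", index=False)
            emit(out / "cp_outcomes.csv")
            report = compare_models(outcomes)
            (out / "evaluation.json").write_text(
                json.dumps(report.as_dict(), indent=2, sort_keys=True))
            emit(out / "evaluation.json")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {current_stage!r} failed: {exc}") from exc

    manifest["files"] = {str(p.relative_to(out)): _file_hash(p)
                         for p in written}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
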