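"""End-to-end orchestration: simulate -> extract -> dtc -> pool -> classify -> describe.

Each stage reads the previous stage's CSV/JSON artifacts from the run
directory and writes its own, so any stage can be re-run from cached
upstream outputs.  A manifest records the seed, configuration, package
version and content hashes of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import ModelSpec, confusion_row_percent, evaluate_model
from .cohort import (
    CohortConfig,
    generate_cohort,
    generate_responses,
    generate_trial,
    participants_frame,
    simulate_cohort,
)
from .cohort_stats import describe_cohort
from .dual_task import weighted_dtc_table
from .io import read_participants, read_trial, trial_filename, write_participants, write_trial
from .kinematics import build_feature_table, extract_trial_features, feature_table_wide
from .pooling import ScreeningConfig, build_pooled_indices
from .signals import CL_LEVELS, EXERCISES

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    exercises: tuple = EXERCISES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    ridge: float = 1e-6

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = [e for e in self.exercises if e not in EXERCISES]
        if unknown:
            raise ValueError(f"unknown exercises {unknown}")
        self.cohort.seed = self.seed
        self.cohort.validate()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """Stage runner bound to one output directory."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.cfg.out_dir.mkdir(parents=True, exist_ok=True)
        self.artifacts: dict[str, str] = {}
        self.warning_counts: dict[str, int] = {}

    def _register(self, *paths: Path) -> None:
        for p in paths:
            self.artifacts[str(p.relative_to(self.cfg.out_dir))] = _sha256(p)

    def simulate(self) -> None:
        cfg = self.cfg
        trials_dir = cfg.out_dir / "trials"
        trials_dir.mkdir(exist_ok=True)
        participants = generate_cohort(cfg.cohort)
        pf = participants_frame(participants)
        p_path = write_participants(pf, cfg.out_dir / "participants.csv")
        rows = []
        for p in participants:
            for ex in cfg.exercises:
                for cl in CL_LEVELS:
                    rec, _ = generate_trial(p, ex, cl, cfg.cohort)
                    path = trials_dir / trial_filename(p.id, ex, cl)
                    write_trial(rec, path)
                    self._register(path)
                    if cl != "CL0":
                        rows.append(
                            dict(participant_id=p.id, exercise=ex, cl=cl,
                                 nc=generate_responses(p, ex, cl, cfg.cohort))
                        )
        nc_path = cfg.out_dir / "responses.csv"
        pd.DataFrame(rows).to_csv(nc_path, index=False)
        self._register(p_path, nc_path)

    def extract(self) -> None:
        cfg = self.cfg
        trials_dir = cfg.out_dir / "trials"
        feats = {}
        for path in sorted(trials_dir.glob("*.csv")):
            rec = read_trial(path)
            if rec.exercise not in cfg.exercises:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                feats[(rec.participant_id, rec.exercise, rec.cl)] = extract_trial_features(rec)
        tidy = build_feature_table(feats)
        tidy.to_csv(cfg.out_dir / "features.csv", index=False)
        feature_table_wide(tidy).to_csv(cfg.out_dir / "features_wide.csv")
        self._register(cfg.out_dir / "features.csv", cfg.out_dir / "features_wide.csv")

    def dtc(self) -> None:
        cfg = self.cfg
        tidy = pd.read_csv(cfg.out_dir / "features.csv")
        nc = pd.read_csv(cfg.out_dir / "responses.csv")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            table = weighted_dtc_table(tidy, nc)
        self.warning_counts["dtc"] = len(caught)
        table.to_csv(cfg.out_dir / "dtc.csv", index=False)
        self._register(cfg.out_dir / "dtc.csv")

    def pool(self) -> None:
        cfg = self.cfg
        dtc_table = pd.read_csv(cfg.out_dir / "dtc.csv")
        participants = read_participants(cfg.out_dir / "participants.csv")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores, report = build_pooled_indices(dtc_table, participants, cfg.screening)
        scores.index.name = "participant_id"
        scores.to_csv(cfg.out_dir / "pooled_indices.csv")
        (cfg.out_dir / "screening_report.json").write_text(json.dumps(report, indent=2))
        self._register(cfg.out_dir / "pooled_indices.csv", cfg.out_dir / "screening_report.json")

    def classify(self) -> None:
        cfg = self.cfg
        scores = pd.read_csv(cfg.out_dir / "pooled_indices.csv").set_index("participant_id")
        participants = read_participants(cfg.out_dir / "participants.csv").set_index("id")
        reports = {}
        summary_rows = []
        for ex in scores.columns:
            data = pd.DataFrame(
                {
                    "group": participants["group"],
                    "pooled_index": scores[ex],
                    "age": participants["age"],
                    "fab": participants["fab"],
                }
            )
            for outcome in ("binary", "ternary"):
                spec = ModelSpec(outcome=outcome, ridge=cfg.ridge)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rep = evaluate_model(data, spec)
                key = f"{ex}_{outcome}"
                reports[key] = dict(
                    exercise=ex,
                    outcome=outcome,
                    predictors=list(spec.predictors),
                    confusion=rep.confusion.to_dict(),
                    confusion_row_percent=confusion_row_percent(rep.confusion).to_dict(),
                    metrics=rep.metrics,
                )
                if outcome == "binary":
                    summary_rows.append(
                        dict(exercise=ex, problem="MCI_vs_OA",
                             sensitivity=round(rep.metrics["sensitivity"]),
                             specificity=round(rep.metrics["specificity"]),
                             accuracy=round(rep.metrics["accuracy"]))
                    )
                else:
                    summary_rows.append(
                        dict(exercise=ex, problem="OA_vs_SCI_vs_MCI",
                             recall=round(rep.metrics["weighted_recall"]),
                             precision=round(rep.metrics["weighted_precision"]),
                             f1=round(rep.metrics["weighted_f1"]),
                             accuracy=round(rep.metrics["overall_accuracy"]))
                    )
        (self.cfg.out_dir / "classification.json").write_text(json.dumps(reports, indent=2))
        pd.DataFrame(summary_rows).to_csv(cfg.out_dir / "classification_summary.csv", index=False)
        self._register(cfg.out_dir / "classification.json",
                       cfg.out_dir / "classification_summary.csv")

    def describe(self) -> None:
        participants = read_participants(self.cfg.out_dir / "participants.csv")
        summary = describe_cohort(participants)
        (self.cfg.out_dir / "cohort_summary.json").write_text(json.dumps(summary, indent=2))
        self._register(self.cfg.out_dir / "cohort_summary.json")

    def write_manifest(self) -> Path:
        manifest = dict(
            seed=self.cfg.seed,
            version=__version__,
            exercises=list(self.cfg.exercises),
            warnings=self.warning_counts,
            artifacts=self.artifacts,
        )
        path = self.cfg.out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2))
        return path


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage in order and return the manifest path."""
    run = PipelineRun(cfg)
    for stage in ("simulate", "extract", "dtc", "pool", "classify", "describe"):
        log.info("stage %s", stage)
        getattr(run, stage)()
    return run.write_manifest()


def run_study(
    cohort_cfg: CohortConfig | None = None,
    exercises: tuple = EXERCISES,
    screening: ScreeningConfig | None = None,
    ridge: float = 1e-6,
) -> dict:
    """In-memory end-to-end analysis of one simulated study.

    Simulates the cohort, extracts features, computes weighted dual-task
    costs, pools them per exercise and leave-one-out-validates both
    classification problems.  Returns a dict with the participants frame,
    tidy feature/cost tables, pooled scores, the screening report and one
    ClassificationReport per (exercise, problem).
    """
    cohort_cfg = cohort_cfg or CohortConfig()
    participants, trials, responses = simulate_cohort(cohort_cfg, exercises)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        features = build_feature_table({k: v[0] for k, v in trials.items()})
        dtc_table = weighted_dtc_table(features, responses)
        pf = participants_frame(participants)
        scores, screen_report = build_pooled_indices(dtc_table, pf, screening)
        reports = {}
        base = pf.set_index("id")
        for ex in scores.columns:
            data = pd.DataFrame(
                {
                    "group": base["group"],
                    "pooled_index": scores[ex],
                    "age": base["age"],
                    "fab": base["fab"],
                }
            )
            for outcome in ("binary", "ternary"):
                reports[(ex, outcome)] = evaluate_model(data, ModelSpec(outcome=outcome, ridge=ridge))
    return dict(
        participants=pf,
        features=features,
        dtc=dtc_table,
        pooled=scores,
        screening=screen_report,
        reports=reports,
        truths={k: v[1] for k, v in trials.items()},
    )
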