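"""End-to-end orchestration: data -> windows -> features -> selection -> RF.

``run_pipeline`` executes the five-experiment comparison: a random forest on
the best nine selected features of each of the three datasets (day, night,
full day), plus the night-selected nine-feature set applied to the day and
full-day datasets (the cross-application that tests whether the night
features generalize).  ``run_all`` additionally writes every artifact (three
feature matrices, three selection traces, the best-set table, the experiment
report, a run log) to an output directory.
"""

from __future__ import annotations

import logging
import time

import numpy as np
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import actidep
from actidep.classify import ExperimentResult, RFConfig, run_experiment
from actidep.features import FEATURE_NAMES, FeatureVector, extract_all
from actidep.io_depresjon import read_cohort_dir
from actidep.preprocess import (
    SCHEMES,
    HourWindow,
    equalize_lengths,
    fit_standardization,
    segment_hours,
    split_by_segment,
    standardize,
)
from actidep.selection import SelectionTrace, SplitSpec, forward_select, split_indices
from actidep.synthetic import CohortConfig, generate_cohort
from actidep.validate import format_percent

logger = logging.getLogger(__name__)

DATASETS = ("day", "night", "full")


@dataclass
class PipelineConfig:
    """One run's data source, preprocessing and modelling settings.

    Exactly one of ``input_dir`` (a directory of Depresjon-dialect files) or
    ``simulate`` (a synthetic cohort spec) must be set.  ``global_stats``
    chooses whether standardization statistics are fitted on the training
    portion only (leakage-free default) or on the whole dataset.
    ``compare_k`` pins the feature-set size used in the experiment table so
    all datasets are compared under the same model size.
    """

    input_dir: str | Path | None = None
    simulate: CohortConfig | None = None
    equalize: int | str = "auto"
    global_stats: str = "train"  # "train" | "all"
    split_spec: SplitSpec = SplitSpec(train_fraction=0.70, seed=0, stratified=True)
    rf_config: RFConfig = RFConfig()
    max_features: int = 10
    compare_k: int = 9
    run_selection: bool = True
    feature_sets: dict | None = None  # dataset -> explicit indices, skips FS

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError("exactly one of input_dir or simulate must be set")
        if self.global_stats not in ("train", "all"):
            raise ValueError("global_stats must be 'train' or 'all'")


@dataclass
class PipelineResult:
    """All per-dataset artifacts of one run."""

    vectors: dict[str, list[FeatureVector]] = field(default_factory=dict)
    traces: dict[str, SelectionTrace] = field(default_factory=dict)
    best_sets: dict[str, tuple[int, ...]] = field(default_factory=dict)
    experiments: list[ExperimentResult] = field(default_factory=list)

    def experiment(self, name: str) -> ExperimentResult:
        for e in self.experiments:
            if e.dataset == name:
                return e
        raise KeyError(name)


def build_windows(config: PipelineConfig) -> list[HourWindow]:
    """Load or simulate the cohort and cut it into labelled hour windows."""
    if config.simulate is not None:
        cohort, _ = generate_cohort(config.simulate)
    else:
        cohort = read_cohort_dir(config.input_dir)
    cohort = equalize_lengths(cohort, config.equalize)
    windows: list[HourWindow] = []
    for series in cohort:
        windows.extend(segment_hours(series))
    return windows


def dataset_vectors(windows: list[HourWindow], dataset: str, config: PipelineConfig) -> list[FeatureVector]:
    """Segment-filter, standardize and featurize one dataset's windows.

    Standardization statistics are pooled over the dataset's training
    portion (or the whole dataset when ``global_stats: all``); the 70/30
    partition here is the same one selection and classification re-derive,
    since it depends only on the label sequence and the split seed.
    """
    subset = split_by_segment(windows, SCHEMES[dataset])
    if config.global_stats == "train":
        labels = np.array([w.label for w in subset])
        train_idx, _ = split_indices(labels, config.split_spec)
        stats = fit_standardization([subset[i] for i in train_idx])
    else:
        stats = fit_standardization(subset)
    return extract_all(standardize(subset, stats))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute segmentation, selection and the five-experiment comparison."""
    result = PipelineResult()
    t0 = time.time()
    windows = build_windows(config)
    logger.info("segmented %d hour windows in %.1fs", len(windows), time.time() - t0)

    for name in DATASETS:
        t0 = time.time()
        vecs = dataset_vectors(windows, name, config)
        result.vectors[name] = vecs
        if config.feature_sets and name in config.feature_sets:
            result.best_sets[name] = tuple(sorted(config.feature_sets[name]))
        elif config.run_selection:
            trace = forward_select(vecs, config.split_spec, config.max_features)
            result.traces[name] = trace
            try:
                result.best_sets[name] = trace.best_set(config.compare_k)
            except KeyError:
                result.best_sets[name] = trace.best_set()
        else:
            result.best_sets[name] = tuple(range(len(FEATURE_NAMES)))
        logger.info("dataset %s: %d windows, best set %s (%.1fs)",
                    name, len(vecs), result.best_sets[name], time.time() - t0)

    experiments = [
        ("best9_day", "day", result.best_sets["day"]),
        ("best9_night", "night", result.best_sets["night"]),
        ("best9_full", "full", result.best_sets["full"]),
        ("night9_on_day", "day", result.best_sets["night"]),
        ("night9_on_full", "full", result.best_sets["night"]),
    ]
    for exp_name, ds, feats in experiments:
        t0 = time.time()
        res = run_experiment(result.vectors[ds], feats, config.split_spec,
                             config.rf_config, dataset_name=exp_name)
        result.experiments.append(res)
        logger.info("experiment %s: accuracy %s (%.1fs)",
                    exp_name, format_percent(res.report.accuracy), time.time() - t0)
    return result


def _write_features_csv(vectors: list[FeatureVector], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("subject_id,label,date,hour," + ",".join(f"f{i}" for i in range(24)) + "\n")
        for v in vectors:
            feats = ",".join(repr(float(x)) for x in v.features)
            fh.write(f"{v.subject_id},{v.label},{v.date},{v.hour},{feats}\n")


def write_report_csv(experiments: list[ExperimentResult], path: Path) -> None:
    """Experiment table: counts plus the five metrics as 2-decimal percents."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("model,TP,TN,FP,FN,sensitivity,specificity,PPV,NPV,accuracy\n")
        for e in experiments:
            p = e.report.as_percent_strings()
            fh.write(
                f"{e.dataset},{e.counts.tp},{e.counts.tn},{e.counts.fp},{e.counts.fn},"
                f"{p['sensitivity']},{p['specificity']},{p['ppv']},{p['npv']},{p['accuracy']}\n"
            )


def run_all(config: PipelineConfig, output_dir: str | Path) -> PipelineResult:
    """Run the pipeline and write every artifact under ``output_dir``."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    result = run_pipeline(config)

    for name in DATASETS:
        _write_features_csv(result.vectors[name], output_dir / f"features_{name}.csv")
        if name in result.traces:
            result.traces[name].to_csv(output_dir / f"selection_{name}.csv")
    with open(output_dir / "best_sets.csv", "w", encoding="utf-8") as fh:
        fh.write("dataset,features\n")
        for name in DATASETS:
            fh.write(f"{name},\"[{','.join(map(str, result.best_sets[name]))}]\"\n")
    write_report_csv(result.experiments, output_dir / "report.csv")

    log = {
        "package_version": actidep.__version__,
        "split_seed": config.split_spec.seed,
        "rf_seed": config.rf_config.seed,
        "simulate_seed": config.simulate.seed if config.simulate else None,
        "global_stats": config.global_stats,
        "equalize": config.equalize,
        "n_windows": {name: len(result.vectors[name]) for name in DATASETS},
        "best_sets": {name: list(result.best_sets[name]) for name in DATASETS},
        "accuracies": {e.dataset: e.report.accuracy for e in result.experiments},
    }
    with open(output_dir / "run_log.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
    return result
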