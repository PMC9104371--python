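"""End-to-end orchestration and reference-table verification.

``run_pipeline`` chains generate -> preprocess -> embed -> train ->
score -> calibrate -> decide -> evaluate -> word cloud as one logged,
seeded run that writes all artifacts plus a manifest into a run
directory.  A single global seed fans out deterministically to per-stage
seeds, so a rerun with the same config is bit-identical for the
deterministic stages.

``verify_reference_tables`` recomputes the metric suite from the bundled
reference-study confusion matrices and checks it against the published
values (tolerance ±0.02 percentage points, which also absorbs the two
truncated cells).  Against the printed matrix orientation the published
"WeightedPrecision" row equals support-weighted one-vs-all recall and
"WeightedRecall" equals support-weighted precision; the comparison maps
rows accordingly (see the fixture file for details).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    CalibrationConfig,
    CalibrationResult,
    decide_all,
    calibrate,
    thresholds_to_yaml,
)
from .cloud import DEFAULT_MIN_COUNT, render_cloud, table_to_tsv, term_frequencies
from .embedding import HashEmbedding
from .evaluation import (
    MetricReport,
    confusion_matrix,
    matrix_to_tsv,
    misclassification_report,
    report_to_json,
    weighted_one_vs_all,
    ConfusionMatrix3,
    accuracy as matrix_accuracy,
)
from .labels import CLASSES
from .regressors import (
    MLPConfig,
    SVRConfig,
    score_corpus,
    train_mlp,
    train_svr,
    validation_accuracy,
)
from .synthetic_data import (
    STUDY_STRATA,
    LexiconConfig,
    StratumSpec,
    default_lexicon,
    generate_binary_corpus,
    generate_survey_corpus,
    strata_from_yaml,
    write_binary_csv,
    write_survey_csv,
)
from .text_prep import default_stopwords, load_stopwords

log = logging.getLogger("trisent.pipeline")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one full pipeline run."""

    out_dir: Path
    model: str = "mlp"  # "mlp" | "svm"
    strata: tuple[StratumSpec, ...] = STUDY_STRATA
    polarity_purity: float = 0.9
    noise_rate: float = 0.2
    binary_n: int = 2000
    binary_balance: float = 0.5
    split_ratio: float = 0.8
    embedding_dimension: int = 20
    polarity_axis: int | None = 0
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    min_count: int = DEFAULT_MIN_COUNT
    seed: int = 0
    strata_yaml: Path | None = None
    stopwords_path: Path | None = None

    def __post_init__(self) -> None:
        if self.model not in ("mlp", "svm"):
            raise ValueError(f"model must be 'mlp' or 'svm', got {self.model!r}")
        for path in (self.strata_yaml, self.stopwords_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input path does not exist: {path}")


@dataclass(frozen=True)
class RunResult:
    out_dir: Path
    report: MetricReport
    cm: ConfusionMatrix3
    calibration: CalibrationResult
    binary_validation_accuracy: float
    n_testimonies: int


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Fan a single global seed out into independent per-stage seeds."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full sentiment pipeline and write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    strata = (
        tuple(strata_from_yaml(config.strata_yaml)) if config.strata_yaml else config.strata
    )
    stopwords = (
        default_stopwords()
        if config.stopwords_path is None
        else load_stopwords(config.stopwords_path)
    )

    log.info("stage=generate strata=%d seed=%d", len(strata), seeds[0])
    survey_lexicon = default_lexicon(
        polarity_purity=config.polarity_purity, noise_rate=config.noise_rate, seed=seeds[0]
    )
    testimonies = generate_survey_corpus(strata, survey_lexicon)
    write_survey_csv(testimonies, out / "survey.csv")

    binary_lexicon = default_lexicon(
        polarity_purity=config.polarity_purity, noise_rate=config.noise_rate, seed=seeds[1]
    )
    binary = generate_binary_corpus(
        config.binary_n, config.binary_balance, binary_lexicon, config.split_ratio
    )
    write_binary_csv(binary, out / "binary.csv")
    log.info("stage=generate testimonies=%d binary=%d", len(testimonies), len(binary))

    provider = HashEmbedding(
        dimension=config.embedding_dimension,
        seed=seeds[2],
        polarity_axis=config.polarity_axis,
        lexicon=survey_lexicon,
    )

    log.info("stage=train model=%s", config.model)
    if config.model == "mlp":
        scorer = train_mlp(binary, provider, MLPConfig(input_dim=provider.dimension, seed=seeds[3]))
    else:
        scorer = train_svr(binary, provider, SVRConfig(seed=seeds[3]))
    bin_acc = validation_accuracy(scorer, binary)
    log.info("stage=train binary_validation_accuracy=%.4f", bin_acc)

    log.info("stage=score n=%d", len(testimonies))
    scored = score_corpus(testimonies, scorer)
    pd.DataFrame(scored, columns=["id", "score"]).to_csv(out / "scores.csv", index=False)

    log.info("stage=calibrate k=%d", config.calibration.k_folds)
    labeled = [(s, t.gold) for (_, s), t in zip(scored, testimonies)]
    calib = calibrate(labeled, dataclasses.replace(config.calibration, seed=seeds[4]))
    thresholds_to_yaml(
        calib.thresholds, out / "thresholds.yaml", model=config.model,
        dataset="synthetic-survey", config=calib.config,
    )

    predictions = decide_all([s for _, s in scored], calib.thresholds)
    pd.DataFrame(
        {
            "id": [t.id for t in testimonies],
            "gold": [t.gold for t in testimonies],
            "predicted": predictions,
        }
    ).to_csv(out / "predictions.csv", index=False)

    log.info("stage=evaluate")
    cm = confusion_matrix(list(zip(predictions, [t.gold for t in testimonies])))
    report = weighted_one_vs_all(cm)
    matrix_to_tsv(cm, out / "confusion.tsv")
    report_to_json(report, out / "metrics.json")
    mis = misclassification_report(testimonies, predictions)
    pd.DataFrame(
        [(e.id, e.gold, e.predicted, e.text) for e in mis.entries],
        columns=["id", "gold", "predicted", "text"],
    ).to_csv(out / "misclassifications.csv", index=False)

    log.info("stage=wordcloud min_count=%d", config.min_count)
    table = term_frequencies(testimonies, stopwords, config.min_count)
    table_to_tsv(table, out / "terms.tsv")
    if table.entries:
        render_cloud(table, out / "cloud.png", seed=seeds[5])

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "model": config.model,
        "config": {
            "polarity_purity": config.polarity_purity,
            "noise_rate": config.noise_rate,
            "binary_n": config.binary_n,
            "binary_balance": config.binary_balance,
            "split_ratio": config.split_ratio,
            "embedding_dimension": config.embedding_dimension,
            "polarity_axis": config.polarity_axis,
            "k_folds": config.calibration.k_folds,
            "grid_step": config.calibration.grid_step,
            "min_count": config.min_count,
        },
        "strata": [dataclasses.asdict(s) for s in strata],
        "counts": {"testimonies": len(testimonies), "binary": len(binary)},
        "binary_validation_accuracy": bin_acc,
        "thresholds": {
            "t_neu_neg": calib.thresholds.t_neu_neg,
            "t_pos_neu": calib.thresholds.t_pos_neu,
        },
        "accuracy": report.accuracy,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    log.info("stage=done accuracy=%.2f", report.accuracy)
    return RunResult(
        out_dir=out,
        report=report,
        cm=cm,
        calibration=calib,
        binary_validation_accuracy=bin_acc,
        n_testimonies=len(testimonies),
    )


# ---------------------------------------------------------------------------
# Reference-table verification


def load_reference_tables() -> dict:
    text = resources.files("trisent.data").joinpath("reference_tables.yaml").read_text("utf-8")
    return yaml.safe_load(text)


@dataclass(frozen=True)
class VerificationFailure:
    dataset: str
    metric: str
    expected: float
    computed: float


@dataclass(frozen=True)
class VerificationReport:
    checks: int
    failures: tuple[VerificationFailure, ...]

    @property
    def passed(self) -> bool:
        return not self.failures


def verify_reference_tables(tables: dict | None = None, tolerance: float = 0.02) -> VerificationReport:
    """Recompute the metric suite from the bundled matrices and compare.

    Row mapping between published labels and standard definitions (the
    published precision/recall row labels are swapped relative to the
    printed rows-predicted matrices):

    ==================  ==========================================
    published row       computed quantity
    ==================  ==========================================
    weighted_accuracy   support-weighted one-vs-all accuracy
    weighted_precision  support-weighted one-vs-all recall
    weighted_recall     support-weighted one-vs-all precision
    weighted_f1         support-weighted one-vs-all F1
    accuracy            trace / total
    ==================  ==========================================
    """
    tables = tables or load_reference_tables()
    failures: list[VerificationFailure] = []
    checks = 0
    for name, rows in tables["confusion_matrices"].items():
        cm = ConfusionMatrix3.from_array(rows)
        report = weighted_one_vs_all(cm)
        computed = {
            "weighted_accuracy": report.weighted_accuracy,
            "weighted_precision": report.weighted_recall,
            "weighted_recall": report.weighted_precision,
            "weighted_f1": report.weighted_f1,
            "accuracy": report.accuracy,
        }
        for metric, expected in tables["expected_metrics"][name].items():
            checks += 1
            if abs(computed[metric] - expected) > tolerance:
                failures.append(
                    VerificationFailure(
                        dataset=name,
                        metric=metric,
                        expected=float(expected),
                        computed=round(computed[metric], 4),
                    )
                )
    return VerificationReport(checks=checks, failures=tuple(failures))
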