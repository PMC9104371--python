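"""Interval-based decision stage: trichotomize scores via two thresholds.

A score O in [-1, 1] is mapped to a class by two boundaries
``t_neu_neg <= t_pos_neu`` (the outer limits are fixed at -1 and +1):

* negative  if O <  t_neu_neg
* neutral   if t_neu_neg <= O < t_pos_neu
* positive  if O >= t_pos_neu

Boundary membership (half-open, lower-inclusive neutral, positive owning
its boundary) is a convention of this implementation.

The boundaries are calibrated by k-fold cross-validation over labeled
scores: for each fold, an exhaustive grid search over ordered threshold
pairs maximizes 3-class accuracy on the k-1 training folds (the held-out
fold's accuracy is recorded as the fold's validation estimate), and the
final :class:`ThresholdPair` is the arithmetic mean of the per-fold
optima.  Ties in the grid search are broken toward the maximizer nearest
the centroid of the maximizing set — the centered, max-margin choice —
then lexicographically, so calibration is deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .labels import CLASSES, NEGATIVE, NEUTRAL, POSITIVE, validate_label


@dataclass(frozen=True)
class ThresholdPair:
    """The two calibrated interval boundaries of the decision stage."""

    t_neu_neg: float
    t_pos_neu: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.t_neu_neg <= self.t_pos_neu <= 1.0:
            raise ValueError(
                "thresholds must satisfy -1 <= t_neu_neg <= t_pos_neu <= 1, "
                f"got ({self.t_neu_neg}, {self.t_pos_neu})"
            )


@dataclass(frozen=True)
class CalibrationConfig:
    k_folds: int = 5
    grid_step: float = 0.01
    stratified: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not 0.0 < self.grid_step <= 0.5:
            raise ValueError("grid_step must lie in (0, 0.5]")


@dataclass(frozen=True)
class CalibrationResult:
    thresholds: ThresholdPair
    fold_thresholds: tuple[ThresholdPair, ...]
    fold_holdout_accuracy: tuple[float, ...]
    config: CalibrationConfig


def decide(score: float, thresholds: ThresholdPair) -> str:
    """Map a sentiment score in [-1, 1] to its class via the interval rule."""
    if not -1.0 <= score <= 1.0:
        raise ValueError(f"score must lie in [-1, 1], got {score}")
    if score < thresholds.t_neu_neg:
        return NEGATIVE
    if score < thresholds.t_pos_neu:
        return NEUTRAL
    return POSITIVE


def decide_all(scores: Sequence[float], thresholds: ThresholdPair) -> list[str]:
    return [decide(s, thresholds) for s in scores]


def threshold_grid(grid_step: float) -> np.ndarray:
    """Evenly spaced candidate thresholds covering [-1, 1]."""
    n = int(round(2.0 / grid_step)) + 1
    return np.linspace(-1.0, 1.0, n)


def _grid_search(scores: np.ndarray, golds: np.ndarray, grid: np.ndarray) -> tuple[int, int, float]:
    """Exhaustive accuracy maximization over ordered grid pairs.

    Returns (i, j, best_accuracy) with grid[i] <= grid[j]; ties resolved
    toward the maximizer closest to the centroid of the maximizing set,
    then lexicographically.
    """
    n = len(scores)
    below = {}
    for k, cls in enumerate(CLASSES):
        cls_scores = np.sort(scores[golds == k])
        below[cls] = np.searchsorted(cls_scores, grid, side="left")
    n_pos_total = int(np.sum(golds == 2))
    # correct = negatives below t1 + neutrals in [t1, t2) + positives >= t2
    correct = (
        below[NEGATIVE][:, None]
        - below[NEUTRAL][:, None]
        + below[NEUTRAL][None, :]
        - below[POSITIVE][None, :]
        + n_pos_total
    ).astype(float)
    ii, jj = np.meshgrid(np.arange(len(grid)), np.arange(len(grid)), indexing="ij")
    correct[ii > jj] = -1.0  # enforce t_neu_neg <= t_pos_neu
    best = correct.max()
    cand_i, cand_j = np.nonzero(correct == best)
    ci, cj = cand_i.mean(), cand_j.mean()
    dist = (cand_i - ci) ** 2 + (cand_j - cj) ** 2
    # nearest-to-centroid; numpy argmin takes the first (lexicographic) tie
    pick = int(np.argmin(dist))
    return int(cand_i[pick]), int(cand_j[pick]), best / n


def _fold_indices(n: int, config: CalibrationConfig, golds: np.ndarray) -> list[np.ndarray]:
    rng = np.random.default_rng(config.seed)
    if not config.stratified:
        return [np.sort(f) for f in np.array_split(rng.permutation(n), config.k_folds)]
    folds: list[list[int]] = [[] for _ in range(config.k_folds)]
    offset = 0
    for k in range(len(CLASSES)):
        idx = rng.permutation(np.nonzero(golds == k)[0])
        for pos, item in enumerate(idx):
            folds[(pos + offset) % config.k_folds].append(int(item))
        offset += len(idx)
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def calibrate(
    scored: Sequence[tuple[float, str]],
    config: CalibrationConfig | None = None,
) -> CalibrationResult:
    """Cross-validate the two decision boundaries over labeled scores.

    Requires at least ``k_folds`` items and all three classes present.
    The returned mean pair always satisfies the ordering invariant, since
    every per-fold pair does and averaging preserves the order.
    """
    config = config or CalibrationConfig()
    if len(scored) < config.k_folds:
        raise ValueError(
            f"need at least k_folds={config.k_folds} labeled scores, got {len(scored)}"
        )
    scores = np.asarray([s for s, _ in scored], dtype=float)
    if scores.size and (scores.min() < -1.0 or scores.max() > 1.0):
        raise ValueError("all scores must lie in [-1, 1]")
    golds = np.asarray([CLASSES.index(validate_label(g)) for _, g in scored])
    if len(np.unique(golds)) < len(CLASSES):
        raise ValueError("all three classes must be represented in the calibration data")
    grid = threshold_grid(config.grid_step)
    folds = _fold_indices(len(scored), config, golds)
    fold_pairs: list[ThresholdPair] = []
    holdout_acc: list[float] = []
    for fold in folds:
        mask = np.ones(len(scored), dtype=bool)
        mask[fold] = False
        i, j, _ = _grid_search(scores[mask], golds[mask], grid)
        pair = ThresholdPair(float(grid[i]), float(grid[j]))
        fold_pairs.append(pair)
        if fold.size:
            held = np.asarray(decide_all(scores[fold], pair))
            holdout_acc.append(float(np.mean(held == np.asarray(CLASSES)[golds[fold]])))
        else:
            holdout_acc.append(float("nan"))
    mean_pair = ThresholdPair(
        float(np.mean([p.t_neu_neg for p in fold_pairs])),
        float(np.mean([p.t_pos_neu for p in fold_pairs])),
    )
    return CalibrationResult(
        thresholds=mean_pair,
        fold_thresholds=tuple(fold_pairs),
        fold_holdout_accuracy=tuple(holdout_acc),
        config=config,
    )


# ---------------------------------------------------------------------------
# Published threshold presets and YAML serialisation


def load_threshold_presets() -> dict[str, ThresholdPair]:
    """Named threshold pairs transcribed from the reference study
    (mlp-students, mlp-staff, svm-students, svm-staff), usable without
    retraining."""
    text = resources.files("trisent.data").joinpath("reference_tables.yaml").read_text("utf-8")
    raw = yaml.safe_load(text)
    return {
        name: ThresholdPair(float(v["t_neu_neg"]), float(v["t_pos_neu"]))
        for name, v in raw["threshold_presets"].items()
    }


def thresholds_to_yaml(
    pair: ThresholdPair,
    path: str | Path,
    model: str = "",
    dataset: str = "",
    config: CalibrationConfig | None = None,
) -> None:
    payload = {
        "model": model,
        "dataset": dataset,
        "t_pos_neu": pair.t_pos_neu,
        "t_neu_neg": pair.t_neu_neg,
    }
    if config is not None:
        payload.update(
            {"k_folds": config.k_folds, "grid_step": config.grid_step, "seed": config.seed}
        )
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def thresholds_from_yaml(path: str | Path) -> ThresholdPair:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return ThresholdPair(float(raw["t_neu_neg"]), float(raw["t_pos_neu"]))
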