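"""Patient-level splitting, training, and repeated-experiment harness.

Splits are always at the patient level (6:2:2 train/validation/test by
largest-remainder apportionment) so that no patient's windows ever appear
in two partitions. Training minimizes mean squared error on normalized
glucose with Adam (batch 512, learning rate 0.001 by default), keeping the
best-on-validation parameters. ``run_experiment`` repeats the whole
split/train/evaluate cycle with derived seeds and aggregates each metric as
mean +- SD, with paired t-tests comparing the full attention model against
the ablated variants (plain GRU, stacked GRU without attention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from sagru.cgm_data import Cohort
from sagru.metrics import (
    DegenerateTTestError,
    MetricReport,
    evaluate_predictions,
    mean_sd,
    paired_t_test,
    rmse as rmse_metric,
)
from sagru.model import (
    SAGRUConfig,
    forward_with_cache,
    init_params,
    sagru_backward,
    sagru_forward,
)
from sagru.preprocess import (
    NormalizationBounds,
    WindowDataset,
    denormalize_glucose,
    normalize_glucose,
    windows_from_cohort,
)

logger = logging.getLogger(__name__)

VARIANTS = ("gru", "stacked", "sagru")


# ---------------------------------------------------------------------------
# patient-level splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test ratios (default 6:2:2) and the shuffle seed."""

    ratios: tuple[float, float, float] = (6.0, 2.0, 2.0)
    seed: int = 0

    def __post_init__(self):
        if len(self.ratios) != 3 or any(r < 0 for r in self.ratios) or sum(self.ratios) <= 0:
            raise ValueError(f"invalid ratios {self.ratios}")


def apportion(n: int, ratios: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of ``n`` items over ``ratios``.

    Remainder ties are broken in ratio order (train, validation, test), so
    a 6:2:2 split gives the validation and test partitions equal counts
    whenever their remainders tie and two seats remain.
    """
    total = float(sum(ratios))
    quotas = [n * r / total for r in ratios]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    seats = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: (-remainders[i], i))
    for i in order[:seats]:
        counts[i] += 1
    return counts


def split_patients(cohort: Cohort, spec: SplitSpec) -> tuple[Cohort, Cohort, Cohort]:
    """Randomly assign whole patients to train/validation/test partitions.

    The assignment is disjoint and exhaustive by construction and is
    re-asserted before returning. Requires at least 3 patients.
    """
    n = len(cohort)
    if n < 3:
        raise ValueError(f"need at least 3 patients to split, got {n}")
    counts = apportion(n, spec.ratios)
    rng = np.random.default_rng(spec.seed)
    ids = list(cohort.patient_ids)
    perm = rng.permutation(n)
    shuffled = [ids[i] for i in perm]
    train_ids = shuffled[: counts[0]]
    val_ids = shuffled[counts[0] : counts[0] + counts[1]]
    test_ids = shuffled[counts[0] + counts[1] :]

    parts = (set(train_ids), set(val_ids), set(test_ids))
    assert sum(len(p) for p in parts) == n
    assert parts[0] | parts[1] | parts[2] == set(ids)
    assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2]), \
        "patient leaked into two partitions"

    return (
        cohort.subset(train_ids, name=f"{cohort.name}-train"),
        cohort.subset(val_ids, name=f"{cohort.name}-val"),
        cohort.subset(test_ids, name=f"{cohort.name}-test"),
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the reference training setup (Adam, batch 512, learning
    rate 0.001); ``epochs`` defaults to a desk-scale 50 rather than the
    full 500. ``loss`` is MSE on normalized glucose ("mse") or MAE ("mae").
    ``select`` picks the returned parameters: best validation loss
    ("best_val") or the final epoch ("last"). ``lr_decay_epochs`` optionally
    multiplies the learning rate by ``lr_decay_factor`` at the start of the
    listed epochs (a simple step schedule; off by default).
    """

    batch_size: int = 512
    learning_rate: float = 1e-3
    epochs: int = 50
    loss: str = "mse"
    select: str = "best_val"
    seed: int = 0
    lr_decay_epochs: tuple[int, ...] = ()
    lr_decay_factor: float = 0.3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.loss not in ("mse", "mae"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.select not in ("best_val", "last"):
            raise ValueError(f"unknown selection rule {self.select!r}")
        if not 0 < self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must be in (0, 1]")


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


@dataclass
class TrainResult:
    params: dict
    model_config: SAGRUConfig
    history: pd.DataFrame  # columns: epoch, train_loss, val_loss
    best_epoch: int
    bounds: NormalizationBounds


def _loss_and_grad(y, t, kind):
    """Loss value and dL/dy for a batch of normalized predictions."""
    d = y - t
    if kind == "mse":
        return float(np.mean(d * d)), 2.0 * d / d.size
    return float(np.mean(np.abs(d))), np.sign(d) / d.size


def _epoch_loss(params, config, X, t_norm, kind, batch_size=4096):
    total = 0.0
    for i in range(0, len(t_norm), batch_size):
        y = sagru_forward(X[i : i + batch_size], params, config)
        d = y - t_norm[i : i + batch_size]
        total += float(np.sum(d * d) if kind == "mse" else np.sum(np.abs(d)))
    return total / len(t_norm)


def train_model(
    train_windows: WindowDataset,
    val_windows: WindowDataset,
    model_config: SAGRUConfig,
    train_config: TrainConfig,
) -> TrainResult:
    """Train by mini-batch Adam on normalized targets; fully seeded.

    Returns the parameters with the best validation loss (or the last
    epoch's, per ``train_config.select``) and a per-epoch loss log.
    """
    if len(train_windows) == 0 or len(val_windows) == 0:
        raise ValueError("training and validation sets must be non-empty")
    bounds = train_windows.bounds
    Xtr = train_windows.inputs
    ttr = normalize_glucose(train_windows.targets, bounds)
    Xval = val_windows.inputs
    tval = normalize_glucose(val_windows.targets, bounds)

    rng = np.random.default_rng(train_config.seed)
    params = init_params(model_config, rng)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(vv) for k, vv in params.items()}
    b1, b2, eps = train_config.adam_beta1, train_config.adam_beta2, train_config.adam_eps
    lr = train_config.learning_rate
    step = 0

    best_val = np.inf
    best_params = {k: p.copy() for k, p in params.items()}
    best_epoch = 0
    rows = []
    n = len(ttr)
    for epoch in range(1, train_config.epochs + 1):
        if epoch in train_config.lr_decay_epochs:
            lr *= train_config.lr_decay_factor
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, train_config.batch_size):
            idx = order[i : i + train_config.batch_size]
            y, cache = forward_with_cache(Xtr[idx], params, model_config)
            loss, dy = _loss_and_grad(y, ttr[idx], train_config.loss)
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            epoch_loss += loss * len(idx)
            grads = sagru_backward(dy, cache, params, model_config)
            step += 1
            corr = lr * np.sqrt(1.0 - b2**step) / (1.0 - b1**step)
            for k in params:
                g = grads[k]
                m[k] = b1 * m[k] + (1.0 - b1) * g
                v[k] = b2 * v[k] + (1.0 - b2) * g * g
                params[k] = params[k] - corr * m[k] / (np.sqrt(v[k]) + eps)
        train_loss = epoch_loss / n
        val_loss = _epoch_loss(params, model_config, Xval, tval, train_config.loss)
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: p.copy() for k, p in params.items()}
            best_epoch = epoch

    if train_config.select == "last":
        best_params, best_epoch = params, train_config.epochs
    return TrainResult(
        params=best_params,
        model_config=model_config,
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        bounds=bounds,
    )


def predict_mgdl(params: dict, config: SAGRUConfig, dataset: WindowDataset,
                 batch_size: int = 4096) -> np.ndarray:
    """Model predictions denormalized to mg/dL."""
    outs = []
    for i in range(0, len(dataset), batch_size):
        outs.append(sagru_forward(dataset.inputs[i : i + batch_size], params, config))
    return denormalize_glucose(np.concatenate(outs), dataset.bounds)


def persistence_predictions(dataset: WindowDataset) -> np.ndarray:
    """Naive baseline: forecast the last observed glucose of each window."""
    return dataset.last_observed_mgdl.copy()


def evaluate_model(result: TrainResult, dataset: WindowDataset) -> MetricReport:
    pred = predict_mgdl(result.params, result.model_config, dataset)
    return evaluate_predictions(pred, dataset.targets)


# ---------------------------------------------------------------------------
# variants and repeated experiments
# ---------------------------------------------------------------------------

def variant_factory(name: str, **overrides) -> SAGRUConfig:
    """Model configuration for an ablation variant.

    - ``"gru"``: one 32-unit GRU layer + FC head, no attention
    - ``"stacked"``: two GRU layers, no attention
    - ``"sagru"``: two GRU layers, each followed by an SE attention block
    """
    base = dict(hidden=32, fc_sizes=(128, 32, 1))
    base.update(overrides)
    if name in ("gru", "GRU"):
        return SAGRUConfig(num_gru_layers=1, use_se=False, **base)
    if name in ("stacked", "stacked-gru", "stacked GRU"):
        return SAGRUConfig(num_gru_layers=2, use_se=False, **base)
    if name in ("sagru", "sa-gru", "SA-GRU"):
        return SAGRUConfig(num_gru_layers=2, use_se=True, **base)
    raise ValueError(f"unknown model variant {name!r}; expected one of {VARIANTS}")


@dataclass
class ExperimentResult:
    """Per-repetition metric rows, mean +- SD aggregates, and t-tests.

    ``rows``: one row per (variant, horizon, repetition) with every metric.
    ``aggregates``: mean and SD per (variant, horizon, metric).
    ``ttests``: paired t-tests of the full model against each other variant
    per (horizon, metric); ``t``/``p`` are NaN when degenerate.
    """

    rows: pd.DataFrame
    aggregates: pd.DataFrame
    ttests: pd.DataFrame


AGG_METRICS = ("rmse", "mae", "mard", "accuracy", "precision", "recall")


def run_experiment(
    cohort: Cohort,
    horizons_min: Sequence[int] = (30, 60),
    variants: Sequence[str] = VARIANTS,
    repetitions: int = 10,
    train_config: TrainConfig = TrainConfig(),
    split_ratios: tuple[float, float, float] = (6.0, 2.0, 2.0),
    seed: int = 0,
    reference_variant: str = "sagru",
) -> ExperimentResult:
    """Repeat split -> train -> evaluate for every variant and horizon.

    Repetition ``k`` uses seed ``seed + k`` for both the patient split and
    training, so the whole experiment is a pure function of
    (cohort, configuration, seed).
    """
    rows = []
    for rep in range(repetitions):
        rep_seed = seed + rep
        train_c, val_c, test_c = split_patients(cohort, SplitSpec(split_ratios, seed=rep_seed))
        for horizon in horizons_min:
            ds_train = windows_from_cohort(train_c, horizon)
            ds_val = windows_from_cohort(val_c, horizon)
            ds_test = windows_from_cohort(test_c, horizon)
            persist_rmse = rmse_metric(persistence_predictions(ds_test), ds_test.targets)
            for vi, variant in enumerate(variants):
                config = variant_factory(variant)
                tc = replace(train_config, seed=rep_seed * 1000 + vi)
                result = train_model(ds_train, ds_val, config, tc)
                report = evaluate_model(result, ds_test)
                rows.append(report.to_row(
                    variant=variant, horizon_min=horizon, repetition=rep,
                    persistence_rmse=persist_rmse, best_epoch=result.best_epoch,
                ))
                logger.info(
                    "rep %d h=%d %s: rmse=%.2f acc=%.2f", rep, horizon, variant,
                    report.rmse, report.accuracy,
                )

    frame = pd.DataFrame(rows)
    aggregates = _aggregate(frame, variants, horizons_min)
    ttests = _ttests(frame, variants, horizons_min, reference_variant)
    return ExperimentResult(rows=frame, aggregates=aggregates, ttests=ttests)


def _aggregate(frame: pd.DataFrame, variants, horizons) -> pd.DataFrame:
    out = []
    for variant in variants:
        for horizon in horizons:
            sub = frame[(frame["variant"] == variant) & (frame["horizon_min"] == horizon)]
            for metric in AGG_METRICS:
                vals = sub[metric].dropna().to_numpy(dtype=float)
                if len(vals) == 0:
                    continue
                mean, sd = mean_sd(vals)
                out.append({
                    "variant": variant, "horizon_min": horizon, "metric": metric,
                    "mean": mean, "sd": sd, "n_reps": len(vals),
                })
    return pd.DataFrame(out)


def _ttests(frame: pd.DataFrame, variants, horizons, reference: str) -> pd.DataFrame:
    out = []
    others = [v for v in variants if v != reference]
    if reference not in list(variants):
        return pd.DataFrame(out)
    for horizon in horizons:
        for other in others:
            for metric in ("rmse", "accuracy"):
                a = frame[(frame["variant"] == reference) & (frame["horizon_min"] == horizon)]
                b = frame[(frame["variant"] == other) & (frame["horizon_min"] == horizon)]
                a = a.sort_values("repetition")[metric].to_numpy(dtype=float)
                b = b.sort_values("repetition")[metric].to_numpy(dtype=float)
                if len(a) != len(b) or len(a) < 2:
                    continue
                try:
                    t, p = paired_t_test(a, b)
                except DegenerateTTestError:
                    t, p = float("nan"), float("nan")
                out.append({
                    "horizon_min": horizon, "metric": metric,
                    "reference": reference, "baseline": other, "t": t, "p": p,
                })
    return pd.DataFrame(out)
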