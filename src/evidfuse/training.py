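"""Training objective, protocol and the accuracy + reliability metrics.

The overall objective is

    L = L_main + α·L_aux^struct + β·L_aux^text        (α = 2, β = 1)

where L_main is the class-weighted cross-entropy on the pignistic
probabilities of the fused mass and the auxiliary terms are weighted
softmax cross-entropies on each bundle's encoder head (structured
bundles weighted by α, text bundles by β).  Class weights default to
balanced inverse frequency, w_c = N / (M·N_c).

The protocol mirrors the usual imbalanced-cohort setup: a stratified
60/20/20 train/validation/test split or 5-fold stratified
cross-validation, Adam at 1e-3, mini-batches of 32, early stopping on
the validation main (fused-prediction) loss, and a ten-metric panel:
precision, recall, specificity, NPV, BACC, F1, AUROC, AUPRC, Brier
score and NLL.  Metrics with a zero denominator are reported as
missing (NaN), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .fusion import (BundleSpec, EvidentialModel, FusionSpec,
                     MultimodalDataset, build_model, bundle_input,
                     split_by_partition)

__all__ = [
    "TrainConfig",
    "class_weights",
    "main_loss",
    "aux_loss",
    "overall_loss",
    "stratified_splits",
    "train",
    "compute_metrics",
    "EvalReport",
    "run_experiment",
]

_LOG_EPS = 1e-12

METRIC_NAMES = (
    "precision", "recall", "specificity", "npv", "bacc",
    "f1", "auroc", "auprc", "brier", "nll",
)


@dataclass
class TrainConfig:
    alpha: float = 2.0
    beta: float = 1.0
    batch_size: int = 32
    max_epochs: int = 150
    patience: int = 10
    learning_rate: float = 1e-3
    seed: int = 0
    train_frac: float = 0.6
    val_frac: float = 0.2
    test_frac: float = 0.2
    n_folds: int = 5
    threshold: float = 0.5
    use_class_weights: bool = True

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def class_weights(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """Balanced inverse-frequency weights w_c = N / (M·N_c)."""
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=n_classes)
    if (counts == 0).any():
        raise ValueError("every class must be present to compute class weights")
    return len(labels) / (n_classes * counts.astype(np.float64))


def _one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    y = np.zeros((len(labels), n_classes))
    y[np.arange(len(labels)), np.asarray(labels, int)] = 1.0
    return y


def main_loss(p: Tensor, y_onehot: np.ndarray, w: np.ndarray) -> Tensor:
    """Weighted cross-entropy on pignistic probabilities, ε-clamped logs."""
    if p.shape != y_onehot.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y_onehot.shape}")
    logp = ad.maximum(p, _LOG_EPS).log()
    return -(logp * Tensor(y_onehot * w)).sum() * (1.0 / len(y_onehot))


def aux_loss(logits: Tensor, y_onehot: np.ndarray, w: np.ndarray) -> Tensor:
    """Weighted softmax cross-entropy on auxiliary logits."""
    if logits.shape != y_onehot.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs y {y_onehot.shape}")
    logp = ad.log_softmax(logits, axis=-1)
    return -(logp * Tensor(y_onehot * w)).sum() * (1.0 / len(y_onehot))


def overall_loss(main, aux_s, aux_n, cfg: TrainConfig):
    """L = L_main + α·L_aux^s + β·L_aux^n."""
    return main + cfg.alpha * aux_s + cfg.beta * aux_n


@dataclass
class Splits:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def stratified_splits(labels: np.ndarray, cfg: TrainConfig, seed: int):
    """Stratified 60/20/20 holdout plus stratified CV folds.

    Each CV fold's test set is one of ``n_folds`` stratified partitions;
    the remainder is split into train/validation so the validation share
    of the whole dataset matches ``cfg.val_frac``.
    """
    labels = np.asarray(labels)
    idx = np.arange(len(labels))
    tr, rest = train_test_split(
        idx, train_size=cfg.train_frac, stratify=labels, random_state=seed
    )
    val_share = cfg.val_frac / (cfg.val_frac + cfg.test_frac)
    va, te = train_test_split(
        rest, train_size=val_share, stratify=labels[rest], random_state=seed
    )
    holdout = Splits(np.sort(tr), np.sort(va), np.sort(te))

    folds: list[Splits] = []
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=seed)
    for rest_idx, test_idx in skf.split(idx, labels):
        val_frac_of_rest = cfg.val_frac / (1.0 - 1.0 / cfg.n_folds)
        ftr, fva = train_test_split(
            rest_idx, test_size=val_frac_of_rest,
            stratify=labels[rest_idx], random_state=seed,
        )
        folds.append(Splits(np.sort(ftr), np.sort(fva), np.sort(test_idx)))
    return holdout, folds


@dataclass
class TrainResult:
    history: list
    best_epoch: int
    best_val_loss: float


def _batch_inputs(inputs: dict, idx: np.ndarray) -> dict:
    return {name: x[idx] for name, x in inputs.items()}


def _model_losses(model, batch_inputs, y_onehot, w, cfg: TrainConfig):
    out = model(batch_inputs)
    if "p" in out and "logits" not in out:
        main = main_loss(out["p"], y_onehot, w)
    else:
        main = aux_loss(out["logits"], y_onehot, w)
    total = main
    for bundle_name, logits in out["aux_logits"].items():
        kind = _bundle_kind(model, bundle_name)
        coef = cfg.alpha if kind == "structured" else cfg.beta
        if coef > 0:
            total = total + coef * aux_loss(logits, y_onehot, w)
    return total, out


def _validation_loss(model, val_inputs, y_onehot, w) -> float:
    """Model-selection criterion: the main (fused-prediction) loss only.

    The auxiliary terms supervise the encoders but keep improving even
    when the fused prediction degrades — monitoring the augmented
    objective would let a large auxiliary term mask a deteriorating
    fused output (e.g. one modality memorizing noise).  Selecting on
    the deployment loss avoids that.
    """
    out = model(val_inputs)
    if "p" in out and "logits" not in out:
        loss = main_loss(out["p"], y_onehot, w)
    else:
        loss = aux_loss(out["logits"], y_onehot, w)
    return float(loss.data)


def _bundle_kind(model, name: str) -> str:
    if isinstance(model, EvidentialModel):
        for b in model.bundles:
            if b.name == name:
                return b.kind
    else:
        return model.kinds[name]
    raise KeyError(name)


def train(
    model,
    inputs: dict,
    labels: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    cfg: TrainConfig,
    weights: np.ndarray | None = None,
) -> TrainResult:
    """Mini-batch Adam minimizing the augmented objective, with early
    stopping on the validation main loss; restores the best-validation
    parameters before returning."""
    labels = np.asarray(labels)
    n_classes = 2
    if weights is None:
        weights = (class_weights(labels[train_idx], n_classes)
                   if cfg.use_class_weights else np.ones(n_classes))
    y = _one_hot(labels, n_classes)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    best_state = model.state()
    best_val = np.inf
    best_epoch = -1
    history: list[dict] = []
    stall = 0
    val_inputs = _batch_inputs(inputs, val_idx)
    for epoch in range(cfg.max_epochs):
        model.train()
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            loss, _ = _model_losses(
                model, _batch_inputs(inputs, batch), y[batch], weights, cfg
            )
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        model.eval()
        val_loss = _validation_loss(model, val_inputs, y[val_idx], weights)
        history.append({
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_loss": val_loss,
        })
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            best_state = model.state()
            stall = 0
        else:
            stall += 1
            if stall > cfg.patience:
                break
    model.load_state(best_state)
    model.eval()
    return TrainResult(history=history, best_epoch=best_epoch, best_val_loss=best_val)


# -- metrics -------------------------------------------------------------

def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(p_positive: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> dict:
    """The ten-metric accuracy + reliability panel.

    Zero-denominator cells come back as NaN (missing), not zero.
    """
    p = np.asarray(p_positive, dtype=np.float64)
    o = np.asarray(labels, dtype=np.float64)
    if p.shape != o.shape:
        raise ValueError("p_positive and labels must align")
    yhat = (p >= threshold).astype(int)
    tp = float(((yhat == 1) & (o == 1)).sum())
    fp = float(((yhat == 1) & (o == 0)).sum())
    fn = float(((yhat == 0) & (o == 1)).sum())
    tn = float(((yhat == 0) & (o == 0)).sum())
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    npv = _safe_div(tn, tn + fn)
    bacc = (recall + specificity) / 2.0
    f1 = (2 * precision * recall / (precision + recall)
          if np.isfinite(precision) and np.isfinite(recall) and precision + recall > 0
          else float("nan"))
    if len(np.unique(o)) == 2:
        auroc = float(roc_auc_score(o, p))
        auprc = float(average_precision_score(o, p))
    else:
        auroc = auprc = float("nan")
    brier = float(np.mean((p - o) ** 2))
    pc = np.clip(p, _LOG_EPS, 1.0 - _LOG_EPS)
    nll = float(-np.mean(o * np.log(pc) + (1 - o) * np.log(1 - pc)))
    return {
        "precision": precision, "recall": recall, "specificity": specificity,
        "npv": npv, "bacc": bacc, "f1": f1, "auroc": auroc, "auprc": auprc,
        "brier": brier, "nll": nll,
    }


@dataclass
class EvalReport:
    """Per-fold metric rows with mean ± standard error (SD/√folds),
    NaN cells excluded from the aggregates."""

    rows: list = field(default_factory=list)

    def add(self, row: dict) -> None:
        self.rows.append(dict(row))

    def summary(self) -> dict:
        out = {}
        for name in METRIC_NAMES:
            vals = np.array([r[name] for r in self.rows if name in r], dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                out[name] = {"mean": float("nan"), "se": float("nan"), "n_folds": 0}
            else:
                se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
                out[name] = {"mean": float(vals.mean()), "se": se, "n_folds": len(vals)}
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        summ = self.summary()
        mean_row = {k: v["mean"] for k, v in summ.items()}
        se_row = {k: v["se"] for k, v in summ.items()}
        df = pd.concat(
            [df, pd.DataFrame([mean_row, se_row], index=["mean", "se"])],
        )
        return df


@dataclass
class ExperimentResult:
    report: EvalReport
    histories: list
    predictions: list          # per evaluated split: DataFrame
    splits: list               # per evaluated split: Splits


def run_experiment(
    raw,
    enc_cfg,
    text_cfg,
    em_cfg,
    fusion: FusionSpec,
    cfg: TrainConfig,
    mode: str = "holdout",
    seed: int | None = None,
) -> ExperimentResult:
    """End-to-end protocol on a raw cohort.

    Per split: fit the structured preprocessor on the training rows
    only, build the model (with prototype initialization from training
    features), train with early stopping, and evaluate the ten-metric
    panel on the test rows.
    """
    from .synthetic import preprocess_structured, preprocess_notes, NOTE_TYPES
    from .encoders import embed_corpus

    seed = cfg.seed if seed is None else seed
    labels = raw.labels
    groups = (["combined"] if fusion.partition != "data_sources"
              else [t for t in NOTE_TYPES])
    tokens = preprocess_notes(raw.notes, raw.ids, groups=groups,
                              max_tokens=text_cfg.max_tokens)
    note_emb = {g: embed_corpus(seqs, text_cfg.embedding_dim)
                for g, seqs in tokens.items()}

    holdout, folds = stratified_splits(labels, cfg, seed)
    eval_splits = [holdout] if mode == "holdout" else folds

    report = EvalReport()
    histories, predictions = [], []
    for k, sp in enumerate(eval_splits):
        X, names, col_tags, _ = preprocess_structured(raw.structured, raw.tags, sp.train)
        dataset = MultimodalDataset(X, col_tags, note_emb, labels, list(raw.ids))
        specs = split_by_partition(dataset, fusion.partition)
        if fusion.include is not None:
            specs = [s for s in specs if s.name in fusion.include]
            if not specs:
                raise ValueError("include filter removed every bundle")
        inputs = {s.name: bundle_input(dataset, s) for s in specs}
        model = build_model(dataset, specs, enc_cfg, text_cfg, em_cfg,
                            fusion.strategy, sp.train, seed=seed + 7919 * k)
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": seed + 7919 * k})
        result = train(model, inputs, labels, sp.train, sp.val, fold_cfg)
        pred = model.predict(_batch_inputs(inputs, sp.test))
        row = compute_metrics(pred["p_positive"], labels[sp.test],
                              fusion.decision_threshold)
        report.add(row)
        histories.append(result.history)
        df = pd.DataFrame({
            "id": [raw.ids[i] for i in sp.test],
            "p_positive": pred["p_positive"],
            "label": labels[sp.test],
            "predicted_label": (pred["p_positive"] >= fusion.decision_threshold).astype(int),
        })
        if "m_singletons" in pred:
            df.insert(2, "m_pos", pred["m_singletons"][:, 1])
            df.insert(3, "m_neg", pred["m_singletons"][:, 0])
            df.insert(4, "m_omega", pred["m_ignorance"])
        predictions.append(df)
    return ExperimentResult(report, histories, predictions, eval_splits)
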