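"""The joint-fusion classifier and its cross-validated evaluation.

A feature-reduction subnetwork (FR-NN) per modality maps each input block to
a fixed-length embedding; the concatenated embeddings feed a classification
head (C-NN) with a single logistic output.  Training uses SGD with momentum,
binary cross-entropy, batch normalization, dropout and an L1 penalty on each
FR-NN's first layer.  Evaluation follows a nested stratified k-fold scheme:
the inner loop selects the C-NN depth/width by mean validation AUC, the
selected model is refit on the full outer-training split and scored once on
the held-out outer fold.  Median/IQR feature scaling is fit inside each
training split only; an audit log records which subject ids every fitted
statistic consumed so leakage is checkable after the fact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import nn
from .evaluation import ROCCurve, accuracy, auc_roc
from .features import FUNCTIONAL, STRUCTURAL, FeatureTable

POSITIVE_LABEL = "ASD"

#: Default C-NN search grid: depth 1-2, width 32/64/128 (second layer half).
DEFAULT_SEARCH_SPACE: tuple[tuple[int, ...], ...] = (
    (32,), (64,), (128,), (32, 32), (64, 32), (128, 64),
)


@dataclass
class ModelSpec:
    """Architecture: per-modality FR-NN widths (last = embedding size) and
    C-NN widths.  Embedding defaults are proportionate to the input widths
    of the two modalities (221 structural vs several thousand functional)."""

    frnn_widths: dict[str, list[int]] = field(
        default_factory=lambda: {STRUCTURAL: [64, 32], FUNCTIONAL: [256, 128]}
    )
    cnn_widths: tuple[int, ...] = (64,)
    dropout: tuple[float, float] = (0.5, 0.2)


@dataclass
class TrainConfig:
    lr: float = 0.001
    momentum: float = 0.9
    epochs: int = 150
    batch_size: int = 64
    l1: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.lr <= 0:
            raise ValueError("epochs >= 1 and lr > 0 required")


# ---------------------------------------------------------------------------
# median/IQR scaling


@dataclass
class Scaler:
    center: np.ndarray
    scale: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.center) / self.scale


def scale_features(train_block: np.ndarray, *other_blocks: np.ndarray):
    """Median/IQR scaling fit on the training block only.

    x' = (x - median)/IQR per feature (linear-interpolation quantiles);
    zero-IQR features are centred but left unscaled.  Returns the scaled
    train block, scaled copies of the held-out blocks, and the scaler.
    """
    if train_block.size == 0:
        raise ValueError("empty training block")
    center = np.median(train_block, axis=0)
    q75, q25 = np.percentile(train_block, [75, 25], axis=0)
    iqr = q75 - q25
    scale = np.where(iqr == 0, 1.0, iqr)
    scaler = Scaler(center=center, scale=scale)
    out = [scaler.transform(train_block)] + [scaler.transform(b) for b in other_blocks]
    return (*out, scaler)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedJointModel:
    net: nn.JointFusionNet
    modalities: list[str]
    spec: ModelSpec
    config: TrainConfig
    loss_history: list[float] = field(default_factory=list)

    def predict_proba(self, blocks: dict[str, np.ndarray]) -> np.ndarray:
        return self.net.predict_proba([blocks[m] for m in self.modalities])


def train_model(
    spec: ModelSpec,
    config: TrainConfig,
    blocks: dict[str, np.ndarray],
    y: np.ndarray,
    freeze_frnn: bool = False,
) -> TrainedJointModel:
    """Train the fusion net (or a single-modality variant) on scaled blocks."""
    modalities = [m for m in (STRUCTURAL, FUNCTIONAL) if m in blocks] or sorted(blocks)
    mats = [np.asarray(blocks[m], dtype=float) for m in modalities]
    net = nn.JointFusionNet(
        input_dims=[b.shape[1] for b in mats],
        frnn_widths=[list(spec.frnn_widths[m]) for m in modalities],
        cnn_widths=list(spec.cnn_widths),
        dropout=spec.dropout,
        seed=config.seed,
    )
    history = nn.train(
        net, mats, np.asarray(y, dtype=float),
        epochs=config.epochs, batch_size=config.batch_size, lr=config.lr,
        momentum=config.momentum, l1=config.l1, seed=config.seed,
        freeze_frnn=freeze_frnn,
    )
    return TrainedJointModel(net=net, modalities=modalities, spec=spec,
                             config=config, loss_history=history)


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class FoldResult:
    test_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray
    roc: ROCCurve
    auc: float
    accuracy: float
    selected_cnn: tuple[int, ...]


@dataclass
class CVResults:
    folds: list[FoldResult]
    modality_mode: str
    auc_mean: float
    auc_sd: float
    acc_mean: float
    acc_sd: float
    outer_k: int
    seed: int
    audit: list[dict] = field(default_factory=list)

    def fold_aucs(self) -> np.ndarray:
        return np.array([f.auc for f in self.folds])

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "modality_mode": self.modality_mode,
            "auc_mean": self.auc_mean, "auc_sd": self.auc_sd,
            "acc_mean": self.acc_mean, "acc_sd": self.acc_sd,
            "outer_k": self.outer_k, "seed": self.seed,
            "folds": [
                {"auc": f.auc, "accuracy": f.accuracy, "n_test": len(f.test_ids),
                 "selected_cnn": list(f.selected_cnn)}
                for f in self.folds
            ],
        }
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def scores_tsv(self, path: str | Path) -> None:
        rows = []
        for k, f in enumerate(self.folds):
            for sid, s, y in zip(f.test_ids, f.scores, f.labels):
                rows.append({"fold": k, "id": sid, "score": s, "label": int(y)})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def binarize_labels(diagnosis: pd.Series) -> np.ndarray:
    return (diagnosis == POSITIVE_LABEL).to_numpy(dtype=float)


def outer_fold_assignments(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Stratified outer-fold test indices (diagnosis proportions preserved)."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def _fit_and_score(spec, config, blocks, y, train_idx, test_idx, seed, audit, stage, ids):
    scaled_train, scaled_test = {}, {}
    for m, X in blocks.items():
        tr, te, _ = scale_features(X[train_idx], X[test_idx])
        scaled_train[m], scaled_test[m] = tr, te
    audit.append({"stage": f"{stage}:scaler", "ids_used": [ids[i] for i in train_idx]})
    cfg = TrainConfig(**{**asdict(config), "seed": seed})
    model = train_model(spec, cfg, scaled_train, y[train_idx])
    audit.append({"stage": f"{stage}:fit", "ids_used": [ids[i] for i in train_idx]})
    return model.predict_proba(scaled_test)


def nested_cv(
    table: FeatureTable,
    diagnosis: pd.Series,
    modality_mode: str = "joint",
    outer_k: int = 10,
    inner_k: int = 5,
    search_space: tuple[tuple[int, ...], ...] = DEFAULT_SEARCH_SPACE,
    config: TrainConfig | None = None,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> CVResults:
    """Nested stratified cross-validation of one modality mode.

    ``modality_mode`` is 'structural', 'functional' or 'joint'.  With a
    single-candidate ``search_space`` the inner loop is skipped (nothing to
    select), which is also the cheap non-nested evaluation path.
    """
    if outer_k < 2 or not search_space:
        raise ValueError("outer_k >= 2 and a non-empty search space required")
    config = config or TrainConfig()
    spec = spec or ModelSpec()
    ids = table.subjects
    y = binarize_labels(diagnosis.reindex(ids))
    if min((y == 1).sum(), (y == 0).sum()) < 2 * outer_k:
        raise ValueError("too few subjects per class for stratified folds")

    if modality_mode == "joint":
        modalities = [STRUCTURAL, FUNCTIONAL]
    elif modality_mode in (STRUCTURAL, FUNCTIONAL):
        modalities = [modality_mode]
    else:
        raise ValueError(f"unknown modality mode {modality_mode!r}")
    blocks = {m: table.select(m).df.to_numpy(dtype=float) for m in modalities}

    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(outer_k * (len(search_space) * inner_k + 1))]
    seed_iter = iter(fold_seeds)

    audit: list[dict] = []
    folds: list[FoldResult] = []
    for fold_no, test_idx in enumerate(outer_fold_assignments(y, outer_k, seed)):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        if len(search_space) > 1:
            inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed + fold_no + 1)
            mean_aucs = []
            for cand in search_space:
                cspec = ModelSpec(frnn_widths=spec.frnn_widths, cnn_widths=tuple(cand),
                                  dropout=spec.dropout)
                aucs = []
                for itr, iva in inner.split(np.zeros(len(train_idx)), y[train_idx]):
                    p = _fit_and_score(
                        cspec, config, blocks, y, train_idx[itr], train_idx[iva],
                        next(seed_iter), audit, f"outer{fold_no}:inner", ids,
                    )
                    aucs.append(auc_roc(p, y[train_idx[iva]]).auc)
                mean_aucs.append(float(np.mean(aucs)))
            best = search_space[int(np.argmax(mean_aucs))]
        else:
            best = search_space[0]
        bspec = ModelSpec(frnn_widths=spec.frnn_widths, cnn_widths=tuple(best),
                          dropout=spec.dropout)
        p = _fit_and_score(bspec, config, blocks, y, train_idx, test_idx,
                           next(seed_iter), audit, f"outer{fold_no}", ids)
        roc = auc_roc(p, y[test_idx])
        folds.append(FoldResult(
            test_ids=[ids[i] for i in test_idx], scores=p, labels=y[test_idx],
            roc=roc, auc=roc.auc, accuracy=accuracy(p, y[test_idx]),
            selected_cnn=tuple(best),
        ))

    aucs = np.array([f.auc for f in folds])
    accs = np.array([f.accuracy for f in folds])
    return CVResults(
        folds=folds, modality_mode=modality_mode,
        auc_mean=float(aucs.mean()), auc_sd=float(aucs.std(ddof=1)),
        acc_mean=float(accs.mean()), acc_sd=float(accs.std(ddof=1)),
        outer_k=outer_k, seed=seed, audit=audit,
    )


def audit_leakage(results: CVResults) -> list[str]:
    """Return audit violations: outer-test ids consumed by any fitted statistic
    of their own outer fold.  Empty list = no leakage recorded."""
    violations = []
    for fold_no, f in enumerate(results.folds):
        test = set(f.test_ids)
        for ev in results.audit:
            if ev["stage"].startswith(f"outer{fold_no}:") and test & set(ev["ids_used"]):
                violations.append(ev["stage"])
    return violations
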