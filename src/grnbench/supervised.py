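"""Supervised and semi-supervised gene-pair classification.

Each unordered gene pair becomes a training sample whose feature vector is
the symmetrized outer product of the two expression profiles (length n^2,
invariant under swapping the pair). A linear maximum-margin classifier is
trained on labeled pairs; its signed decision value is the predicted
interaction confidence. Semi-supervised label schemes keep a fraction of the
true labels and relabel everything else as negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .evaluate import pair_auc
from .netio import ExpressionMatrix, UndirectedTruth, WeightMatrix

__all__ = [
    "PairSample",
    "PairDataset",
    "TrainConfig",
    "outer_product_features",
    "build_pair_dataset",
    "apply_label_scheme",
    "train_margin_classifier",
    "decision_weights",
    "crossval_score",
]

LABEL_MODES = ("pos_neg", "pos_only", "full")


@dataclass
class PairSample:
    pair: frozenset[str]
    features: np.ndarray
    label: int  # +1 / -1 (0 = unlabeled, only transiently)

    def __post_init__(self) -> None:
        if len(self.pair) != 2:
            raise ValueError("pair must contain two distinct genes")
        self.features = np.asarray(self.features, dtype=float)
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        if self.label not in (+1, -1, 0):
            raise ValueError("label must be +1, -1 or 0")


@dataclass
class PairDataset:
    samples: list[PairSample]
    gene_ids: list[str]
    n_samples_expr: int

    def __post_init__(self) -> None:
        seen = set()
        for s in self.samples:
            if s.pair in seen:
                raise ValueError(f"duplicate pair {set(s.pair)}")
            seen.add(s.pair)

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])

    def feature_matrix(self) -> np.ndarray:
        return np.vstack([s.features for s in self.samples])


@dataclass
class TrainConfig:
    """Cross-validation / label-scheme configuration.

    label_mode: 'full' keeps all true labels; 'pos_neg' keeps a seeded
    label_fraction of positives and of negatives and relabels the rest as
    negative; 'pos_only' keeps only a fraction of positives.
    """

    C_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    folds: int = 5
    label_fraction: float = 1.0
    label_mode: str = "full"
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if len(self.C_grid) == 0 or any(c <= 0 for c in self.C_grid):
            raise ValueError("C_grid must be nonempty positive reals")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not (0 < self.label_fraction <= 1):
            raise ValueError("label_fraction must be in (0, 1]")
        if self.label_mode not in LABEL_MODES:
            raise ValueError(f"label_mode must be one of {LABEL_MODES}")


def outer_product_features(X: ExpressionMatrix, pair) -> np.ndarray:
    """Symmetrized outer product (X_i X_j^T + X_j X_i^T) / 2, flattened.

    Symmetrization makes the feature vector invariant under swapping the
    pair's gene order, so predictions are undirected by construction.
    """
    a, b = tuple(pair)
    xi = X.values[X.gene_index(a)]
    xj = X.values[X.gene_index(b)]
    op = (np.outer(xi, xj) + np.outer(xj, xi)) / 2.0
    return op.ravel()


def all_pairs(gene_ids: list[str]) -> list[frozenset[str]]:
    return [frozenset((gene_ids[i], gene_ids[j]))
            for i in range(len(gene_ids)) for j in range(i + 1, len(gene_ids))]


def build_pair_dataset(X: ExpressionMatrix, truth: UndirectedTruth) -> PairDataset:
    """One sample per unordered pair, labeled +1 iff the pair is in truth."""
    unknown = set(truth.gene_ids) - set(X.gene_ids)
    if unknown:
        raise ValueError(f"truth genes absent from expression matrix: {unknown}")
    samples = []
    for pair in all_pairs(X.gene_ids):
        label = +1 if pair in truth.pairs else -1
        samples.append(PairSample(pair, outer_product_features(X, pair), label))
    return PairDataset(samples, list(X.gene_ids), X.n_samples)


def apply_label_scheme(ds: PairDataset, cfg: TrainConfig) -> PairDataset:
    """Partial-label relabeling: keep a seeded fraction of the true labels,
    relabel everything else as negative (-1)."""
    if cfg.label_mode == "full" or cfg.label_fraction == 1.0:
        return PairDataset([PairSample(s.pair, s.features, s.label)
                            for s in ds.samples], list(ds.gene_ids),
                           ds.n_samples_expr)
    rng = np.random.default_rng(cfg.seed)
    pos_idx = [i for i, s in enumerate(ds.samples) if s.label == +1]
    neg_idx = [i for i, s in enumerate(ds.samples) if s.label == -1]
    n_pos_keep = math.ceil(cfg.label_fraction * len(pos_idx))
    keep_pos = set(rng.choice(pos_idx, size=n_pos_keep, replace=False)) if pos_idx else set()
    if cfg.label_mode == "pos_neg" and neg_idx:
        # negatives keep their label on a fraction too; the rest are
        # "unlabeled" and relabeled -1, which is a no-op on the label value
        n_neg_keep = math.ceil(cfg.label_fraction * len(neg_idx))
        rng.choice(neg_idx, size=n_neg_keep, replace=False)
    samples = []
    for i, s in enumerate(ds.samples):
        label = +1 if i in keep_pos else -1
        samples.append(PairSample(s.pair, s.features, label))
    return PairDataset(samples, list(ds.gene_ids), ds.n_samples_expr)


@dataclass
class _Standardizer:
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, F: np.ndarray) -> "_Standardizer":
        sd = F.std(axis=0)
        return cls(F.mean(axis=0), np.where(sd > 0, sd, 1.0))

    def transform(self, F: np.ndarray) -> np.ndarray:
        return (F - self.mean) / self.sd


@dataclass
class MarginModel:
    svc: SVC
    scaler: _Standardizer | None

    def decision_values(self, F: np.ndarray) -> np.ndarray:
        if self.scaler is not None:
            F = self.scaler.transform(F)
        return self.svc.decision_function(F)


def train_margin_classifier(ds: PairDataset, C: float,
                            standardize: bool = True) -> MarginModel:
    """Linear maximum-margin classifier with complexity parameter C.

    Uniform sample weights; features optionally standardized (fit on the
    training pairs only).
    """
    y = ds.labels()
    if len(set(y.tolist())) < 2:
        raise ValueError("training data contain a single class")
    F = ds.feature_matrix()
    scaler = _Standardizer.fit(F) if standardize else None
    if scaler is not None:
        F = scaler.transform(F)
    svc = SVC(kernel="linear", C=C)
    svc.fit(F, y)
    return MarginModel(svc, scaler)


def decision_weights(model: MarginModel, X: ExpressionMatrix,
                     pairs: list[frozenset[str]]) -> WeightMatrix:
    """Signed decision values as a WeightMatrix over the given pairs
    (unlisted pairs and the diagonal stay at 0)."""
    index = {g: i for i, g in enumerate(X.gene_ids)}
    n = len(X.gene_ids)
    w = np.zeros((n, n))
    if pairs:
        F = np.vstack([outer_product_features(X, p) for p in pairs])
        vals = model.decision_values(F)
        for p, v in zip(pairs, vals):
            a, b = tuple(p)
            i, j = index[a], index[b]
            w[i, j] = w[j, i] = v
    return WeightMatrix(list(X.gene_ids), w)


def _grid_search_C(F: np.ndarray, y_train: np.ndarray, y_true: np.ndarray,
                   cfg: TrainConfig, rng: np.random.Generator,
                   n_splits: int = 3) -> float:
    """Pick C by mean AUC over seeded stratified 80/20 splits of the
    training pairs.

    Stratification is on the (possibly relabeled) training labels; model
    selection never sees test-fold pairs. Ties resolve to the smaller C.
    """
    scores = np.zeros(len(cfg.C_grid))
    counts = 0
    for _ in range(n_splits):
        pos = np.flatnonzero(y_train == +1)
        neg = np.flatnonzero(y_train == -1)
        val = []
        for idx in (pos, neg):
            idx = rng.permutation(idx)
            n_val = max(1, int(round(0.2 * len(idx)))) if len(idx) > 1 else 0
            val.extend(idx[:n_val].tolist())
        val = np.array(sorted(val), dtype=int)
        fit = np.setdiff1d(np.arange(len(y_train)), val)
        if (len(set(y_train[fit].tolist())) < 2 or len(val) == 0
                or len(set(y_true[val].tolist())) < 2):
            continue
        scaler = _Standardizer.fit(F[fit]) if cfg.standardize else None
        Ffit = scaler.transform(F[fit]) if scaler else F[fit]
        Fval = scaler.transform(F[val]) if scaler else F[val]
        for ci, C in enumerate(cfg.C_grid):
            svc = SVC(kernel="linear", C=C)
            svc.fit(Ffit, y_train[fit])
            scores[ci] += pair_auc(svc.decision_function(Fval), y_true[val])
        counts += 1
    if counts == 0:
        return cfg.C_grid[len(cfg.C_grid) // 2]  # degenerate split: midpoint C
    return cfg.C_grid[int(np.argmax(scores))]


def _make_folds(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.asarray(f) for f in np.array_split(perm, folds)]


def crossval_score(X: ExpressionMatrix, truth: UndirectedTruth,
                   cfg: TrainConfig) -> tuple[WeightMatrix, float, float]:
    """Whole-network 5-fold CV scoring.

    Pairs are partitioned into seeded folds; per fold the label scheme is
    applied to the training portion only, C is grid-searched on an inner
    split of training pairs, and decision values are recorded for the test
    fold. Returns (out-of-fold WeightMatrix, mean per-fold AUC, sd).
    """
    ds = build_pair_dataset(X, truth)
    n_pairs = len(ds.samples)
    if cfg.folds > n_pairs:
        raise ValueError("more folds than pairs")
    F_all = ds.feature_matrix()
    y_true = ds.labels()
    rng = np.random.default_rng(cfg.seed)
    for attempt in range(2):
        fold_idx = _make_folds(n_pairs, cfg.folds, rng)
        ok = all(len(set(y_true[np.setdiff1d(np.arange(n_pairs), f)].tolist())) == 2
                 for f in fold_idx)
        if ok:
            break
        if attempt == 1:
            raise ValueError("a fold's training data contain a single class "
                             "even after a re-draw")
    index = {g: i for i, g in enumerate(X.gene_ids)}
    n = len(X.gene_ids)
    oof = np.zeros((n, n))
    fold_aucs: list[float] = []
    for f, test in enumerate(fold_idx):
        train = np.setdiff1d(np.arange(n_pairs), test)
        sub = PairDataset([ds.samples[i] for i in train], list(ds.gene_ids),
                          ds.n_samples_expr)
        sub_cfg = TrainConfig(cfg.C_grid, cfg.folds, cfg.label_fraction,
                              cfg.label_mode, cfg.seed * 1000 + f,
                              cfg.standardize)
        sub = apply_label_scheme(sub, sub_cfg)
        y_train = sub.labels()
        if len(set(y_train.tolist())) < 2:
            raise ValueError("training fold has a single class after relabeling")
        inner_rng = np.random.default_rng(cfg.seed * 7919 + f)
        C = _grid_search_C(F_all[train], y_train, y_true[train], sub_cfg,
                           inner_rng)
        model = train_margin_classifier(sub, C, cfg.standardize)
        vals = model.decision_values(F_all[test])
        for i, v in zip(test, vals):
            a, b = tuple(ds.samples[i].pair)
            ia, ib = index[a], index[b]
            oof[ia, ib] = oof[ib, ia] = v
        if len(set(y_true[test].tolist())) == 2:
            fold_aucs.append(pair_auc(vals, y_true[test]))
    # single-class test folds (tiny pair sets) yield no per-fold AUC; the
    # assembled out-of-fold weights remain usable for whole-matrix AUC
    mean_auc = float(np.mean(fold_aucs)) if fold_aucs else float("nan")
    sd_auc = float(np.std(fold_aucs)) if fold_aucs else float("nan")
    return WeightMatrix(list(X.gene_ids), oof), mean_auc, sd_auc
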