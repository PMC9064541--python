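"""MultDS ensemble classification for imbalanced diagnostic cohorts.

Multiple Down-Sizing (MultDS) counters class imbalance by training many
random-forest models, each on ALL minority-class training samples plus an
equal-size draw (without replacement) from the majority class; ensemble
probabilities are the arithmetic mean over models. Hyperparameters
(mtry, the number of features tried per split) are tuned per model by
stratified cross-validated AUC over an integer grid; forest size and
minimum node size follow the published grid (ntree=1000, nodesize=25,
mtry spanning 1-100 clipped to the feature count). Evaluation reports the
held-out AUC with a DeLong-style asymptotic 95% CI and the sensitivity /
specificity at the Youden-optimal threshold chosen on TRAINING
probabilities only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .differential import empirical_auc

__all__ = [
    "MultDSConfig",
    "EnsembleModel",
    "DiagnosticPerformance",
    "split_train_test",
    "multds_sample",
    "fit_ensemble",
    "predict_proba",
    "evaluate",
    "delong_ci",
]


@dataclass
class MultDSConfig:
    """MultDS ensemble settings (defaults follow the published grid)."""

    n_models: int = 100
    train_fraction: float = 0.70
    ntree: int = 1000
    nodesize: int = 25
    mtry_grid: tuple[int, ...] = ()  # empty -> 1..min(100, n_features)
    cv_folds: int = 10
    seed: int = 0
    positive_label: str | int = 1

    def __post_init__(self) -> None:
        self.mtry_grid = tuple(int(m) for m in self.mtry_grid)
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.ntree < 1 or self.nodesize < 1 or self.cv_folds < 2:
            raise ValueError("invalid forest/CV settings")

    def grid_for(self, n_features: int) -> tuple[int, ...]:
        if self.mtry_grid:
            return tuple(m for m in self.mtry_grid if 1 <= m <= n_features) or (
                min(self.mtry_grid[0], n_features),
            )
        return tuple(range(1, min(100, n_features) + 1))


@dataclass
class DiagnosticPerformance:
    """Held-out performance of a fitted classifier."""

    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    threshold: float
    n_test_positive: int
    n_test_negative: int

    def summary(self) -> str:
        return (
            f"AUC {self.auc:.3f} (CI 95% [{self.ci_low:.3f}-{self.ci_high:.3f}]), "
            f"Se {self.sensitivity * 100:.1f}%, Sp {self.specificity * 100:.1f}% "
            f"(threshold {self.threshold:.3f}; "
            f"test n={self.n_test_positive}+/{self.n_test_negative}-)"
        )


@dataclass
class EnsembleModel:
    """The fitted MultDS ensemble with its split and sampling record."""

    forests: list = field(default_factory=list)
    balanced_indices: list = field(default_factory=list)  # per model, train ids
    chosen_mtry: list = field(default_factory=list)
    feature_ids: tuple[str, ...] = ()
    threshold: float = 0.5
    train_ids: tuple = ()
    test_ids: tuple = ()
    config: MultDSConfig | None = None


def split_train_test(
    labels: pd.Series, train_fraction: float = 0.70, seed: int = 0
) -> tuple[list, list]:
    """Stratified random train/test split on sample ids.

    Per-class training counts are round(fraction * n_class), so class
    proportions are preserved within rounding; the split is deterministic
    given the seed, disjoint and exhaustive.
    """
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)
    classes = sorted(pd.unique(labels), key=str)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    train, test = [], []
    for cls in classes:
        ids = list(labels.index[labels == cls])
        if len(ids) < 4:
            raise ValueError(f"class {cls!r} has fewer than 4 samples")
        perm = rng.permutation(len(ids))
        n_train = int(round(train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return train, test


def multds_sample(
    labels: pd.Series, rng: np.random.Generator, minority_label=None
) -> list:
    """One balanced down-sized index set: the full minority class plus an
    equal-count draw (without replacement) from the majority class.

    ``minority_label`` names the nominal minority class (usually the case
    group); if that class actually outnumbers the other, the roles are
    swapped with a warning. Without it the smaller class is the minority.
    """
    labels = pd.Series(labels)
    classes = sorted(pd.unique(labels), key=str)
    if len(classes) != 2:
        raise ValueError("multds_sample requires exactly two classes")
    a_ids = list(labels.index[labels == classes[0]])
    b_ids = list(labels.index[labels == classes[1]])
    minority, majority = (a_ids, b_ids) if len(a_ids) <= len(b_ids) else (b_ids, a_ids)
    if minority_label is not None and len(labels.index[labels == minority_label]) > len(
        minority
    ):
        warnings.warn("nominal minority class outnumbers majority; roles swapped")
    draw = rng.choice(len(majority), size=len(minority), replace=False)
    return minority + [majority[i] for i in draw]


def _cv_mtry(X, y, grid, config, rng) -> int:
    """Choose mtry by stratified k-fold CV AUC (ties -> smallest mtry)."""
    folds = min(config.cv_folds, int(np.bincount(y).min()))
    if folds < 2:
        return grid[0]
    skf = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    best_mtry, best_auc = grid[0], -np.inf
    splits = list(skf.split(X, y))
    for mtry in grid:
        aucs = []
        for tr, va in splits:
            if len(np.unique(y[va])) < 2:
                continue
            rf = RandomForestClassifier(
                n_estimators=max(50, config.ntree // 10),
                min_samples_leaf=config.nodesize,
                max_features=mtry,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(X[tr], y[tr])
            p = rf.predict_proba(X[va])[:, 1]
            aucs.append(empirical_auc(p, y[va]))
        mean_auc = float(np.mean(aucs)) if aucs else -np.inf
        if mean_auc > best_auc + 1e-12:
            best_auc, best_mtry = mean_auc, mtry
    return best_mtry


def fit_ensemble(
    matrix: pd.DataFrame, labels: pd.Series, config: MultDSConfig
) -> EnsembleModel:
    """Fit the MultDS ensemble on the training split.

    The stratified 70/30 split is drawn first; each of the ``n_models``
    balanced down-sized sets then selects mtry by cross-validated AUC and
    fits a forest on the full balanced set. All randomness derives from
    ``config.seed`` through per-model substreams, so the first k models
    are identical whatever ``n_models`` is.
    """
    if matrix.isna().to_numpy().any():
        raise ValueError(
            "feature matrix contains missing values; impute or drop before fitting"
        )
    labels = pd.Series(labels).reindex(matrix.index)
    y_all = (labels == config.positive_label).astype(int)
    train_ids, test_ids = split_train_test(
        labels, config.train_fraction, seed=config.seed
    )
    Xtr = matrix.loc[train_ids]
    ytr = y_all.loc[train_ids]
    grid = config.grid_for(matrix.shape[1])
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_models)
    model = EnsembleModel(
        feature_ids=tuple(str(c) for c in matrix.columns),
        train_ids=tuple(train_ids),
        test_ids=tuple(test_ids),
        config=config,
    )
    for k in range(config.n_models):
        rng = np.random.default_rng(streams[k])
        bal_ids = multds_sample(ytr, rng)
        Xb = Xtr.loc[bal_ids].to_numpy(dtype=float)
        yb = ytr.loc[bal_ids].to_numpy()
        mtry = _cv_mtry(Xb, yb, grid, config, rng)
        rf = RandomForestClassifier(
            n_estimators=config.ntree,
            min_samples_leaf=config.nodesize,
            max_features=mtry,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(Xb, yb)
        model.forests.append(rf)
        model.balanced_indices.append(tuple(bal_ids))
        model.chosen_mtry.append(mtry)
    # operating threshold: Youden's J on TRAINING probabilities
    p_train = predict_proba(model, Xtr)
    model.threshold = _youden_threshold(p_train.to_numpy(), ytr.to_numpy())
    return model


def _youden_threshold(p: np.ndarray, y: np.ndarray) -> float:
    cand = np.unique(p)
    best_t, best_j = 0.5, -np.inf
    for t in cand:
        pred = p >= t
        sens = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
        spec = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def predict_proba(model: EnsembleModel, samples: pd.DataFrame) -> pd.Series:
    """Mean positive-class probability across the ensemble's forests."""
    cols = samples.rename(columns=str)
    missing = [f for f in model.feature_ids if f not in cols.columns]
    if missing:
        raise KeyError(f"samples lack model features: {missing}")
    X = cols[list(model.feature_ids)].to_numpy(dtype=float)
    probs = np.mean([rf.predict_proba(X)[:, 1] for rf in model.forests], axis=0)
    return pd.Series(probs, index=samples.index, name="p_positive")


def delong_ci(
    scores: np.ndarray, y: np.ndarray, level: float = 0.95
) -> tuple[float, float, float]:
    """Empirical AUC with its DeLong asymptotic confidence interval.

    Uses the structural-component (midrank) variance estimator for a
    single correlated ROC curve; the interval is clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes required")
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos, r_neg = all_ranks[:m], all_ranks[m:]
    auc = (r_pos.sum() - m * (m + 1) / 2) / (m * n)
    v10 = (r_pos - stats.rankdata(pos)) / n  # P(neg < pos_i) components
    v01 = 1.0 - (r_neg - stats.rankdata(neg)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(0.5 + level / 2)
    return float(auc), float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se))


def evaluate(
    model: EnsembleModel, samples: pd.DataFrame, labels: pd.Series
) -> tuple[DiagnosticPerformance, pd.DataFrame]:
    """Held-out performance report plus the ROC curve table.

    ``samples`` must be disjoint from the training split recorded in the
    model (a shared id is a hard error: performance on seen samples is
    meaningless). Sensitivity/specificity use the training-derived
    threshold unchanged.
    """
    overlap = set(samples.index) & set(model.train_ids)
    if overlap:
        raise ValueError(f"test samples overlap the training split: {sorted(overlap)[:5]}")
    labels = pd.Series(labels).reindex(samples.index)
    pos = model.config.positive_label if model.config else 1
    y = (labels == pos).astype(int).to_numpy()
    p = predict_proba(model, samples).to_numpy()
    auc, lo, hi = delong_ci(p, y)
    pred = p >= model.threshold
    sens = float((pred & (y == 1)).sum() / max((y == 1).sum(), 1))
    spec = float((~pred & (y == 0)).sum() / max((y == 0).sum(), 1))
    perf = DiagnosticPerformance(
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        sensitivity=sens,
        specificity=spec,
        threshold=model.threshold,
        n_test_positive=int((y == 1).sum()),
        n_test_negative=int((y == 0).sum()),
    )
    order = np.argsort(-p, kind="stable")
    tps = np.cumsum(y[order] == 1)
    fps = np.cumsum(y[order] == 0)
    roc = pd.DataFrame(
        {
            "threshold": p[order],
            "tpr": tps / max((y == 1).sum(), 1),
            "fpr": fps / max((y == 0).sum(), 1),
        }
    )
    return perf, roc
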