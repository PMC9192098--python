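"""RBF-SVM classification with exhaustive-subset feature selection.

Pipeline: single-feature screening (keep features whose cross-validated
single-feature accuracy exceeds a threshold), exhaustive evaluation of all
non-empty candidate subsets ranked by mean CV accuracy (ties: fewer
features, then higher AUC), and a PCA baseline whose dimensionality is
chosen by Minka's MLE. Metrics: accuracy, specificity, sensitivity, F1
from the confusion counts, AUC by the rank (Mann-Whitney) statistic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError

#: Candidate pools per model flavour.
ECG_FEATURES = ("S_I", "S_II", "S_III", "S_AVR", "S_AVL", "S_AVF",
                "S_V1", "S_V2", "S_V3", "S_V4", "S_V5", "S_V6")
VCG_FEATURES = ("S_Vx", "S_Vy", "S_Vz", "SHI", "THI")

METRIC_NAMES = ("accuracy", "specificity", "sensitivity", "f1", "auc")


@dataclass(frozen=True)
class ModelConfig:
    C: float = 1.0
    gamma: str | float = "scale"
    screen_threshold: float = 0.6
    cv_folds: int = 5
    seed: int = 0
    class_weight: str | None = None
    max_grid_candidates: int = 12

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ConfigError("C must be positive")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if not 0.0 <= self.screen_threshold < 1.0:
            raise ConfigError("screen_threshold must be in [0, 1)")


@dataclass
class EvaluationReport:
    per_fold: list[dict[str, float]]
    mean: dict[str, float]
    sd: dict[str, float]
    confusion: list[dict[str, int]]
    selected_features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "mean": self.mean,
            "sd": self.sd,
            "confusion": self.confusion,
            "selected_features": self.selected_features,
        }


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auc_rank(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic (ties get half credit)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: y_true contains a single class")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(y_true, y_pred, scores) -> dict[str, float]:
    """Accuracy, specificity, sensitivity, F1 from confusion counts; rank AUC.

    Positive class is label 1 (ischemic), negative 0 (healthy).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    total = tp + tn + fp + fn
    out = {
        "accuracy": (tp + tn) / total,
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan"),
        "auc": auc_rank(y_true, scores),
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }
    return out


# ---------------------------------------------------------------------------
# Training and cross-validation
# ---------------------------------------------------------------------------

def _make_estimator(cfg: ModelConfig) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", C=cfg.C, gamma=cfg.gamma,
                    class_weight=cfg.class_weight)),
    ])


def train_svm(X: np.ndarray, y: np.ndarray, cfg: ModelConfig = ModelConfig()) -> Pipeline:
    """Fit a standardize+RBF-SVM pipeline; constant columns trigger a warning
    (the scaler leaves them at zero, which is equivalent to dropping them)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes")
    if np.any(X.std(axis=0) == 0):
        warnings.warn("constant feature column(s); standardized to zero",
                      stacklevel=2)
    est = _make_estimator(cfg)
    est.fit(X, y)
    return est


def _stratified_folds(y: np.ndarray, cfg: ModelConfig):
    """Stratified partition where every training split holds both classes;
    re-drawn with a shifted seed up to 100 times before giving up."""
    for attempt in range(100):
        skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                              random_state=cfg.seed + attempt)
        folds = list(skf.split(np.zeros_like(y), y))
        if all(np.unique(y[tr]).size == 2 for tr, _ in folds):
            return folds
    raise ValueError("could not build folds with both classes in every train split")


def cross_validate(X: np.ndarray, y: np.ndarray,
                   cfg: ModelConfig = ModelConfig(),
                   feature_names: list[str] | None = None) -> EvaluationReport:
    """Stratified k-fold evaluation; every sample is tested exactly once."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < cfg.cv_folds:
        raise ValueError("fewer samples than folds")
    per_fold, confusion = [], []
    for tr, te in _stratified_folds(y, cfg):
        est = _make_estimator(cfg)
        est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        score = est.decision_function(X[te])
        m = compute_metrics(y[te], pred, score)
        confusion.append({k: m.pop(k) for k in ("tp", "tn", "fp", "fn")})
        per_fold.append(m)
    mean = {k: float(np.mean([f[k] for f in per_fold])) for k in METRIC_NAMES}
    sd = {k: float(np.std([f[k] for f in per_fold])) for k in METRIC_NAMES}
    return EvaluationReport(per_fold, mean, sd, confusion,
                            selected_features=list(feature_names or []))


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

def screen_single_features(X: np.ndarray, y: np.ndarray, names: list[str],
                           cfg: ModelConfig = ModelConfig()) -> list[tuple[str, float]]:
    """Keep features whose single-feature CV accuracy exceeds the threshold.

    Returns (name, accuracy) pairs sorted by descending accuracy; empty
    list when nothing clears the bar.
    """
    X = np.asarray(X, dtype=float)
    kept = []
    for i, name in enumerate(names):
        rep = cross_validate(X[:, [i]], y, cfg)
        acc = rep.mean["accuracy"]
        if acc > cfg.screen_threshold:
            kept.append((name, acc))
    return sorted(kept, key=lambda t: -t[1])


def grid_search_subsets(X: np.ndarray, y: np.ndarray, candidates: list[str],
                        names: list[str],
                        cfg: ModelConfig = ModelConfig()) -> tuple[list[str], EvaluationReport]:
    """Exhaustively evaluate every non-empty subset of the candidates.

    Ranking: mean CV accuracy, ties broken by fewer features, then higher
    mean AUC. All SVMs share the same hyperparameters and fold seed.
    """
    if not candidates:
        raise ValueError("no candidate features to search over")
    if len(candidates) > cfg.max_grid_candidates:
        raise ValueError(
            f"{len(candidates)} candidates exceed the 2^{cfg.max_grid_candidates} cap"
        )
    idx = {n: names.index(n) for n in candidates}
    best_key, best = None, None
    for size in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            cols = [idx[n] for n in subset]
            rep = cross_validate(X[:, cols], y, cfg, feature_names=list(subset))
            key = (-rep.mean["accuracy"], size, -rep.mean["auc"])
            if best_key is None or key < best_key:
                best_key, best = key, (list(subset), rep)
    return best


def pca_baseline(X: np.ndarray, y: np.ndarray,
                 cfg: ModelConfig = ModelConfig()) -> tuple[np.ndarray, EvaluationReport]:
    """Project onto principal components (dimension by Minka's MLE) and
    cross-validate the same SVM on the projection."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n <= d:
        raise ValueError("need n > d for the MLE dimension rule")
    try:
        pca = PCA(n_components="mle", svd_solver="full").fit(X)
    except Exception:
        warnings.warn("MLE dimension estimation failed; using full rank",
                      stacklevel=2)
        pca = PCA(n_components=min(n, d), svd_solver="full").fit(X)
    Z = pca.transform(X)
    rep = cross_validate(Z, y, cfg,
                         feature_names=[f"PC{i + 1}" for i in range(Z.shape[1])])
    return Z, rep


# ---------------------------------------------------------------------------
# Model flavours
# ---------------------------------------------------------------------------

def select_and_evaluate(X: np.ndarray, y: np.ndarray, names: list[str],
                        feature_set: str,
                        cfg: ModelConfig = ModelConfig()) -> tuple[list[str], EvaluationReport]:
    """Run screening + subset search for one model flavour.

    ``feature_set``: "ecg_only" (12 ECG SampEn), "vcg_only" (3 VCG SampEn +
    SHI + THI) or "ecg_plus_vcg" (union of the two flavours' selections).
    """
    if feature_set == "ecg_only":
        pool = [n for n in ECG_FEATURES if n in names]
    elif feature_set == "vcg_only":
        pool = [n for n in VCG_FEATURES if n in names]
    elif feature_set == "ecg_plus_vcg":
        sel_e, _ = select_and_evaluate(X, y, names, "ecg_only", cfg)
        sel_v, _ = select_and_evaluate(X, y, names, "vcg_only", cfg)
        pool = sel_e + sel_v
    else:
        raise ConfigError(f"unknown feature_set {feature_set!r}")
    cols = [names.index(n) for n in pool]
    kept = screen_single_features(X[:, cols], y, pool, cfg)
    candidates = [n for n, _ in kept]
    if not candidates:
        # nothing cleared the screen: fall back to the best single feature
        accs = [(n, cross_validate(X[:, [names.index(n)]], y, cfg).mean["accuracy"])
                for n in pool]
        candidates = [max(accs, key=lambda t: t[1])[0]]
    return grid_search_subsets(X, y, candidates, names, cfg)
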