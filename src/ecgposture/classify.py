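"""Lying-position classification: quantile normalization, random forest,
the three evaluation schemes and learning curves.

Schemes
-------
subject-specific
    Per subject: a stratified 20 % of epochs trains the forest, the other
    80 % are the test set; repeated 10 times with fresh random splits.
subject-independent (raw)
    Leave-one-subject-out: the other subjects' pooled epochs train, the
    held-out subject tests. Between-subject morphology offsets make this
    hard.
subject-independent (normalized)
    As above, but every subject's features are first rescaled by their
    own 5 %/95 % quantiles mapped linearly to [0, 1] (values outside the
    quantile span extrapolate linearly). Fitting per subject is the only
    choice that can remove a subject-level offset for an unseen subject.

The forest uses 500 fully grown trees on bootstrap resamples with
sqrt(n_features) candidate features per split, majority vote for the hard
prediction and the vote fraction as the per-class score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .core import CLASS_ORDER
from .evaluate import ConfusionMatrix, MetricsBundle, evaluate_predictions
from .features import SELECTED_FEATURES

__all__ = [
    "NormalizationParams",
    "SchemeConfig",
    "SchemeResult",
    "quantile_normalize_fit",
    "quantile_normalize_apply",
    "normalize_per_subject",
    "train_forest",
    "run_subject_specific",
    "run_subject_independent",
    "learning_curve",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature 5 %/95 % quantiles; constant features are flagged."""

    q05: dict[str, float]
    q95: dict[str, float]
    constant: frozenset[str] = frozenset()


def quantile_normalize_fit(
    values: pd.DataFrame,
    features: tuple[str, ...] | None = None,
    min_samples: int = 20,
) -> NormalizationParams:
    """Fit the 5 % and 95 % empirical quantiles (linear interpolation) of
    each feature column; the span between them maps to [0, 1] and covers
    90 % of the samples. A constant feature (q95 = q05) is flagged and
    later maps to 0.5."""
    features = tuple(features or values.columns)
    q05: dict[str, float] = {}
    q95: dict[str, float] = {}
    constant: set[str] = set()
    for feat in features:
        vals = values[feat].dropna().to_numpy(dtype=float)
        if vals.size < min_samples:
            raise ValueError(
                f"need >= {min_samples} non-missing values to fit {feat!r}, "
                f"got {vals.size}")
        lo, hi = np.quantile(vals, [0.05, 0.95])  # linear interpolation
        q05[feat], q95[feat] = float(lo), float(hi)
        if hi == lo:
            constant.add(feat)
    return NormalizationParams(q05=q05, q95=q95, constant=frozenset(constant))


def quantile_normalize_apply(
    values: pd.DataFrame,
    params: NormalizationParams,
) -> pd.DataFrame:
    """(x - q05) / (q95 - q05) per feature; values outside the quantile
    span extrapolate linearly (results may leave [0, 1]). Constant
    features map to 0.5."""
    out = values.copy()
    for feat in params.q05:
        if feat not in out.columns:
            continue
        if feat in params.constant:
            out[feat] = 0.5
        else:
            span = params.q95[feat] - params.q05[feat]
            out[feat] = (out[feat] - params.q05[feat]) / span
    return out


def normalize_per_subject(
    records: pd.DataFrame,
    features: tuple[str, ...],
) -> pd.DataFrame:
    """Rescale every subject's features by their own quantile span."""
    parts = []
    for _, sub in records.groupby("subject_id", observed=True, sort=False):
        params = quantile_normalize_fit(sub[list(features)], features)
        out = sub.copy()
        out[list(features)] = quantile_normalize_apply(sub[list(features)], params)
        parts.append(out)
    return pd.concat(parts).loc[records.index]


@dataclass(frozen=True)
class SchemeConfig:
    """Classification configuration shared by all schemes."""

    features: tuple[str, ...] = SELECTED_FEATURES
    normalize: bool = False
    train_fraction: float = 0.2
    repeats: int = 10
    n_trees: int = 500
    m_try: int | str = "sqrt"
    min_class_epochs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class SchemeResult:
    """Per-run metrics plus aggregates over repeats/folds."""

    runs: list[MetricsBundle] = field(default_factory=list)
    run_labels: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    @property
    def pooled_cm(self) -> ConfusionMatrix:
        if not self.runs:
            raise ValueError("no runs")
        cm = self.runs[0].cm
        for r in self.runs[1:]:
            cm = cm + r.cm
        return cm

    def summary(self) -> dict:
        acc = [r.accuracy for r in self.runs]
        kap = [r.kappa for r in self.runs]
        out = {
            "n_runs": len(self.runs),
            "accuracy_mean": float(np.mean(acc)) if acc else float("nan"),
            "accuracy_sd": float(np.std(acc, ddof=1)) if len(acc) > 1 else 0.0,
            "kappa_mean": float(np.nanmean(kap)) if kap else float("nan"),
            "kappa_sd": float(np.nanstd(kap, ddof=1)) if len(kap) > 1 else 0.0,
        }
        def nanmean(vals: list[float]) -> float:
            arr = np.asarray(vals, dtype=float)
            arr = arr[np.isfinite(arr)]
            return float(arr.mean()) if arr.size else float("nan")

        for cls in (self.runs[0].cm.class_order if self.runs else ()):
            out[f"auc_{cls}"] = nanmean([r.per_class[cls]["auc"] for r in self.runs])
            out[f"sensitivity_{cls}"] = nanmean(
                [r.per_class[cls]["sensitivity"] for r in self.runs])
        if self.runs:
            out["pooled_confusion_matrix"] = self.pooled_cm.counts.tolist()
            out["pooled_total"] = self.pooled_cm.total
        return out


def _clean_xy(records: pd.DataFrame, features: tuple[str, ...]):
    """Drop rows with any missing selected feature; return X, y, index."""
    cols = list(features)
    ok = records[cols].notna().all(axis=1)
    sub = records.loc[ok]
    return sub[cols].to_numpy(dtype=float), sub["position"].to_numpy(), sub.index


def train_forest(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SchemeConfig,
    seed: int | None = None,
) -> RandomForestClassifier:
    """Fit the random forest: ``n_trees`` unpruned trees on bootstrap
    resamples of size N, ``m_try`` candidate features per split."""
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    if np.isnan(X).any():
        raise ValueError("training matrix contains missing values")
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.m_try,
        bootstrap=True,
        random_state=cfg.seed if seed is None else seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def _score_matrix(forest: RandomForestClassifier, X: np.ndarray,
                  class_order: tuple[str, ...]) -> np.ndarray:
    """Vote fractions re-ordered to ``class_order`` (absent classes = 0)."""
    proba = forest.predict_proba(X)
    out = np.zeros((X.shape[0], len(class_order)))
    for j, cls in enumerate(class_order):
        hits = np.where(forest.classes_ == cls)[0]
        if hits.size:
            out[:, j] = proba[:, hits[0]]
    return out


def _run_split(
    X_train, y_train, X_test, y_test, cfg: SchemeConfig, seed: int,
    class_order: tuple[str, ...],
) -> MetricsBundle:
    forest = train_forest(X_train, y_train, cfg, seed=seed)
    y_pred = forest.predict(X_test)
    scores = _score_matrix(forest, X_test, class_order)
    return evaluate_predictions(y_test, y_pred, scores, class_order)


def run_subject_specific(
    records: pd.DataFrame,
    cfg: SchemeConfig | None = None,
    class_order: tuple[str, ...] = CLASS_ORDER,
) -> SchemeResult:
    """Within-subject scheme: stratified train_fraction/rest splits,
    repeated ``cfg.repeats`` times with fresh draws.

    ``records`` must hold a single subject's classification-ready epochs
    (prone already excluded). A class with fewer than
    ``cfg.min_class_epochs`` epochs raises (the subject is unusable).
    """
    cfg = cfg or SchemeConfig()
    X, y, _ = _clean_xy(records, cfg.features)
    present = [c for c in class_order if np.sum(y == c) > 0]
    counts = {c: int(np.sum(y == c)) for c in present}
    if any(v < cfg.min_class_epochs for v in counts.values()) or len(present) < 2:
        raise ValueError(f"too few epochs per class for a stratified split: {counts}")
    result = SchemeResult()
    rng = np.random.default_rng(cfg.seed)
    for rep in range(cfg.repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=cfg.train_fraction, stratify=y, random_state=rep_seed)
        result.runs.append(
            _run_split(X_tr, y_tr, X_te, y_te, cfg, rep_seed, class_order))
        result.run_labels.append(f"repeat{rep + 1}")
    return result


def run_subject_independent(
    records: pd.DataFrame,
    cfg: SchemeConfig | None = None,
    class_order: tuple[str, ...] = CLASS_ORDER,
) -> SchemeResult:
    """Leave-one-subject-out scheme, optionally with per-subject quantile
    normalization (``cfg.normalize``). One fold per subject; a fold whose
    test subject lacks some classes still runs, noted in the fold label."""
    cfg = cfg or SchemeConfig()
    subjects = list(dict.fromkeys(records["subject_id"]))
    if len(subjects) < 3:
        raise ValueError("subject-independent scheme needs >= 3 subjects")
    data = records
    if cfg.normalize:
        data = normalize_per_subject(records, cfg.features)
    result = SchemeResult()
    rng = np.random.default_rng(cfg.seed)
    for subject in subjects:
        fold_seed = int(rng.integers(0, 2**31 - 1))
        test = data[data["subject_id"] == subject]
        train = data[data["subject_id"] != subject]
        X_tr, y_tr, _ = _clean_xy(train, cfg.features)
        X_te, y_te, _ = _clean_xy(test, cfg.features)
        if len(y_te) == 0:
            result.skipped.append(subject)
            continue
        bundle = _run_split(X_tr, y_tr, X_te, y_te, cfg, fold_seed, class_order)
        missing = [c for c in class_order if c not in set(y_te)]
        label = subject + (f" (absent: {','.join(missing)})" if missing else "")
        result.runs.append(bundle)
        result.run_labels.append(label)
    return result


def learning_curve(
    records: pd.DataFrame,
    fractions: tuple[float, ...] = (0.05, 0.1, 0.2),
    repeats: int = 10,
    cfg: SchemeConfig | None = None,
    class_order: tuple[str, ...] = CLASS_ORDER,
) -> pd.DataFrame:
    """Accuracy/kappa versus training fraction (repeated stratified splits).

    Fractions that leave some class without a training epoch are skipped.
    Returns one row per surviving fraction with mean and SD of accuracy
    and kappa over the repeats.
    """
    cfg = cfg or SchemeConfig()
    X, y, _ = _clean_xy(records, cfg.features)
    rows = []
    rng = np.random.default_rng(cfg.seed)
    classes, counts = np.unique(y, return_counts=True)
    for frac in fractions:
        if np.floor(counts * frac).min() < 1:
            continue  # a class would be empty in training
        accs, kaps = [], []
        for _rep in range(repeats):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, train_size=frac, stratify=y, random_state=rep_seed)
            bundle = _run_split(X_tr, y_tr, X_te, y_te, cfg, rep_seed, class_order)
            accs.append(bundle.accuracy)
            kaps.append(bundle.kappa)
        rows.append({
            "train_fraction": frac,
            "accuracy_mean": float(np.mean(accs)),
            "accuracy_sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            "kappa_mean": float(np.mean(kaps)),
            "kappa_sd": float(np.std(kaps, ddof=1)) if len(kaps) > 1 else 0.0,
        })
    return pd.DataFrame(rows)
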