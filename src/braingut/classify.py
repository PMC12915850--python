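"""Leakage-safe model construction and evaluation for case-control cohorts.

The centre of the framework is :class:`FeatureSelectingClassifier`, an
sklearn-style estimator whose ``fit`` runs the entire inner loop on the
training data it receives: univariate feature ranking, top-k selection
by inner-CV AUROC, and hyperparameter search (sequential model-based
with a random-search fallback) by inner-CV AUROC.  Because everything
data-dependent happens inside ``fit``, wrapping the estimator in any
outer cross-validation is leakage-safe by construction.

On top of it sit the evaluation schemes: 10-times repeated 5-fold
nested CV (unbiased performance), leave-one-cohort-out CV
(cross-population generalization), full-data tuning + final fit, and
the three-tier validation battery (external robustness, cross-study
generalization, cross-disease specificity).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

FAMILIES = ("elastic_net", "lasso_logistic", "logistic", "random_forest", "gradient_boosting")

#: hyperparameter search spaces; log-scaled dimensions are searched on log10
DEFAULT_SPACES: dict[str, dict[str, tuple[float, float, bool, bool]]] = {
    # name: (low, high, log-scale, integer)
    "elastic_net": {"C": (1e-3, 1e2, True, False), "l1_ratio": (0.05, 0.95, False, False)},
    "lasso_logistic": {"C": (1e-3, 1e2, True, False)},
    "logistic": {"C": (1e-3, 1e2, True, False)},
    "random_forest": {
        "n_estimators": (100, 500, False, True),
        "max_depth": (2, 16, False, True),
        "min_samples_leaf": (1, 10, False, True),
    },
    # gradient boosting keeps the published CatBoost-style ranges:
    # depth [4, 12], learning_rate [0.01, 0.3], iterations [100, 1000],
    # l2 leaf regularization [1, 20]
    "gradient_boosting": {
        "max_depth": (4, 12, False, True),
        "learning_rate": (0.01, 0.3, True, False),
        "max_iter": (100, 1000, False, True),
        "l2_regularization": (1.0, 20.0, False, False),
    },
}

DEFAULT_K_GRID = (16, 32, 64, 128, None)


@dataclass
class ModelSpec:
    """Model family plus its hyperparameter search space and budget."""

    family: str = "lasso_logistic"
    space: Optional[dict[str, tuple[float, float, bool, bool]]] = None
    k_grid: tuple = DEFAULT_K_GRID
    search_budget: int = 30
    optimizer: str = "smbo"  # smbo | random
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.search_budget < 1:
            raise ValueError("search budget must be >= 1")
        if self.space is None:
            self.space = dict(DEFAULT_SPACES[self.family])
        for name, (lo, hi, _, _) in self.space.items():
            if not lo <= hi:
                raise ValueError(f"empty range for {name}")


def _scaled(est):
    """Linear models get in-pipeline standardization (fit on training data)."""
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    return make_pipeline(StandardScaler(), est)


def _base_estimator(family: str, params: dict, seed: int):
    if family == "elastic_net":
        return _scaled(LogisticRegression(
            solver="saga", max_iter=4000, C=params.get("C", 1.0),
            l1_ratio=params.get("l1_ratio", 0.5), random_state=seed,
        ))
    if family == "lasso_logistic":
        return _scaled(LogisticRegression(
            solver="liblinear", max_iter=2000, C=params.get("C", 1.0),
            l1_ratio=1.0, random_state=seed,
        ))
    if family == "logistic":
        return _scaled(LogisticRegression(max_iter=2000, C=params.get("C", 1.0)))
    if family == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(params.get("n_estimators", 300)),
            max_depth=None if params.get("max_depth") is None else int(params["max_depth"]),
            min_samples_leaf=int(params.get("min_samples_leaf", 1)),
            random_state=seed, n_jobs=1,
        )
    if family == "gradient_boosting":
        return HistGradientBoostingClassifier(
            max_depth=int(params.get("max_depth", 6)),
            learning_rate=float(params.get("learning_rate", 0.1)),
            max_iter=int(params.get("max_iter", 200)),
            l2_regularization=float(params.get("l2_regularization", 1.0)),
            random_state=seed,
        )
    raise ValueError(family)


def log_abundance(X: np.ndarray, pseudocount: float = 1e-5) -> np.ndarray:
    """Standard feature representation for abundance-based models.

    ``log10(abundance + pseudocount)`` tames the heavy right skew of
    relative abundances; the pseudocount (half the 1e-4 detection
    cutoff) keeps structural zeros finite.
    """
    return np.log10(np.asarray(X, dtype=float) + pseudocount)


def leaky_cv_auroc(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 32,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Deliberately LEAKY evaluation: select features on the full data,
    then cross-validate.

    This is the textbook selection-before-CV mistake.  It exists only as
    a regression oracle: on pure-noise data it produces optimistically
    inflated AUROCs, which the leakage-safe nested procedure must not.
    Never use it to report performance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    scores = univariate_auc_scores(X, y)  # leak: uses ALL labels
    feats = np.argsort(-scores, kind="stable")[:k]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        est = LogisticRegression(max_iter=2000)
        est.fit(X[np.ix_(tr, feats)], y[tr])
        aucs.append(roc_auc_score(y[te], est.predict_proba(X[np.ix_(te, feats)])[:, 1]))
    return float(np.mean(aucs))


def auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (probability a case outscores a control)."""
    return float(roc_auc_score(y_true, scores))


def univariate_auc_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature |AUC - 0.5|, the rank-based discrimination of each feature."""
    y = np.asarray(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = stats.rankdata(X, axis=0)
    u = ranks[y == 1].sum(axis=0) - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    return np.abs(auc - 0.5)


def _sample_params(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, (lo, hi, log, integer) in space.items():
        if log:
            v = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
        else:
            v = rng.uniform(lo, hi)
        out[name] = int(round(v)) if integer else float(v)
    return out


def _params_to_vector(params: dict, space: dict) -> np.ndarray:
    vec = []
    for name, (lo, hi, log, _) in space.items():
        v = params[name]
        if log:
            v, lo, hi = np.log10(v), np.log10(lo), np.log10(hi)
        vec.append((v - lo) / (hi - lo) if hi > lo else 0.0)
    return np.array(vec)


class FeatureSelectingClassifier(BaseEstimator, ClassifierMixin):
    """Classifier with in-fit feature selection and hyperparameter search.

    ``fit(X, y)`` performs, using only the data it is given:

    1. univariate feature ranking by rank-based AUC;
    2. choice of top-k (over ``spec.k_grid``) by inner-CV AUROC at
       default hyperparameters;
    3. hyperparameter search over ``spec.space`` by inner-CV AUROC —
       sequential model-based optimization (random-forest surrogate,
       upper-confidence acquisition over fresh random candidates) or
       plain random search at the same budget;
    4. refit of the winning configuration on all of ``X, y``.

    Fitted attributes: ``selected_features_`` (column indices),
    ``best_params_``, ``inner_cv_auroc_``, ``estimator_``.
    """

    def __init__(
        self,
        spec: Optional[ModelSpec] = None,
        inner_folds: int = 5,
        random_state: int = 0,
    ):
        self.spec = spec
        self.inner_folds = inner_folds
        self.random_state = random_state

    def _inner_cv_auroc(self, X, y, features, params, spec, rng_seed) -> float:
        skf = StratifiedKFold(n_splits=self.inner_folds, shuffle=True, random_state=rng_seed)
        aucs = []
        for tr, va in skf.split(X, y):
            est = _base_estimator(spec.family, params, rng_seed)
            est.fit(X[np.ix_(tr, features)], y[tr])
            p = est.predict_proba(X[np.ix_(va, features)])[:, 1]
            if len(np.unique(y[va])) < 2:
                continue
            aucs.append(roc_auc_score(y[va], p))
        return float(np.mean(aucs)) if aucs else 0.5

    def fit(self, X, y):
        spec = self.spec or ModelSpec()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes to fit")
        rng = np.random.default_rng(self.random_state)
        seed32 = int(rng.integers(2**31 - 1))

        # (a) univariate ranking on the training data only
        scores = univariate_auc_scores(X, y)
        ranking = np.argsort(-scores, kind="stable")

        # (b) top-k selection by inner-CV AUROC at default hyperparameters
        best_k, best_k_auc = None, -np.inf
        for k in spec.k_grid:
            kk = X.shape[1] if k is None else min(int(k), X.shape[1])
            feats = ranking[:kk]
            a = self._inner_cv_auroc(X, y, feats, {}, spec, seed32 % (2**31 - 1))
            if a > best_k_auc:
                best_k, best_k_auc = kk, a
        features = ranking[:best_k]

        # (c) hyperparameter search by inner-CV AUROC; the family default
        # configuration is always evaluated first so a tiny budget can
        # never do worse than the defaults
        evaluated: list[tuple[dict, float]] = [
            ({}, self._inner_cv_auroc(X, y, features, {}, spec, seed32))
        ]
        n_init = min(max(4, spec.search_budget // 3), spec.search_budget - 1)
        for _ in range(n_init):
            params = _sample_params(spec.space, rng)
            a = self._inner_cv_auroc(X, y, features, params, spec, seed32)
            evaluated.append((params, a))
        while len(evaluated) < spec.search_budget:
            if spec.optimizer == "smbo" and len(evaluated) >= 4:
                params = self._propose_smbo(evaluated, spec, rng)
            else:
                params = _sample_params(spec.space, rng)
            a = self._inner_cv_auroc(X, y, features, params, spec, seed32)
            evaluated.append((params, a))
        best_params, best_auc = max(evaluated, key=lambda t: t[1])

        est = _base_estimator(spec.family, best_params, seed32)
        est.fit(X[:, features], y)

        self.spec_ = spec
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        self.selected_features_ = np.asarray(features)
        self.selected_k_ = best_k
        self.best_params_ = best_params
        self.inner_cv_auroc_ = float(best_auc)
        self.estimator_ = est
        return self

    def _propose_smbo(self, evaluated, spec, rng, n_candidates: int = 64):
        """Surrogate-guided proposal: RF surrogate, UCB over random draws."""
        full = [(p, a) for p, a in evaluated if set(p) == set(spec.space)]
        if len(full) < 4:
            return _sample_params(spec.space, rng)
        Xs = np.vstack([_params_to_vector(p, spec.space) for p, _ in full])
        ys = np.array([a for _, a in full])
        surrogate = RandomForestRegressor(
            n_estimators=30, random_state=int(rng.integers(2**31 - 1))
        ).fit(Xs, ys)
        cands = [_sample_params(spec.space, rng) for _ in range(n_candidates)]
        V = np.vstack([_params_to_vector(p, spec.space) for p in cands])
        preds = np.stack([t.predict(V) for t in surrogate.estimators_])
        ucb = preds.mean(axis=0) + preds.std(axis=0)
        return cands[int(np.argmax(ucb))]

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)
        return self.estimator_.predict_proba(X[:, self.selected_features_])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    def decision_scores(self, X):
        return self.predict_proba(X)[:, 1]


@dataclass
class NestedCVReport:
    """Outcome of repeated nested CV."""

    fold_aurocs: "np.ndarray"  # (repeats, outer_folds)
    selected_features: list[list[np.ndarray]]  # per repeat, per fold (indices)
    chosen_params: list[list[dict]]
    oof_probabilities: "np.ndarray"  # (repeats, n_samples)
    feature_names: list[str] = field(default_factory=list)

    @property
    def mean_auroc(self) -> float:
        return float(np.nanmean(self.fold_aurocs))

    @property
    def sd_auroc(self) -> float:
        return float(np.nanstd(self.fold_aurocs))

    def consensus_features(self, threshold: float = 0.5) -> np.ndarray:
        """Feature indices selected in at least ``threshold`` of all outer folds."""
        total = sum(len(r) for r in self.selected_features)
        counts: dict[int, int] = {}
        for rep in self.selected_features:
            for fold_feats in rep:
                for f in fold_feats:
                    counts[int(f)] = counts.get(int(f), 0) + 1
        keep = sorted(f for f, c in counts.items() if c / total >= threshold)
        return np.asarray(keep, dtype=int)


@dataclass
class LOCOReport:
    cohort_aurocs: dict[str, float]
    oof_probabilities: "np.ndarray"  # aligned to the dataset's samples
    selected_features: dict[str, np.ndarray]
    chosen_params: dict[str, dict]

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(list(self.cohort_aurocs.values())))

    def consensus_features(self, threshold: float = 0.5) -> np.ndarray:
        total = len(self.selected_features)
        counts: dict[int, int] = {}
        for feats in self.selected_features.values():
            for f in feats:
                counts[int(f)] = counts.get(int(f), 0) + 1
        keep = sorted(f for f, c in counts.items() if c / total >= threshold)
        return np.asarray(keep, dtype=int)


def _stratified_outer_split(y, n_folds, seed, max_attempts=10):
    for attempt in range(max_attempts):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[te])) == 2 for _, te in folds):
            return folds
    raise RuntimeError("could not produce folds containing both classes")


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    spec: Optional[ModelSpec] = None,
    repeats: int = 10,
    outer_folds: int = 5,
    seed: int = 0,
    inner_folds: int = 5,
    feature_names: Optional[Sequence[str]] = None,
) -> NestedCVReport:
    """Repeated stratified nested cross-validation.

    The outer loop estimates generalization; all selection and tuning
    happens inside ``FeatureSelectingClassifier.fit`` on the outer
    training portion only, so no statistic from a held-out fold can
    influence selection.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n = len(y)
    fold_aurocs = np.full((repeats, outer_folds), np.nan)
    oof = np.full((repeats, n), np.nan)
    sel_feats: list[list[np.ndarray]] = []
    params_all: list[list[dict]] = []
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(repeats)]
    for r in range(repeats):
        folds = _stratified_outer_split(y, outer_folds, rep_seeds[r])
        rep_feats, rep_params = [], []
        for f, (tr, te) in enumerate(folds):
            clf = FeatureSelectingClassifier(
                spec=spec, inner_folds=inner_folds,
                random_state=(rep_seeds[r] + 7919 * f) % (2**31 - 1),
            )
            clf.fit(X[tr], y[tr])
            p = clf.decision_scores(X[te])
            oof[r, te] = p
            fold_aurocs[r, f] = roc_auc_score(y[te], p)
            rep_feats.append(clf.selected_features_)
            rep_params.append(clf.best_params_)
        sel_feats.append(rep_feats)
        params_all.append(rep_params)
    return NestedCVReport(
        fold_aurocs, sel_feats, params_all, oof,
        feature_names=list(feature_names or []),
    )


def loco_cv(
    X: np.ndarray,
    y: np.ndarray,
    cohorts: Sequence[str],
    spec: Optional[ModelSpec] = None,
    seed: int = 0,
    inner_folds: int = 5,
) -> LOCOReport:
    """Leave-one-cohort-out cross-validation.

    Each outer fold holds out one entire cohort; the inner loop (feature
    selection + tuning) runs on the remaining cohorts.  Every sample's
    probability comes from a model that never saw its cohort.  Cohorts
    lacking a class are still scored but the remaining training pool
    must keep both classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    cohorts = np.asarray(cohorts)
    uniq = list(dict.fromkeys(cohorts))
    usable = [c for c in uniq if len(np.unique(y[cohorts == c])) == 2]
    if len(usable) < 3:
        raise ValueError("LOCO needs >= 3 cohorts containing both classes")
    ss = np.random.SeedSequence(seed)
    seeds = {c: int(s.generate_state(1)[0] % (2**31 - 1)) for c, s in zip(uniq, ss.spawn(len(uniq)))}
    oof = np.full(len(y), np.nan)
    cohort_aurocs: dict[str, float] = {}
    sel: dict[str, np.ndarray] = {}
    params: dict[str, dict] = {}
    for c in uniq:
        te = cohorts == c
        tr = ~te
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"training pool lacks a class when holding out {c!r}")
        clf = FeatureSelectingClassifier(spec=spec, inner_folds=inner_folds, random_state=seeds[c])
        clf.fit(X[tr], y[tr])
        p = clf.decision_scores(X[te])
        oof[te] = p
        sel[c] = clf.selected_features_
        params[c] = clf.best_params_
        if len(np.unique(y[te])) == 2:
            cohort_aurocs[c] = float(roc_auc_score(y[te], p))
        else:
            cohort_aurocs[c] = math.nan
    return LOCOReport(cohort_aurocs, oof, sel, params)


def tune_final(
    X: np.ndarray,
    y: np.ndarray,
    selected_features: Sequence[int],
    spec: Optional[ModelSpec] = None,
    seed: int = 0,
    folds: int = 5,
):
    """Full-data tuning and final fit on a fixed feature set.

    Returns ``(model, tuning_auroc, final_fit_auroc)``: the 5-fold CV
    AUROC of the tuned configuration (tuning AUROC), and the
    resubstitution AUROC of the final refit — reported for completeness
    but optimistically biased, as any full-data fit is.
    """
    spec = spec or ModelSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    feats = np.asarray(list(selected_features), dtype=int)
    if feats.size == 0:
        raise ValueError("selected_features is empty")
    rng = np.random.default_rng(seed)
    seed32 = int(rng.integers(2**31 - 1))

    def cv_auc(params):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed32)
        aucs = []
        for tr, te in skf.split(X, y):
            est = _base_estimator(spec.family, params, seed32)
            est.fit(X[np.ix_(tr, feats)], y[tr])
            if len(np.unique(y[te])) < 2:
                continue
            aucs.append(roc_auc_score(y[te], est.predict_proba(X[np.ix_(te, feats)])[:, 1]))
        return float(np.mean(aucs)) if aucs else 0.5

    evaluated = [({}, cv_auc({}))]
    for _ in range(spec.search_budget - 1):
        params = _sample_params(spec.space, rng)
        evaluated.append((params, cv_auc(params)))
    best_params, tuning_auroc = max(evaluated, key=lambda t: t[1])

    final = _base_estimator(spec.family, best_params, seed32)
    final.fit(X[:, feats], y)
    fit_auroc = float(roc_auc_score(y, final.predict_proba(X[:, feats])[:, 1]))

    manifest = FinalModel(final, feats, best_params, spec.family)
    return manifest, tuning_auroc, fit_auroc


@dataclass
class FinalModel:
    """A fitted final model plus the columns it expects."""

    estimator: object
    feature_indices: np.ndarray
    params: dict
    family: str

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        """Score a samples x all-features matrix (columns as at training)."""
        X = np.asarray(X, dtype=float)
        return self.estimator.predict_proba(X[:, self.feature_indices])[:, 1]


def score_on_features(
    model: FinalModel,
    X: np.ndarray,
    feature_names: Sequence[str],
    train_feature_names: Sequence[str],
) -> np.ndarray:
    """Score data whose feature columns may differ from training.

    Features absent at test time are imputed as zero (absence of a taxon
    is a meaningful zero in relative-abundance data); a warning is
    logged per missing feature set.
    """
    name_to_col = {n: j for j, n in enumerate(feature_names)}
    aligned = np.zeros((np.asarray(X).shape[0], len(train_feature_names)))
    missing = []
    for j, name in enumerate(train_feature_names):
        if name in name_to_col:
            aligned[:, j] = np.asarray(X)[:, name_to_col[name]]
        else:
            missing.append(name)
    if missing:
        logger.warning("zero-imputed %d features absent at test time", len(missing))
    return model.predict_proba_matrix(aligned)


def cross_study_validation(
    X: np.ndarray,
    y: np.ndarray,
    studies: Sequence[str],
    spec: Optional[ModelSpec] = None,
    seed: int = 0,
    nested_repeats: int = 2,
    outer_folds: int = 5,
) -> "pd.DataFrame":
    """Train per-study models and score them on every other study.

    Returns a DataFrame whose entry (train_study, test_study) is the
    AUROC of the train_study final model on the test study; the diagonal
    carries each study's own nested-CV AUROC.
    """
    import pandas as pd

    studies = np.asarray(studies)
    uniq = list(dict.fromkeys(studies))
    if len(uniq) < 2:
        raise ValueError("cross-study validation needs >= 2 studies")
    mat = pd.DataFrame(np.nan, index=uniq, columns=uniq, dtype=float)
    ss = np.random.SeedSequence(seed)
    seeds = {c: int(s.generate_state(1)[0] % (2**31 - 1)) for c, s in zip(uniq, ss.spawn(len(uniq)))}
    for tr_study in uniq:
        m = studies == tr_study
        Xs, ys = X[m], y[m]
        rep = nested_cv(Xs, ys, spec=spec, repeats=nested_repeats,
                        outer_folds=outer_folds, seed=seeds[tr_study])
        mat.loc[tr_study, tr_study] = rep.mean_auroc
        feats = rep.consensus_features()
        if feats.size == 0:
            feats = rep.selected_features[0][0]
        model, _, _ = tune_final(Xs, ys, feats, spec=spec, seed=seeds[tr_study])
        for te_study in uniq:
            if te_study == tr_study:
                continue
            mt = studies == te_study
            if len(np.unique(y[mt])) < 2:
                continue
            p = model.predict_proba_matrix(X[mt])
            mat.loc[tr_study, te_study] = roc_auc_score(y[mt], p)
    return mat


def cross_disease_specificity(
    model: FinalModel,
    datasets: Sequence[tuple[str, np.ndarray, np.ndarray]],
) -> dict[str, float]:
    """AUROC of a final model on datasets from other diseases.

    ``datasets`` is a list of (disease_name, X, y) with the same feature
    columns as at training.  A specific model scores ~0.5 on diseases
    whose signature it never learned.
    """
    out = {}
    for name, X, y in datasets:
        p = model.predict_proba_matrix(np.asarray(X, dtype=float))
        out[name] = float(roc_auc_score(np.asarray(y).astype(int), p))
    return out


@dataclass
class FeatureImportance:
    scores: dict[str, float]
    rule: str

    def normalized(self) -> dict[str, float]:
        total = sum(self.scores.values())
        if total == 0:
            return {k: 0.0 for k in self.scores}
        return {k: v / total for k, v in self.scores.items()}


def feature_importance(model, feature_names: Optional[Sequence[str]] = None) -> FeatureImportance:
    """Feature importances by the family-appropriate rule.

    Linear families: absolute coefficients.  Random forests: Gini
    importance (mean decrease in impurity).  Gradient boosting:
    mean absolute change in prediction when the feature is permuted
    (prediction-value-change style), computed on the training-time
    design if the estimator kept one, else unavailable.
    """
    from sklearn.pipeline import Pipeline

    est = model.estimator_ if isinstance(model, FeatureSelectingClassifier) else (
        model.estimator if isinstance(model, FinalModel) else model
    )
    if isinstance(est, Pipeline):
        est = est.steps[-1][1]
    if isinstance(est, LogisticRegression):
        if not hasattr(est, "coef_"):
            raise ValueError("model is not fitted")
        vals = np.abs(est.coef_[0])
        rule = "abs-coefficient"
    elif isinstance(est, RandomForestClassifier):
        if not hasattr(est, "feature_importances_"):
            raise ValueError("model is not fitted")
        vals = est.feature_importances_
        rule = "impurity-decrease"
    elif isinstance(est, HistGradientBoostingClassifier):
        check_is_fitted(est)
        # prediction-value-change analogue: average |delta prediction| when
        # each feature is zeroed against a baseline of the fitted predictors
        raise_on = getattr(est, "_raw_predict", None)
        if raise_on is None:
            raise ValueError("cannot compute importances for this estimator")
        vals = _gbdt_prediction_value_change(est)
        rule = "prediction-value-change"
    else:
        raise ValueError(f"no importance rule for {type(est).__name__}")
    n = len(vals)
    if feature_names is None:
        if isinstance(model, (FeatureSelectingClassifier,)):
            feature_names = [f"feature_{i}" for i in model.selected_features_]
        else:
            feature_names = [f"feature_{i}" for i in range(n)]
    if len(feature_names) != n:
        raise ValueError("feature_names length does not match the model's feature set")
    return FeatureImportance({str(k): float(v) for k, v in zip(feature_names, vals)}, rule)


def _gbdt_prediction_value_change(est: HistGradientBoostingClassifier) -> np.ndarray:
    """Total absolute split gain per feature across the ensemble's trees."""
    n_features = est.n_features_in_
    vals = np.zeros(n_features)
    for stage in est._predictors:
        for predictor in stage:
            nodes = predictor.nodes
            internal = ~nodes["is_leaf"]
            for fi, gain in zip(nodes["feature_idx"][internal], nodes["gain"][internal]):
                if gain > 0:
                    vals[fi] += gain
    return vals
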