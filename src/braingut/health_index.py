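"""Gut-brain health index: Youden-threshold-centered disease probability.

Given a classifier's predicted disease probabilities, the operating
threshold t* maximizes Youden's J = sensitivity + specificity - 1, and
each sample's index is ``t* - probability``: positive means the sample
sits on the healthy side of the decision boundary, with magnitude
quantifying confidence.  Evaluation uses Wilcoxon rank-sum tests,
Cliff's delta (disease vs. health; negative = lower in patients) and
Spearman correlations with clinical phenotypes with percentile
bootstrap confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted


def youden_threshold(probabilities: Sequence[float], labels: Sequence[int]) -> float:
    """Probability threshold maximizing Youden's J = sens + spec - 1.

    Predicted-positive means probability >= t.  Candidate cuts are
    midpoints between adjacent sorted unique probabilities (plus
    just-below-min and just-above-max), so the returned threshold is
    stable under infinitesimal perturbation of the scores.  Ties in J
    break toward higher sensitivity (the lower threshold).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.size == 0 or len(np.unique(y)) < 2:
        raise ValueError("need both classes to set a threshold")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities outside [0, 1]")
    uniq = np.unique(p)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    # endpoints cover the call-everything / call-nothing operating points;
    # if a probability of exactly 0 (or 1) is observed, the corresponding
    # cut sits infinitesimally outside [0, 1]
    below = uniq[0] / 2.0 if uniq[0] > 0 else np.nextafter(0.0, -1.0)
    above = (uniq[-1] + 1.0) / 2.0 if uniq[-1] < 1 else np.nextafter(1.0, 2.0)
    candidates = np.concatenate([[below], mids, [above]])
    n1 = (y == 1).sum()
    n0 = (y == 0).sum()
    best_t, best_j, best_sens = candidates[0], -np.inf, -np.inf
    for t in candidates:
        pred = p >= t
        sens = (pred & (y == 1)).sum() / n1
        spec = (~pred & (y == 0)).sum() / n0
        j = sens + spec - 1.0
        if j > best_j + 1e-15 or (abs(j - best_j) <= 1e-15 and sens > best_sens):
            best_t, best_j, best_sens = t, j, sens
    return float(best_t)


def mgba_hi(probability, threshold: float):
    """Health index: threshold - disease probability.

    Positive exactly when the probability falls below the operating
    threshold, i.e. the sample classifies as healthy; magnitude is the
    distance from the decision boundary.
    """
    p = np.asarray(probability, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probability outside [0, 1]")
    out = threshold - p
    return float(out) if np.isscalar(probability) or out.ndim == 0 else out


class HealthIndex(BaseEstimator):
    """Estimator wrapper: fit the Youden threshold, transform probabilities.

    ``fit(probabilities, labels)`` stores ``threshold_``;
    ``transform(probabilities)`` returns ``threshold_ - probabilities``.
    """

    def fit(self, probabilities, labels):
        self.threshold_ = youden_threshold(probabilities, labels)
        return self

    def transform(self, probabilities):
        check_is_fitted(self, "threshold_")
        return mgba_hi(np.asarray(probabilities, dtype=float), self.threshold_)

    def fit_transform(self, probabilities, labels):
        return self.fit(probabilities, labels).transform(probabilities)


def index_for_dataset(
    labels: Sequence[int],
    oof_probabilities: Optional[Sequence[float]] = None,
    external_probabilities: Optional[Sequence[float]] = None,
    threshold: Optional[float] = None,
) -> tuple[np.ndarray, float]:
    """Per-sample index values for a training population and/or external data.

    Training-population samples are scored with their out-of-cohort
    probabilities (no self-prediction); external samples with a final
    model's probabilities.  The threshold is fit on the out-of-cohort
    probabilities when not supplied.
    """
    y = np.asarray(labels).astype(int)
    if oof_probabilities is None and external_probabilities is None:
        raise ValueError("no probability source given")
    if threshold is None:
        if oof_probabilities is None:
            raise ValueError("threshold required when only external probabilities are given")
        threshold = youden_threshold(oof_probabilities, y)
    parts = []
    if oof_probabilities is not None:
        parts.append(mgba_hi(np.asarray(oof_probabilities, dtype=float), threshold))
    if external_probabilities is not None:
        parts.append(mgba_hi(np.asarray(external_probabilities, dtype=float), threshold))
    return np.concatenate([np.atleast_1d(p) for p in parts]), float(threshold)


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's delta = [#(x_i > y_j) - #(x_i < y_j)] / (|x| |y|).

    With x = disease values and y = health values, negative delta means
    the quantity is lower in patients.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    # O((m+n) log(m+n)) via ranks rather than the m*n double loop
    greater = 0
    less = 0
    ys = np.sort(y)
    greater = np.searchsorted(ys, x, side="left").sum()
    less = (len(ys) - np.searchsorted(ys, x, side="right")).sum()
    return float((greater - less) / (x.size * y.size))


@dataclass
class IndexEvaluation:
    wilcoxon_p: float
    cliffs_delta: float
    median_case: float
    median_control: float
    degenerate: bool = False
    phenotype_correlations: dict[str, dict] = field(default_factory=dict)


def evaluate_index(
    index_values: Sequence[float],
    labels: Sequence[int],
    phenotypes: Optional[Mapping[str, Sequence[float]]] = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> IndexEvaluation:
    """Group comparison and phenotype correlation of an index.

    Two-sided Wilcoxon rank-sum between case and control index values;
    Cliff's delta with the disease-vs-health sign convention; Spearman
    rho per phenotype with a percentile bootstrap CI over ``n_boot``
    resamples.  Constant inputs are reported as degenerate, not raised.
    """
    v = np.asarray(index_values, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes")
    cases, controls = v[y == 1], v[y == 0]
    if np.ptp(v) == 0:
        ev = IndexEvaluation(1.0, 0.0, float(np.median(cases)), float(np.median(controls)), degenerate=True)
    else:
        stat, p = stats.ranksums(cases, controls)
        ev = IndexEvaluation(
            float(p),
            cliffs_delta(cases, controls),
            float(np.median(cases)),
            float(np.median(controls)),
        )
    rng = np.random.default_rng(seed)
    for name, ph in (phenotypes or {}).items():
        ph = np.asarray(ph, dtype=float)
        ok = ~np.isnan(ph) & ~np.isnan(v)
        if ok.sum() < 5:
            ev.phenotype_correlations[name] = {"rho": math.nan, "p": math.nan,
                                               "ci_low": math.nan, "ci_high": math.nan,
                                               "n": int(ok.sum()), "degenerate": True}
            continue
        vv, pp = v[ok], ph[ok]
        if np.ptp(vv) == 0 or np.ptp(pp) == 0:
            ev.phenotype_correlations[name] = {"rho": math.nan, "p": math.nan,
                                               "ci_low": math.nan, "ci_high": math.nan,
                                               "n": int(ok.sum()), "degenerate": True}
            continue
        rho, p = stats.spearmanr(vv, pp)
        n = len(vv)
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = np.empty(n_boot)
        for b in range(n_boot):
            sb = idx[b]
            if np.ptp(vv[sb]) == 0 or np.ptp(pp[sb]) == 0:
                boots[b] = np.nan
            else:
                boots[b] = stats.spearmanr(vv[sb], pp[sb]).statistic
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
        ev.phenotype_correlations[name] = {
            "rho": float(rho), "p": float(p),
            "ci_low": float(lo), "ci_high": float(hi),
            "n": n, "degenerate": False,
        }
    return ev
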