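"""Per-cohort association, BH correction and random-effects pooling.

Each cohort is analysed with the simplest models honoring the two
classic views of a microbial feature: a linear model of log10 abundance
(abundance mode) and a logistic model of presence/absence (prevalence
mode), both with optional age/sex adjustment.  Cohort effects are pooled
per taxon with the DerSimonian-Laird random-effects estimator, corrected
by Benjamini-Hochberg within each (disease, mode) family, and taxa are
classified by the sign agreement of their significant pooled effects
across diseases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import MultiStudyDataset

Mode = Literal["abundance", "prevalence"]


@dataclass
class AssociationResult:
    taxon: str
    cohort: str
    mode: str
    effect: float
    se: float
    p: float
    q: float = math.nan
    estimable: bool = True


@dataclass
class PooledResult:
    taxon: str
    disease: str
    mode: str
    effect: float
    se: float
    tau_squared: float
    p: float
    q: float = math.nan
    n_cohorts: int = 0
    pooled: bool = True  # False when a single cohort passed through

    @property
    def direction(self) -> str:
        return "health-enriched" if self.effect < 0 else "disease-enriched"


@dataclass
class CrossDiseaseClassification:
    taxon: str
    significant_directions: dict[str, int]  # disease -> sign(-1 health / +1 disease)
    category: Optional[str]  # consistent-health | consistent-disease | context-dependent | None


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _ols_assoc(y: np.ndarray, X: np.ndarray) -> tuple[float, float, float]:
    """OLS of y on X (first non-intercept column = case indicator)."""
    import statsmodels.api as sm

    model = sm.OLS(y, X).fit()
    return float(model.params[1]), float(model.bse[1]), float(model.pvalues[1])


def _logit_assoc(y: np.ndarray, X: np.ndarray) -> tuple[float, float, float]:
    """Logistic regression of presence on X; ridge fallback on separation.

    When maximum likelihood diverges (perfect separation), a weakly
    L2-penalized fit provides finite, shrunken estimates with a
    Wald-type p from the penalized information matrix.
    """
    import statsmodels.api as sm

    try:
        with np.errstate(all="ignore"):
            model = sm.Logit(y, X).fit(disp=0, maxiter=200)
        se = float(model.bse[1])
        if np.isfinite(se) and se < 50 and np.isfinite(model.params[1]):
            return float(model.params[1]), se, float(model.pvalues[1])
    except Exception:
        pass
    # bias-reduction-style fallback: small ridge penalty on all coefficients
    alpha = 1.0
    with np.errstate(all="ignore"):
        model = sm.Logit(y, X).fit_regularized(
            disp=0, alpha=alpha, L1_wt=0.0, maxiter=500
        )
    beta = np.asarray(model.params, dtype=float)
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    W = mu * (1 - mu)
    info = X.T @ (X * W[:, None]) + 2 * alpha * np.eye(X.shape[1])
    cov = np.linalg.inv(info)
    se = float(np.sqrt(cov[1, 1]))
    z = beta[1] / se
    return float(beta[1]), se, float(2 * stats.norm.sf(abs(z)))


def cohort_association(
    ds: MultiStudyDataset,
    mode: Mode = "abundance",
    covariates: Sequence[str] = (),
    pseudocount: float = 1e-5,
    presence_threshold: float = 0.0,
) -> list[AssociationResult]:
    """Case-vs-control association for every taxon in a single cohort.

    abundance mode: OLS of ``log10(abundance + pseudocount)`` on the
    case indicator (+ covariates); effect is the case coefficient, i.e.
    the adjusted mean log10 difference case - control.  prevalence mode:
    logistic model of presence; effect is the case log-odds ratio.
    Records missing a requested covariate are dropped for that model.
    Taxa with constant presence in prevalence mode are flagged
    not-estimable.  BH adjustment is applied across taxa within the call.
    """
    studies = set(s.study_id for s in ds.samples)
    cohort = next(iter(studies)) if len(studies) == 1 else "+".join(sorted(studies))
    meta = ds.metadata_frame()
    y_case = ds.labels().astype(float)

    cov_cols = []
    keep = np.ones(len(ds.samples), dtype=bool)
    for c in covariates:
        if c not in meta.columns:
            raise ValueError(f"unknown covariate {c!r}")
        col = meta[c]
        if c == "sex":
            col = col.map({"M": 0.0, "F": 1.0})
        col = pd.to_numeric(col, errors="coerce").to_numpy()
        keep &= ~np.isnan(col)
        cov_cols.append(col)
    if keep.sum() < 6:
        raise ValueError("fewer than 6 samples after covariate missingness removal")
    y_case = y_case[keep]
    if min((y_case == 1).sum(), (y_case == 0).sum()) < 3:
        raise ValueError("need >= 3 cases and >= 3 controls")

    X = np.column_stack(
        [np.ones(keep.sum()), y_case] + [c[keep] for c in cov_cols]
    )
    values = ds.profiles.values[keep]

    results: list[AssociationResult] = []
    for j, taxon in enumerate(ds.taxon_ids):
        v = values[:, j]
        if mode == "abundance":
            eff, se, p = _ols_assoc(np.log10(v + pseudocount), X)
            results.append(AssociationResult(taxon, cohort, mode, eff, se, p))
        elif mode == "prevalence":
            pres = (v > presence_threshold).astype(float)
            if pres.min() == pres.max():
                results.append(
                    AssociationResult(
                        taxon, cohort, mode, math.nan, math.nan, math.nan, estimable=False
                    )
                )
                continue
            eff, se, p = _logit_assoc(pres, X)
            results.append(AssociationResult(taxon, cohort, mode, eff, se, p))
        else:
            raise ValueError(f"unknown mode {mode!r}")

    est = [r for r in results if r.estimable]
    q = bh_adjust([r.p for r in est])
    for r, qv in zip(est, q):
        r.q = float(qv)
    return results


def random_effects_pool(
    effects: Sequence[float],
    ses: Sequence[float],
    taxon: str = "",
    disease: str = "",
    mode: str = "",
) -> PooledResult:
    """DerSimonian-Laird random-effects pooling of per-cohort effects.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with
    fixed-effect weights w = 1/se^2; pooled estimate and standard error
    use weights 1/(se^2 + tau^2); two-sided normal p.
    A single cohort passes through unpooled (flagged).
    """
    e = np.asarray(effects, dtype=float)
    s = np.asarray(ses, dtype=float)
    if e.shape != s.shape or e.ndim != 1 or e.size == 0:
        raise ValueError("effects and ses must be equal-length 1-D")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    k = e.size
    if k == 1:
        p = float(2 * stats.norm.sf(abs(e[0] / s[0])))
        return PooledResult(taxon, disease, mode, float(e[0]), float(s[0]), 0.0, p, n_cohorts=1, pooled=False)
    w = 1.0 / s**2
    e_bar = (w * e).sum() / w.sum()
    Q = (w * (e - e_bar) ** 2).sum()
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (s**2 + tau2)
    pooled = (w_star * e).sum() / w_star.sum()
    se_pooled = w_star.sum() ** -0.5
    p = float(2 * stats.norm.sf(abs(pooled / se_pooled)))
    return PooledResult(
        taxon, disease, mode, float(pooled), float(se_pooled), float(tau2), p, n_cohorts=k
    )


def pool_associations(
    per_cohort: Sequence[AssociationResult],
    disease: str,
    mode: Mode = "abundance",
) -> list[PooledResult]:
    """Pool per-cohort association results taxon by taxon, then BH-adjust.

    Not-estimable cohort results are excluded from pooling; BH is
    applied within this (disease, mode) family.
    """
    by_taxon: dict[str, list[AssociationResult]] = {}
    for r in per_cohort:
        if r.mode == mode and r.estimable:
            by_taxon.setdefault(r.taxon, []).append(r)
    pooled = [
        random_effects_pool(
            [r.effect for r in rs], [r.se for r in rs], taxon=t, disease=disease, mode=mode
        )
        for t, rs in by_taxon.items()
    ]
    q = bh_adjust([r.p for r in pooled])
    for r, qv in zip(pooled, q):
        r.q = float(qv)
    return pooled


def classify_directions(
    pooled: Sequence[PooledResult], q_threshold: float = 0.1
) -> list[CrossDiseaseClassification]:
    """Classify taxa by sign agreement of significant per-disease effects.

    ``consistent-health``: every significant pooled effect negative
    (lower in cases); ``consistent-disease``: every one positive;
    ``context-dependent``: both signs occur.  Taxa significant nowhere
    get category ``None``.
    """
    by_taxon: dict[str, dict[str, int]] = {}
    for r in pooled:
        by_taxon.setdefault(r.taxon, {})
        if not math.isnan(r.q) and r.q < q_threshold:
            sign = -1 if r.effect < 0 else 1
            by_taxon[r.taxon][r.disease] = sign
    out = []
    for taxon, dirs in by_taxon.items():
        signs = set(dirs.values())
        if not signs:
            cat = None
        elif signs == {-1}:
            cat = "consistent-health"
        elif signs == {1}:
            cat = "consistent-disease"
        else:
            cat = "context-dependent"
        out.append(CrossDiseaseClassification(taxon, dirs, cat))
    return out
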