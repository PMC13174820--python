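"""Statistical battery for glymphatic cohort analyses.

Covers the association and group-difference analyses applied to the subject
feature tables: covariate-adjusted standardized-β regression with
Benjamini-Hochberg FDR control, ANCOVA with Tukey HSD post hoc tests and a
nonparametric rank-ANCOVA/Wilcoxon fallback, a stratified cross-validation
classification harness with pairwise DeLong AUC comparisons, serial
two-mediator bootstrap mediation with bias-corrected CIs, and the phenotype
derivations (mean arterial pressure, tracer-specific amyloid positivity).

Ordinary model fits delegate to statsmodels/scikit-learn; the DeLong test,
the CV pooling harness and the serial-mediation bootstrap are implemented
here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError

__all__ = [
    "RegressionResult",
    "AncovaResult",
    "AucComparison",
    "CvResult",
    "MediationResult",
    "standardized_beta",
    "bh_fdr",
    "ancova",
    "tukey_hsd",
    "rank_ancova_wilcoxon",
    "cv_classify",
    "delong_test",
    "serial_mediation",
    "derive_map",
    "amyloid_positivity",
    "AMYLOID_THRESHOLDS",
]


# --------------------------------------------------------------------------
# Regression with standardized coefficients + FDR
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    beta: float          # standardized coefficient of the predictor
    t: float
    p: float
    p_adjusted: float | None
    n: int
    covariates: tuple[str, ...]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise InputError("cannot z-score a constant variable")
    return (x - x.mean()) / sd


def standardized_beta(
    outcome: str,
    predictor: str,
    covariates: Sequence[str],
    data: pd.DataFrame,
) -> RegressionResult:
    """OLS of z-scored outcome on z-scored predictor plus raw covariates.

    The reported β is the predictor's coefficient on the standardized scale;
    p is the two-sided t-test of that coefficient.
    """
    import statsmodels.api as sm

    cols = [outcome, predictor, *covariates]
    df = data[cols].dropna()
    n = df.shape[0]
    if n <= len(covariates) + 3:
        raise InputError(f"too few complete cases (n={n}) for {len(covariates)} covariates")
    y = _zscore(df[outcome].to_numpy(dtype=float))
    x = _zscore(df[predictor].to_numpy(dtype=float))
    X = np.column_stack([x] + [df[c].to_numpy(dtype=float) for c in covariates])
    X = sm.add_constant(X, prepend=False)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InputError("rank-deficient design (collinear covariates?)")
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        beta=float(fit.params[0]),
        t=float(fit.tvalues[0]),
        p=float(fit.pvalues[0]),
        p_adjusted=None,
        n=n,
        covariates=tuple(covariates),
    )


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    FDR families are the caller's responsibility: pass one family (e.g. one
    anatomical compartment) per call.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_results(results: Sequence[RegressionResult]) -> list[RegressionResult]:
    """Apply BH-FDR across one family of regression results."""
    adj = bh_fdr([r.p for r in results])
    return [
        RegressionResult(beta=r.beta, t=r.t, p=r.p, p_adjusted=float(a),
                         n=r.n, covariates=r.covariates)
        for r, a in zip(results, adj)
    ]


# --------------------------------------------------------------------------
# ANCOVA + Tukey HSD + nonparametric fallback
# --------------------------------------------------------------------------

@dataclass
class AncovaResult:
    F: float
    p: float
    df_group: int
    df_resid: int
    adjusted_means: dict[str, float]
    groups: tuple[str, ...]
    group_sizes: dict[str, int]
    mse: float
    # internals for Tukey: coefficient estimates/covariance of group dummies
    _group_coefs: np.ndarray = field(repr=False, default=None)
    _group_cov: np.ndarray = field(repr=False, default=None)


def _ancova_design(df: pd.DataFrame, outcome: str, group: str,
                   covariates: Sequence[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    levels = sorted(df[group].astype(str).unique())
    y = df[outcome].to_numpy(dtype=float)
    cols = [np.ones(df.shape[0])]
    for lev in levels[1:]:  # reference = first level
        cols.append((df[group].astype(str) == lev).to_numpy(dtype=float))
    for c in covariates:
        cols.append(df[c].to_numpy(dtype=float))
    return y, np.column_stack(cols), levels


def ancova(
    outcome: str,
    group: str,
    covariates: Sequence[str],
    data: pd.DataFrame,
) -> AncovaResult:
    """F test of a group factor after covariate adjustment (nested OLS models).

    With no covariates this reduces exactly to one-way ANOVA.  Adjusted group
    means evaluate each group at the grand covariate means.
    """
    import statsmodels.api as sm

    df = data[[outcome, group, *covariates]].dropna()
    levels = sorted(df[group].astype(str).unique())
    if len(levels) < 2:
        raise InputError("need at least two groups")
    sizes = df.groupby(df[group].astype(str)).size().to_dict()
    if min(sizes.values()) < len(covariates) + 2:
        raise InputError("a group has too few observations for the covariates")
    y, X_full, levels = _ancova_design(df, outcome, group, covariates)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise InputError("singular ANCOVA design")
    fit_full = sm.OLS(y, X_full).fit()
    # reduced model: drop the group dummies
    keep = [0] + list(range(len(levels), X_full.shape[1]))
    fit_red = sm.OLS(y, X_full[:, keep]).fit()
    df_group = len(levels) - 1
    df_resid = int(fit_full.df_resid)
    F = float(((fit_red.ssr - fit_full.ssr) / df_group) / (fit_full.ssr / df_resid))
    p = float(sps.f.sf(F, df_group, df_resid))

    xbar = [df[c].to_numpy(dtype=float).mean() for c in covariates]
    base = float(fit_full.params[0] + np.dot(fit_full.params[len(levels):], xbar))
    adjusted = {levels[0]: base}
    for i, lev in enumerate(levels[1:], start=1):
        adjusted[lev] = base + float(fit_full.params[i])
    cov = fit_full.cov_params()
    idx = list(range(len(levels)))  # intercept + dummies
    return AncovaResult(
        F=F, p=p, df_group=df_group, df_resid=df_resid,
        adjusted_means=adjusted, groups=tuple(levels), group_sizes=sizes,
        mse=float(fit_full.ssr / df_resid),
        _group_coefs=np.asarray(fit_full.params[:len(levels)]),
        _group_cov=np.asarray(cov)[np.ix_(idx, idx)],
    )


def tukey_hsd(fitted: AncovaResult) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons of covariate-adjusted group means.

    Uses the studentized-range distribution with q = sqrt(2)|diff|/se(diff),
    k groups and the ANCOVA residual df; with k = 2 this equals the pooled
    t-test p-value.
    """
    levels = fitted.groups
    k = len(levels)
    if k < 2:
        raise InputError("Tukey HSD needs at least two groups")
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = fitted.adjusted_means[levels[j]] - fitted.adjusted_means[levels[i]]
            # var(beta_j - beta_i); reference level has coefficient 0 = index 0's dummy absent
            v = np.zeros(k)
            if j > 0:
                v[j] = 1.0
            if i > 0:
                v[i] = -1.0
            se = float(np.sqrt(v @ fitted._group_cov @ v))
            if se == 0:
                q, p = np.inf, 0.0
            else:
                q = np.sqrt(2.0) * abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, fitted.df_resid))
            rows.append({"group_a": levels[i], "group_b": levels[j],
                         "diff": diff, "se": se, "q": q, "p_adj": min(p, 1.0)})
    return pd.DataFrame(rows)


def rank_ancova_wilcoxon(
    outcome: str,
    group: str,
    covariates: Sequence[str],
    data: pd.DataFrame,
    alternative: str = "two-sided",
) -> tuple[AncovaResult, pd.DataFrame]:
    """Nonparametric fallback: ANCOVA on rank-transformed outcome plus
    pairwise Wilcoxon rank-sum tests.

    The outcome is replaced by mid-ranks (ties averaged) before the ANCOVA,
    making the F test invariant to monotone transforms.  Pairwise tests use
    the exact Mann-Whitney null when samples are small and tie-free, else the
    tie-corrected normal approximation.
    """
    df = data[[outcome, group, *covariates]].dropna().copy()
    df["_ranked"] = sps.rankdata(df[outcome].to_numpy(dtype=float))
    res = ancova("_ranked", group, covariates, df)
    levels = res.groups
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a = df.loc[df[group].astype(str) == levels[i], outcome].to_numpy(dtype=float)
            b = df.loc[df[group].astype(str) == levels[j], outcome].to_numpy(dtype=float)
            stat, p = sps.mannwhitneyu(a, b, alternative=alternative, method="auto")
            rows.append({"group_a": levels[i], "group_b": levels[j],
                         "U": float(stat), "p": float(p)})
    return res, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Cross-validated classification + DeLong
# --------------------------------------------------------------------------

@dataclass
class CvResult:
    scores: np.ndarray       # pooled out-of-fold decision scores, subject order
    labels: np.ndarray
    auc: float
    model: str
    n_splits: int
    seed: int
    fold_of_subject: np.ndarray


def _make_estimator(model: str, seed: int):
    from sklearn.ensemble import GradientBoostingClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    if model == "logistic":
        est = LogisticRegression(max_iter=5000)
    elif model == "svm-linear":
        est = SVC(kernel="linear")
    elif model == "svm-rbf":
        est = SVC(kernel="rbf")
    elif model == "gboost":
        est = GradientBoostingClassifier(random_state=seed)
    elif model == "xgboost":
        from xgboost import XGBClassifier

        est = XGBClassifier(random_state=seed, eval_metric="logloss")
    else:
        raise InputError(f"unknown model spec {model!r}")
    return make_pipeline(StandardScaler(), est)


def cv_classify(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray | pd.Series,
    model: str = "logistic",
    n_splits: int = 10,
    seed: int = 42,
) -> CvResult:
    """Stratified k-fold CV with pooled out-of-fold decision scores.

    One ROC/AUC is computed over the concatenated out-of-fold scores (kept in
    subject order so paired DeLong tests between models line up).  Fold
    assignment is deterministic given the seed.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int).ravel()
    classes = np.unique(y)
    if classes.size != 2:
        raise InputError(f"need exactly two classes, got {classes.tolist()}")
    counts = np.bincount(y)
    if counts.min() < n_splits:
        raise InputError("each class must have at least n_splits members")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores = np.empty(y.shape[0])
    fold_of = np.empty(y.shape[0], dtype=int)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        est = _make_estimator(model, seed)
        est.fit(X[tr], y[tr])
        if hasattr(est, "decision_function"):
            s = est.decision_function(X[te])
        else:
            s = est.predict_proba(X[te])[:, 1]
        scores[te] = s
        fold_of[te] = fold
    return CvResult(
        scores=scores, labels=y, auc=float(roc_auc_score(y, scores)),
        model=model, n_splits=n_splits, seed=seed, fold_of_subject=fold_of,
    )


@dataclass(frozen=True)
class AucComparison:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p: float
    degenerate: bool = False


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Midrank AUC and DeLong structural components V10 (pos), V01 (neg)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_s = np.concatenate([pos, neg])
    rk_all = sps.rankdata(all_s)
    rk_pos = sps.rankdata(pos)
    rk_neg = sps.rankdata(neg)
    auc = (rk_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rk_all[:m] - rk_pos) / n
    v01 = 1.0 - (rk_all[m:] - rk_neg) / m
    return float(auc), v10, v01


def delong_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
) -> AucComparison:
    """DeLong test for the difference of two correlated (paired) AUCs.

    Scores must be paired on the same subjects.  The AUC uses the midrank
    (Mann-Whitney) estimator; the variance of the difference comes from the
    empirical covariance of the DeLong structural components; p is two-sided
    normal.  A degenerate variance (e.g. identical scores) is flagged with
    p = 1.
    """
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    y = np.asarray(labels).astype(int).ravel()
    if not (a.shape == b.shape == y.shape):
        raise InputError("scores and labels must be paired (same length)")
    if np.unique(y).size != 2:
        raise InputError("labels must contain both classes")
    auc_a, v10_a, v01_a = _delong_components(a, y)
    auc_b, v10_b, v01_b = _delong_components(b, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var <= 0 or not np.isfinite(var):
        return AucComparison(auc_a=auc_a, auc_b=auc_b, delta=delta,
                             z=0.0, p=1.0, degenerate=True)
    z = delta / np.sqrt(var)
    p = float(2 * sps.norm.sf(abs(z)))
    return AucComparison(auc_a=auc_a, auc_b=auc_b, delta=delta,
                         z=float(z), p=min(p, 1.0))


# --------------------------------------------------------------------------
# Serial mediation
# --------------------------------------------------------------------------

@dataclass
class MediationResult:
    """Serial two-mediator path model X -> M1 -> M2 -> Y.

    a1: X->M1; a2: M1->M2 (given X); a3: X->M2 direct; d1: M1->Y direct;
    b: M2->Y; c: total X->Y; c_prime: direct X->Y given both mediators.
    The serial indirect effect is a1*a2*b with a bias-corrected bootstrap CI.
    """

    a1: float
    a2: float
    a3: float
    d1: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n: int
    significant: bool
    standardized: bool
    boot_indirect: np.ndarray = field(repr=False, default=None)


def _ols_coef(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise InputError("collinear design in mediation fit")
    return coef


def _mediation_paths(x, m1, m2, yv, C):
    one = np.ones_like(x)
    X1 = np.column_stack([one, x, *C])                 # M1 ~ X
    X2 = np.column_stack([one, x, m1, *C])             # M2 ~ X + M1
    X3 = np.column_stack([one, x, m1, m2, *C])         # Y ~ X + M1 + M2
    X0 = np.column_stack([one, x, *C])                 # Y ~ X (total)
    a1 = _ols_coef(m1, X1)[1]
    c2 = _ols_coef(m2, X2)
    a3, a2 = c2[1], c2[2]
    c3 = _ols_coef(yv, X3)
    c_prime, d1, b = c3[1], c3[2], c3[3]
    c_tot = _ols_coef(yv, X0)[1]
    return a1, a2, a3, d1, b, c_tot, c_prime


def serial_mediation(
    X: str,
    M1: str,
    M2: str,
    Y: str,
    data: pd.DataFrame,
    covariates: Sequence[str] = (),
    n_boot: int = 5000,
    seed: int = 0,
    standardize: bool = False,
    alpha: float = 0.05,
) -> MediationResult:
    """Serial two-mediator mediation with case-resampling bootstrap.

    Three nested OLS fits (M1 ~ X; M2 ~ X + M1; Y ~ X + M1 + M2, each plus
    covariates) and the total-effect fit give the path coefficients; the
    serial indirect effect a1*a2*b gets a nonparametric bias-corrected (BC)
    percentile CI from ``n_boot`` case resamples.  Significance means the CI
    excludes zero.  ``standardize`` optionally z-scores all variables first.
    """
    cols = [X, M1, M2, Y, *covariates]
    df = data[cols].dropna()
    n = df.shape[0]
    n_params = 4 + len(covariates)
    if n < 10 * n_params:
        warnings.warn(f"n={n} below the recommended 10x parameters "
                      f"({10 * n_params})", stacklevel=2)
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is very small for a bootstrap CI",
                      stacklevel=2)
    arrs = {c: df[c].to_numpy(dtype=float) for c in cols}
    if standardize:
        arrs = {c: _zscore(v) for c, v in arrs.items()}
    x, m1, m2, yv = arrs[X], arrs[M1], arrs[M2], arrs[Y]
    C = [arrs[c] for c in covariates]

    a1, a2, a3, d1, b, c_tot, c_prime = _mediation_paths(x, m1, m2, yv, C)
    indirect = a1 * a2 * b

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        Cb = [c[idx] for c in C]
        try:
            ba1, ba2, _, _, bb, _, _ = _mediation_paths(
                x[idx], m1[idx], m2[idx], yv[idx], Cb)
            boot[i] = ba1 * ba2 * bb
        except InputError:
            boot[i] = np.nan
    boot = boot[np.isfinite(boot)]
    if boot.size < max(50, n_boot // 2):
        raise InputError("bootstrap failed on too many resamples")

    # bias-corrected percentile interval
    prop = np.mean(boot < indirect)
    prop = min(max(prop, 1.0 / (boot.size + 1)), 1.0 - 1.0 / (boot.size + 1))
    z0 = sps.norm.ppf(prop)
    za = sps.norm.ppf(alpha / 2)
    lo_q = sps.norm.cdf(2 * z0 + za)
    hi_q = sps.norm.cdf(2 * z0 - za)
    ci_low = float(np.quantile(boot, lo_q))
    ci_high = float(np.quantile(boot, hi_q))
    return MediationResult(
        a1=float(a1), a2=float(a2), a3=float(a3), d1=float(d1), b=float(b),
        c=float(c_tot), c_prime=float(c_prime), indirect=float(indirect),
        ci_low=ci_low, ci_high=ci_high, n_boot=n_boot, seed=seed, n=n,
        significant=bool(ci_low > 0 or ci_high < 0),
        standardized=standardize, boot_indirect=boot,
    )


# --------------------------------------------------------------------------
# Phenotype derivations
# --------------------------------------------------------------------------

def derive_map(systolic: float | np.ndarray, diastolic: float | np.ndarray):
    """Mean arterial pressure: MAP = (2 x diastolic + systolic) / 3 (mmHg)."""
    systolic = np.asarray(systolic, dtype=float)
    diastolic = np.asarray(diastolic, dtype=float)
    if np.any(systolic <= 0) or np.any(diastolic <= 0):
        raise InputError("blood pressures must be positive")
    out = (2.0 * diastolic + systolic) / 3.0
    return float(out) if out.ndim == 0 else out


# Tracer-specific composite SUVR cutoffs for amyloid-PET positivity
AMYLOID_THRESHOLDS: Mapping[str, float] = {"AV45": 1.11, "FBB": 1.478}


def amyloid_positivity(suvr: float, tracer: str) -> bool:
    """Amyloid positivity by strict SUVR threshold (AV45 > 1.11, FBB > 1.478)."""
    if tracer not in AMYLOID_THRESHOLDS:
        raise InputError(f"unknown tracer {tracer!r}; expected one of "
                         f"{sorted(AMYLOID_THRESHOLDS)}")
    return bool(float(suvr) > AMYLOID_THRESHOLDS[tracer])
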