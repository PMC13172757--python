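"""Diagnostic and correlation statistics over feature tables.

The centrepiece is the rank-based ROC machinery: the empirical AUC equals
the Mann–Whitney U statistic divided by n1·n2 (tie-aware on both sides),
its standard error and confidence interval come from DeLong's method, and
optimal cutoffs are chosen by the Youden index.  Group contrasts follow the
classical decision tree (Shapiro–Wilk normality, then Welch's t or
Mann–Whitney; chi-square for sex), binary logistic regression reports Wald
statistics and Cox–Snell / Nagelkerke pseudo-R², Spearman correlations get
percentile-bootstrap confidence intervals, and families of p-values are
FDR-adjusted with the Benjamini–Hochberg step-up rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import Logit, add_constant
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import InvalidArgumentError, UndefinedStatisticError

#: Exact Mann–Whitney p-values are used up to this many pairwise comparisons
#: (and only without ties); beyond it the tie- and continuity-corrected
#: normal approximation applies.
EXACT_MW_LIMIT = 400


# ---------------------------------------------------------------------------
# Rank statistics and ROC
# ---------------------------------------------------------------------------

def mann_whitney(x, y, two_tailed: bool = True) -> tuple[float, float]:
    """Mann–Whitney U for sample ``x``, with its two-tailed p-value.

    The statistic follows the convention in which U/(n1·n2) estimates
    P(X > Y) + ½·P(X = Y).  The p-value is exact (full enumeration) when
    n1·n2 ≤ 400 and the data contain no ties, and otherwise uses the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise InvalidArgumentError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size * y.size <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    alternative = "two-sided" if two_tailed else "greater"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def auc_from_u(U: float, n1: int, n2: int) -> float:
    """The AUC–U identity: empirical ROC AUC = U / (n1·n2)."""
    if n1 <= 0 or n2 <= 0:
        raise InvalidArgumentError("group sizes must be positive")
    if not (0 <= U <= n1 * n2):
        raise InvalidArgumentError(f"U={U} outside [0, {n1 * n2}]")
    return float(U) / (n1 * n2)


def _midranks(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """(AUC, variance of AUC) by DeLong's placement-value method."""
    m, n = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    rank_all = _midranks(combined)
    rank_pos = _midranks(pos)
    rank_neg = _midranks(neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rank_all[:m] - rank_pos) / n            # placements of positives
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m      # placements of negatives
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


@dataclass(frozen=True)
class ROCResult:
    auc: float
    se: float
    ci95: tuple[float, float]
    p_vs_half: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float


def youden_cutoff(scores, labels) -> tuple[float, float, float, float]:
    """Optimal cutoff by the Youden index (J = sensitivity + specificity − 1).

    Candidate cutoffs are the midpoints between adjacent sorted unique
    scores; the classification rule is "score ≥ cutoff → positive".  Ties
    in J break toward higher specificity, then toward the lower cutoff.
    Returns (cutoff, sensitivity, specificity, accuracy).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise InvalidArgumentError("both classes must be present")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise InvalidArgumentError("scores are constant; no cutoff exists")
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for c in cuts:
        sens = float(np.mean(pos >= c))
        spec = float(np.mean(neg < c))
        j = sens + spec - 1.0
        key = (j, spec, -c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, cutoff, sens, spec = best
    acc = (sens * pos.size + spec * neg.size) / scores.size
    return float(cutoff), sens, spec, float(acc)


def confusion_accuracy(sensitivity: float, specificity: float,
                       n_pos: int, n_neg: int) -> float:
    """Accuracy implied by printed sensitivity/specificity and group sizes.

    Rates are first converted back to integer confusion counts (reported
    rates are rounded versions of counts/n), then accuracy = (TP+TN)/N.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise InvalidArgumentError("rates must be in [0,1]")
    tp = round(sensitivity * n_pos)
    tn = round(specificity * n_neg)
    return (tp + tn) / (n_pos + n_neg)


def roc_analysis(scores, labels) -> ROCResult:
    """Empirical ROC of one feature against a binary group label.

    The AUC is the tie-aware rank statistic (identical to Mann–Whitney
    U / n1·n2 on the same data); SE and the 95% CI come from DeLong's
    method and the p-value tests AUC = 0.5 with a two-tailed DeLong z.
    The AUC is reported as-is for anti-discriminating features (values
    below 0.5 are not flipped).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise InvalidArgumentError("both classes must be present")
    auc, var = delong_variance(pos, neg)
    se = float(np.sqrt(max(var, 0.0)))
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2.0 * sps.norm.sf(abs(z)))
        ci = (max(auc - 1.959963984540054 * se, 0.0),
              min(auc + 1.959963984540054 * se, 1.0))
    else:
        p = 1.0 if auc == 0.5 else 0.0
        ci = (auc, auc)
    cutoff, sens, spec, acc = youden_cutoff(scores, labels)
    return ROCResult(auc=auc, se=se, ci95=ci, p_vs_half=p, cutoff=cutoff,
                     sensitivity=sens, specificity=spec, accuracy=acc)


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticResult:
    feature_names: tuple[str, ...]
    coefficients: np.ndarray          # includes intercept first
    wald_stats: np.ndarray
    p_values: np.ndarray
    odds_ratios: np.ndarray
    omnibus_chi2: float
    omnibus_df: int
    omnibus_p: float
    cox_snell_r2: float
    nagelkerke_r2: float
    pct_correct: float
    converged: bool
    diagnostic: str = ""


def logistic_fit(features: pd.DataFrame | np.ndarray, labels,
                 feature_names: list[str] | None = None) -> LogisticResult:
    """Maximum-likelihood binary logistic regression with the paper-style
    summary: Wald statistics, omnibus likelihood-ratio chi-square,
    Cox–Snell and Nagelkerke pseudo-R², and percent correctly classified
    at a probability threshold of 0.5.

    Predictors enter untransformed.  Non-convergence or perfect separation
    is reported through ``converged``/``diagnostic`` rather than raised.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(float)
    else:
        X = np.asarray(features, float)
        if X.ndim == 1:
            X = X[:, None]
        names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(labels, float)
    n, p = X.shape
    if n <= p + 1:
        raise InvalidArgumentError(f"need n > p+1 observations, got n={n}, p={p}")
    if np.any(np.ptp(X, axis=0) == 0):
        raise InvalidArgumentError("constant predictor column")

    Xc = add_constant(X, has_constant="add")
    converged, diagnostic = True, ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = Logit(y, Xc).fit(method="newton", maxiter=100, tol=1e-8, disp=False)
            converged = bool(fit.mle_retvals.get("converged", True))
            if not converged:
                diagnostic = "Newton iterations did not converge"
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            # refit with a tiny ridge via regularized path, flag the result
            fit = Logit(y, Xc).fit_regularized(alpha=1e-6, disp=False)
            converged = False
            diagnostic = f"perfect separation or singular Hessian: {exc}"

    beta = np.asarray(fit.params, float)
    se = np.asarray(fit.bse, float) if converged else np.full_like(beta, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = (beta / se) ** 2
    p_vals = sps.chi2.sf(wald, df=1)

    ll_full = float(fit.llf)
    ll_null = float(Logit(y, np.ones((n, 1))).fit(disp=False).llf)
    omnibus = 2.0 * (ll_full - ll_null)
    omnibus_p = float(sps.chi2.sf(omnibus, df=p))
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    nagelkerke = cox_snell / (1.0 - np.exp(2.0 * ll_null / n))
    pct_correct = float(np.mean((fit.predict(Xc) >= 0.5) == (y == 1)))

    with np.errstate(over="ignore"):  # huge coefficients map to inf odds
        odds = np.exp(beta)

    return LogisticResult(
        feature_names=tuple(names),
        coefficients=beta, wald_stats=wald, p_values=p_vals,
        odds_ratios=odds,
        omnibus_chi2=float(omnibus), omnibus_df=p, omnibus_p=omnibus_p,
        cox_snell_r2=float(cox_snell), nagelkerke_r2=float(nagelkerke),
        pct_correct=pct_correct, converged=converged, diagnostic=diagnostic,
    )


# ---------------------------------------------------------------------------
# Correlation and multiplicity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    ci95: tuple[float, float]
    q: float = float("nan")
    n: int = 0


def spearman_bootstrap(x, y, n_boot: int = 1000, seed: int = 0) -> CorrelationResult:
    """Spearman's rank correlation with a percentile-bootstrap 95% CI.

    rho is the Pearson correlation of average (tie-aware) ranks; the
    p-value uses the t approximation.  The CI resamples (x, y) pairs with
    replacement ``n_boot`` times under a seeded generator; degenerate
    resamples (constant x or y) are skipped.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 5:
        raise InvalidArgumentError(f"need at least 5 paired observations, got {n}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise UndefinedStatisticError("correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = np.full(n_boot, np.nan)
    for b in range(n_boot):
        xb, yb = x[idx[b]], y[idx[b]]
        if np.unique(xb).size < 2 or np.unique(yb).size < 2:
            continue
        boots[b] = sps.spearmanr(xb, yb).statistic
    ok = np.isfinite(boots)
    lo, hi = np.percentile(boots[ok], [2.5, 97.5]) if ok.any() else (np.nan, np.nan)
    return CorrelationResult(rho=float(rho), p=float(p), ci95=(float(lo), float(hi)), n=n)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidArgumentError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Group comparisons and SBR
# ---------------------------------------------------------------------------

def group_compare_suite(cohort: pd.DataFrame, group_col: str = "group",
                        variables: list[str] | None = None,
                        sex_col: str | None = None,
                        normality_alpha: float = 0.05) -> pd.DataFrame:
    """Two-group comparison table with test selection by normality.

    Each continuous variable is Shapiro–Wilk-tested within both groups;
    when both pass (p > alpha) a Welch t-test is used, otherwise
    Mann–Whitney.  An optional categorical sex column gets a (Pearson,
    uncorrected) chi-square test.  All tests are two-tailed and the whole
    family is BH-adjusted.  Variables degenerate in either group are
    skipped with a note row.
    """
    groups = cohort[group_col].dropna().unique()
    if len(groups) != 2:
        raise InvalidArgumentError(f"exactly two groups required, got {list(groups)}")
    g1 = cohort[cohort[group_col] == groups[0]]
    g2 = cohort[cohort[group_col] == groups[1]]
    if variables is None:
        variables = [c for c in cohort.columns
                     if c not in (group_col, sex_col)
                     and pd.api.types.is_numeric_dtype(cohort[c])]
    rows = []
    for var in variables:
        a = g1[var].dropna().to_numpy(float)
        b = g2[var].dropna().to_numpy(float)
        if a.size < 3 or b.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
            rows.append({"variable": var, "test": "skipped", "statistic": np.nan,
                         "p": np.nan, "note": "degenerate or too small"})
            continue
        normal = (sps.shapiro(a).pvalue > normality_alpha
                  and sps.shapiro(b).pvalue > normality_alpha)
        if normal:
            res = sps.ttest_ind(a, b, equal_var=False)
            rows.append({"variable": var, "test": "welch_t",
                         "statistic": float(res.statistic), "p": float(res.pvalue),
                         "note": ""})
        else:
            u, p = mann_whitney(a, b)
            rows.append({"variable": var, "test": "mann_whitney",
                         "statistic": u, "p": p, "note": ""})
    if sex_col is not None:
        table = pd.crosstab(cohort[group_col], cohort[sex_col])
        chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
        rows.append({"variable": sex_col, "test": "chi_square",
                     "statistic": float(chi2), "p": float(p), "note": f"df={dof}"})
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out


def compute_sbr(roi_mean: float, background_mean: float) -> float:
    """Striatal binding ratio: (ROI uptake − background) / background."""
    if background_mean <= 0:
        raise InvalidArgumentError("background uptake must be positive")
    return (roi_mean - background_mean) / background_mean


def log_sbr(sbr: float) -> float:
    """Natural log of a positive SBR (for mixed-model style analyses)."""
    if sbr <= 0:
        raise InvalidArgumentError("log(SBR) defined only for SBR > 0")
    return float(np.log(sbr))
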