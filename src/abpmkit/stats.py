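"""Cohort statistics: group comparisons, logistic regression, ROC, agreement.

Implements the workflow used to relate ABPM-derived indices to organ
damage in a two-group cohort:

* group comparisons with a Kolmogorov-Smirnov normality gate choosing
  between Student's t and Mann-Whitney U (chi-square for categoricals);
* closed-form 2x2 odds ratios with Wald confidence limits;
* univariable logistic screening (p < 0.25 rule) followed by a
  multivariable model with Hosmer-Lemeshow calibration, Nagelkerke R²
  and collinearity / influence diagnostics;
* ROC analysis with the rank (Mann-Whitney) AUC, DeLong confidence
  interval and the Youden-optimal cut-off;
* Cohen's kappa for inter-rater agreement.

Numeric predictors are z-standardised (whole-sample mean/SD) before
logistic fits, so odds ratios for continuous variables are per SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "LogitResult",
    "RocResult",
    "DiagnosticsResult",
    "SeparationError",
    "compare_groups",
    "odds_ratio_2x2",
    "fit_univariable",
    "select_predictors",
    "fit_multivariable",
    "collinearity_diagnostics",
    "roc_analysis",
    "cohens_kappa",
    "hosmer_lemeshow",
    "nagelkerke_r2",
]

#: z for a 95 % two-sided Wald interval, at the precision used throughout.
Z_95 = 1.959964


class SeparationError(RuntimeError):
    """Raised when a logistic fit is abandoned due to (quasi-)separation."""


@dataclass(frozen=True)
class ComparisonResult:
    """One variable's two-group comparison."""

    variable: str
    test_used: str  # t | mann_whitney | chi_square
    summary_a: str
    summary_b: str
    p_value: float


@dataclass(frozen=True)
class LogitResult:
    """Logistic-regression output: per-variable ORs plus model-level fit."""

    table: pd.DataFrame  # columns: variable, odds_ratio, ci_low, ci_high, p_value
    hosmer_lemeshow_p: float | None
    nagelkerke_r2: float
    included_variables: tuple[str, ...]
    n: int


@dataclass(frozen=True)
class RocResult:
    """ROC summary for one score against a binary outcome."""

    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    cutoff: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class DiagnosticsResult:
    """Collinearity and influence diagnostics for a predictor set."""

    pearson_r_max: float
    tolerance_min: float
    vif_max: float
    condition_number: float
    std_residual_range: tuple[float, float] | None
    cooks_distance_max: float | None
    vif: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# group comparisons


def _is_categorical(series: pd.Series) -> bool:
    if series.dtype == bool or series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        return True
    return series.dropna().nunique() <= 2


def _ks_normal(x: np.ndarray, alpha: float = 0.05, lilliefors: bool = False) -> bool:
    """Normality gate: one-sample KS against the fitted normal."""
    if np.std(x, ddof=1) == 0:
        return False
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        p = _lf(x, dist="norm")[1]
    else:
        p = sps.kstest(x, "norm", args=(np.mean(x), np.std(x, ddof=1))).pvalue
    return p > alpha


def compare_groups(
    cohort: pd.DataFrame,
    group: str,
    variables: list[str] | None = None,
    alpha_normality: float = 0.05,
    lilliefors: bool = False,
) -> list[ComparisonResult]:
    """Compare every variable between the two levels of ``group``.

    Continuous variables pass a per-group Kolmogorov-Smirnov normality
    check: Student's t-test (and mean ± SD summaries) when both groups
    look normal, Mann-Whitney U (and median (IQR)) otherwise.
    Categorical variables use the chi-square test with n (%) summaries.
    """
    levels = sorted(cohort[group].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"group column {group!r} must have exactly two levels, got {levels}")
    a = cohort[cohort[group] == levels[0]]
    b = cohort[cohort[group] == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two subjects")
    if variables is None:
        variables = [c for c in cohort.columns if c != group]

    results = []
    for var in variables:
        xa = a[var].dropna()
        xb = b[var].dropna()
        if cohort[var].dropna().nunique() < 2:
            raise ValueError(f"variable {var!r} has zero variance")
        if _is_categorical(cohort[var]):
            table = pd.crosstab(cohort[group], cohort[var])
            chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
            cats = sorted(cohort[var].dropna().unique())
            pos = cats[-1]
            summ = [
                f"{(x == pos).sum()} ({100 * (x == pos).mean():.1f}%)" for x in (xa, xb)
            ]
            results.append(ComparisonResult(var, "chi_square", summ[0], summ[1], float(p)))
            continue
        xa_v, xb_v = xa.to_numpy(float), xb.to_numpy(float)
        if np.std(np.concatenate([xa_v, xb_v])) == 0:
            raise ValueError(f"variable {var!r} has zero variance")
        normal = _ks_normal(xa_v, alpha_normality, lilliefors) and _ks_normal(
            xb_v, alpha_normality, lilliefors
        )
        if normal:
            p = float(sps.ttest_ind(xa_v, xb_v, equal_var=True).pvalue)
            summ = [f"{x.mean():.2f} ± {x.std(ddof=1):.2f}" for x in (xa_v, xb_v)]
            results.append(ComparisonResult(var, "t", summ[0], summ[1], p))
        else:
            p = float(sps.mannwhitneyu(xa_v, xb_v, alternative="two-sided").pvalue)
            summ = [
                f"{np.median(x):.2f} ({np.percentile(x, 25):.2f}-{np.percentile(x, 75):.2f})"
                for x in (xa_v, xb_v)
            ]
            results.append(ComparisonResult(var, "mann_whitney", summ[0], summ[1], p))
    return results


# ---------------------------------------------------------------------------
# odds ratios


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float, float]:
    """Cross-product odds ratio with the 95 % Wald log interval.

    For counts (a, b; c, d) = (exposed case, exposed control; unexposed
    case, unexposed control): OR = ad/bc, CI = exp(ln OR ± z·sqrt(1/a +
    1/b + 1/c + 1/d)).  Zero cells get the Haldane-Anscombe 0.5
    correction to every cell (flagged with a warning).
    """
    counts = np.array([a, b, c, d], dtype=float)
    if (counts < 0).any():
        raise ValueError("cell counts must be non-negative")
    if counts[0] + counts[1] == 0 or counts[2] + counts[3] == 0 or counts[0] + counts[2] == 0 or counts[1] + counts[3] == 0:
        raise ValueError("degenerate 2x2 table: a zero row or column margin")
    if (counts == 0).any():
        logger.warning("zero cell in 2x2 table; applying Haldane-Anscombe 0.5 correction")
        counts = counts + 0.5
    a_, b_, c_, d_ = counts
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt((1 / counts).sum())
    return float(or_), float(np.exp(np.log(or_) - Z_95 * se)), float(np.exp(np.log(or_) + Z_95 * se))


# ---------------------------------------------------------------------------
# logistic regression


def _design(cohort: pd.DataFrame, variables: list[str], standardize: bool) -> pd.DataFrame:
    X = pd.DataFrame(index=cohort.index)
    for var in variables:
        col = cohort[var]
        if col.dtype == object or col.dtype == bool or isinstance(col.dtype, pd.CategoricalDtype):
            cats = sorted(col.dropna().unique())
            if len(cats) != 2:
                raise ValueError(f"categorical predictor {var!r} must be binary, got {cats}")
            X[var] = (col == cats[-1]).astype(float)
        else:
            x = col.astype(float)
            if standardize and x.nunique() > 2:
                X[var] = (x - x.mean()) / x.std(ddof=1)
            else:
                X[var] = x
    return X


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> sm.Logit:
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and numerical failures
        raise SeparationError(f"logistic fit failed ({exc}); check for separation") from exc
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 30:
        raise SeparationError(
            "logistic fit did not converge to finite coefficients; "
            "data are (quasi-)separated"
        )
    return res


def nagelkerke_r2(llf: float, llnull: float, n: int) -> float:
    """Nagelkerke's rescaled Cox-Snell pseudo-R²."""
    cox_snell = 1.0 - np.exp(2.0 * (llnull - llf) / n)
    max_cs = 1.0 - np.exp(2.0 * llnull / n)
    return float(cox_snell / max_cs)


def hosmer_lemeshow(y: np.ndarray, p: np.ndarray, groups: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow goodness-of-fit over equal-frequency risk groups.

    Returns (chi2, p) with ``groups - 2`` degrees of freedom.
    """
    order = np.argsort(p, kind="mergesort")
    chunks = np.array_split(order, groups)
    chi2 = 0.0
    for idx in chunks:
        if len(idx) == 0:
            continue
        obs = y[idx].sum()
        exp = p[idx].sum()
        n_g = len(idx)
        denom = exp * (1.0 - exp / n_g)
        if denom <= 0:
            continue
        chi2 += (obs - exp) ** 2 / denom
    return float(chi2), float(sps.chi2.sf(chi2, groups - 2))


def fit_univariable(
    cohort: pd.DataFrame, outcome: str, variable: str, standardize: bool = True
) -> LogitResult:
    """Single-predictor logistic regression with Wald OR, CI and p."""
    return fit_multivariable(cohort, outcome, [variable], standardize=standardize, hl_groups=None)


def fit_multivariable(
    cohort: pd.DataFrame,
    outcome: str,
    variables: list[str],
    standardize: bool = True,
    hl_groups: int | None = 10,
) -> LogitResult:
    """Joint logistic regression of a binary outcome on ``variables``.

    Numeric predictors are z-standardised on the whole sample, so their
    odds ratios are per SD.  Reports the per-variable Wald OR / 95 % CI
    / p, the Hosmer-Lemeshow calibration p (``hl_groups`` equal-
    frequency groups) and Nagelkerke R².  Separation and rank
    deficiency raise :class:`SeparationError` / ``ValueError``.
    """
    data = cohort[[outcome] + list(variables)].dropna()
    y = data[outcome].astype(float).to_numpy()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    X = _design(data, list(variables), standardize)
    if np.linalg.matrix_rank(sm.add_constant(X.to_numpy())) < X.shape[1] + 1:
        raise ValueError("design matrix is rank deficient")
    res = _fit_logit(y, X)
    params = res.params.drop("const")
    se = res.bse.drop("const")
    pvals = res.pvalues.drop("const")
    table = pd.DataFrame(
        {
            "variable": params.index,
            "odds_ratio": np.exp(params.to_numpy()),
            "ci_low": np.exp(params.to_numpy() - Z_95 * se.to_numpy()),
            "ci_high": np.exp(params.to_numpy() + Z_95 * se.to_numpy()),
            "p_value": pvals.to_numpy(),
        }
    ).reset_index(drop=True)
    hl_p = None
    if hl_groups is not None:
        _, hl_p = hosmer_lemeshow(y, res.predict(), hl_groups)
    return LogitResult(
        table=table,
        hosmer_lemeshow_p=hl_p,
        nagelkerke_r2=nagelkerke_r2(res.llf, res.llnull, len(y)),
        included_variables=tuple(variables),
        n=len(y),
    )


def select_predictors(
    univariable: dict[str, float] | list[tuple[str, float]],
    clinical_set: list[str] | tuple[str, ...] = (),
    threshold: float = 0.25,
) -> list[str]:
    """Screen predictors for the multivariable model.

    Keeps every variable with a univariable p below ``threshold`` and
    adds the clinically forced set, preserving input order.  An empty
    selection returns the clinical set with a warning.
    """
    items = list(univariable.items()) if isinstance(univariable, dict) else list(univariable)
    selected = [v for v, p in items if p < threshold]
    for v in clinical_set:
        if v not in selected:
            selected.append(v)
    if not selected:
        logger.warning("no predictor passed the p<%.2f screen; returning clinical set", threshold)
        return list(clinical_set)
    return selected


def collinearity_diagnostics(
    cohort: pd.DataFrame,
    variables: list[str],
    outcome: str | None = None,
    standardize: bool = True,
) -> DiagnosticsResult:
    """Multicollinearity and (optionally) influence diagnostics.

    Tolerance is 1 - R² of each predictor regressed on the others, VIF
    its reciprocal; the condition number is taken on the standardised
    design with intercept.  When ``outcome`` is given, standardised
    Pearson residuals and Cook's distances come from the logistic fit.
    Flags encode the screening rules |r| < 0.70, tolerance > 0.25,
    VIF < 4, condition number < 10, |residual| < 3.29, Cook < 0.5.
    """
    if len(variables) < 2:
        raise ValueError("diagnostics need at least two predictors")
    X = _design(cohort.dropna(subset=list(variables)), list(variables), standardize)
    if (X.std(ddof=0) == 0).any():
        raise ValueError("constant predictor column")
    corr = X.corr().to_numpy()
    r_max = float(np.max(np.abs(corr - np.eye(len(variables)))))

    vif = {}
    for var in variables:
        others = [v for v in variables if v != var]
        ols = sm.OLS(X[var], sm.add_constant(X[others], has_constant="add")).fit()
        r2 = min(ols.rsquared, 1 - 1e-12)
        vif[var] = 1.0 / (1.0 - r2)
    vif_max = max(vif.values())
    tol_min = 1.0 / vif_max

    Z = (X - X.mean()) / X.std(ddof=1)
    cond = float(np.linalg.cond(sm.add_constant(Z.to_numpy())))

    resid_range = None
    cooks_max = None
    if outcome is not None:
        data = cohort.dropna(subset=[outcome] + list(variables))
        y = data[outcome].astype(float).to_numpy()
        Xo = _design(data, list(variables), standardize)
        try:
            glm = sm.GLM(
                y, sm.add_constant(Xo, has_constant="add"), family=sm.families.Binomial()
            ).fit()
            infl = glm.get_influence()
            rp = infl.resid_studentized
            resid_range = (float(np.min(rp)), float(np.max(rp)))
            cooks_max = float(np.max(infl.cooks_distance[0]))
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("influence diagnostics unavailable (%s); model likely separated", exc)

    flags = {
        "pearson_ok": r_max < 0.70,
        "tolerance_ok": tol_min > 0.25,
        "vif_ok": vif_max < 4.0,
        "condition_ok": cond < 10.0,
    }
    if resid_range is not None:
        flags["residuals_ok"] = max(abs(resid_range[0]), abs(resid_range[1])) < 3.29
        flags["cooks_ok"] = cooks_max < 0.5
    return DiagnosticsResult(
        pearson_r_max=r_max,
        tolerance_min=float(tol_min),
        vif_max=float(vif_max),
        condition_number=cond,
        std_residual_range=resid_range,
        cooks_distance_max=cooks_max,
        vif=vif,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# ROC


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by midranks — identical to the normalised Mann-Whitney U."""
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = sps.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_se(scores: np.ndarray, labels: np.ndarray, auc: float) -> float:
    """DeLong standard error of the AUC via placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # V10[i]: fraction of negatives below positive i (ties count half)
    v10 = np.array([(np.sum(neg < x) + 0.5 * np.sum(neg == x)) / len(neg) for x in pos])
    v01 = np.array([(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / len(pos) for x in neg])
    s10 = np.var(v10, ddof=1) if len(pos) > 1 else 0.0
    s01 = np.var(v01, ddof=1) if len(neg) > 1 else 0.0
    return float(np.sqrt(s10 / len(pos) + s01 / len(neg)))


def roc_analysis(scores, labels) -> RocResult:
    """ROC analysis of a continuous score against a binary outcome.

    AUC by the rank (Mann-Whitney) method with a DeLong 95 % interval
    and a DeLong z-test against AUC = 0.5.  The reported cut-off is the
    midpoint threshold (score >= cutoff calls a case) maximising the
    Youden index J = sensitivity + specificity - 1, ties broken toward
    higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if set(np.unique(labels)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC analysis requires both classes present")

    auc = _rank_auc(scores, labels)
    se = _delong_se(scores, labels, auc)
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2 * sps.norm.sf(abs(z)))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    ci_low = float(np.clip(auc - Z_95 * se, 0.0, 1.0))
    ci_high = float(np.clip(auc + Z_95 * se, 0.0, 1.0))

    uniq = np.unique(scores)
    cuts = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    best = None
    for c in cuts:
        pred = scores >= c
        sens = np.sum(pred & (labels == 1)) / n1
        spec = np.sum(~pred & (labels == 0)) / n0
        j = sens + spec - 1.0
        key = (round(j, 12), round(spec, 12), c)
        if best is None or key > best[0]:
            best = (key, float(c), float(sens), float(spec))
    _, cutoff, sens, spec = best
    return RocResult(
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
    )


# ---------------------------------------------------------------------------
# agreement


def cohens_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa: chance-corrected agreement between two raters.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement p_e from
    the product of the two raters' marginal distributions.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if len(a) != len(b):
        raise ValueError("rating vectors must have equal length")
    if len(a) == 0:
        raise ValueError("empty rating vectors")
    cats = np.unique(np.concatenate([a, b]))
    n = len(a)
    p_o = np.mean(a == b)
    p_e = sum((np.mean(a == c)) * (np.mean(b == c)) for c in cats)
    if p_e >= 1.0:
        raise ValueError("kappa undefined: both raters use a single category")
    return float((p_o - p_e) / (1.0 - p_e))
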