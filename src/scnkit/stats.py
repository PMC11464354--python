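"""Group-level statistics: CI classification, volumetric ratios,
normality-routed univariate tests, covariate-adjusted logistic regression,
adjusted AUC comparison, and Benjamini-Hochberg FDR.

Test routing follows the study convention: each variable's per-group
normality is checked with the Shapiro-Wilk test; if both groups are
compatible with normality (p > 0.05) the groups are compared with an
unpaired two-tailed t-test, otherwise with the Mann-Whitney U test.
Categorical variables use the chi-square test.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

#: Education-dependent MMSE cutoffs: CI iff MMSE <= cutoff.
MMSE_CUTOFFS = {"illiterate": 19, "elementary": 22, "secondary": 26}


def classify_ci(mmse: float, education_level: str) -> str:
    """Classify a subject as CI/NCI from MMSE and education level."""
    if not 0 <= mmse <= 30:
        raise ValueError(f"mmse must be in [0, 30], got {mmse}")
    try:
        cutoff = MMSE_CUTOFFS[education_level]
    except KeyError:
        raise ValueError(
            f"unknown education level {education_level!r}; "
            f"expected one of {sorted(MMSE_CUTOFFS)}"
        ) from None
    return "CI" if mmse <= cutoff else "NCI"


def volume_ratios(volumes, etiv: float, percent: bool = True) -> pd.Series:
    """Volumes as ratios to eTIV (in percent by default).

    ``volumes`` maps names to mm^3 values. ``Left-X``/``Right-X`` pairs are
    summed into a single ``X`` entry before division; nonpositive volumes
    are rejected.
    """
    if etiv <= 0:
        raise ValueError(f"etiv must be positive, got {etiv}")
    volumes = dict(volumes)
    combined: dict[str, float] = {}
    for name, val in volumes.items():
        stem = name
        for side in ("Left-", "Right-"):
            if name.startswith(side):
                stem = name[len(side):]
        combined[stem] = combined.get(stem, 0.0) + float(val)
    bad = sorted(k for k, v in combined.items() if v <= 0)
    if bad:
        raise ValueError(f"nonpositive volumes: {bad}")
    scale = 100.0 if percent else 1.0
    return pd.Series({k: scale * v / etiv for k, v in combined.items()})


def subcortical_ratio_table(
    features: pd.DataFrame, subjects: pd.DataFrame, percent: bool = True
) -> pd.DataFrame:
    """Per-subject ratio-to-eTIV table for the bilateral subcortical volumes."""
    vol_cols = [c for c in features.columns if c.startswith(("Left-", "Right-"))]
    if not vol_cols:
        raise ValueError("feature table has no subcortical volume columns")
    rows = {}
    for sid in features.index:
        rows[sid] = volume_ratios(
            features.loc[sid, vol_cols], float(subjects.loc[sid, "etiv"]),
            percent=percent,
        )
    out = pd.DataFrame(rows).T
    out.index.name = "subject_id"
    return out


@dataclass
class TestResult:
    """Outcome of one univariate or model-based group comparison."""

    variable: str
    test: str  # t | mann_whitney | chi_square | linear_model_t
    statistic: float
    p_value: float
    group_summaries: dict[str, str] = field(default_factory=dict)
    p_adjusted: float | None = None


def _summary(values: np.ndarray, parametric: bool) -> str:
    if parametric:
        return f"{np.mean(values):.3g} ± {np.std(values, ddof=1):.3g}"
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.3g} ({q1:.3g}–{q3:.3g})"


def compare_variable(
    values,
    groups,
    variable: str = "",
    force_test: str | None = None,
) -> TestResult:
    """Compare one variable between two groups with normality routing.

    Continuous data: Shapiro-Wilk per group; t-test if both groups have
    p > 0.05, else Mann-Whitney U. Categorical data (or
    ``force_test="chi_square"``): chi-square on the contingency table.
    """
    values = pd.Series(list(values))
    groups = pd.Series(list(groups))
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")

    categorical = force_test == "chi_square" or not pd.api.types.is_numeric_dtype(values)
    if categorical:
        table = pd.crosstab(groups, values)
        chi2, p, _, _ = sps.chi2_contingency(table)
        summaries = {
            g: "/".join(str(c) for c in table.loc[g]) for g in labels
        }
        return TestResult(variable, "chi_square", float(chi2), float(p), summaries)

    values = pd.to_numeric(values)
    a = values[groups == labels[0]].to_numpy(float)
    b = values[groups == labels[1]].to_numpy(float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 observations")
    if force_test is None:
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise ValueError(
                f"variable {variable!r} is constant within a group; cannot "
                "route by normality (supply force_test)"
            )
        normal = sps.shapiro(a).pvalue > 0.05 and sps.shapiro(b).pvalue > 0.05
        test = "t" if normal else "mann_whitney"
    else:
        test = force_test
    if test == "t":
        stat, p = sps.ttest_ind(a, b, equal_var=True)
    elif test == "mann_whitney":
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {force_test!r}")
    parametric = test == "t"
    summaries = {labels[0]: _summary(a, parametric), labels[1]: _summary(b, parametric)}
    return TestResult(variable, test, float(stat), float(p), summaries)


@dataclass
class ORResult:
    """Covariate-adjusted logistic-regression result for one predictor."""

    predictor: str
    coef: float  # B, log odds ratio
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    covariates: tuple[str, ...]


def _logistic_design(
    data: pd.DataFrame, predictor: str, covariates: tuple[str, ...]
) -> pd.DataFrame:
    X = pd.DataFrame(index=data.index)
    for name in (predictor, *covariates):
        if name == "gender":
            X["gender"] = (data["gender"] == "M").astype(float)
        else:
            X[name] = pd.to_numeric(data[name])
    return sm.add_constant(X, has_constant="add")


def logistic_adjusted(
    data: pd.DataFrame,
    outcome,
    predictor: str,
    covariates: tuple[str, ...] = ("age", "gender", "duration"),
) -> ORResult:
    """Binary logistic regression of the outcome on predictor + covariates.

    Returns the predictor's coefficient B, odds ratio exp(B) and Wald 95%
    interval exp(B +/- 1.96 SE). Separation and non-convergence raise with
    an explicit diagnostic instead of returning silent coefficients.
    """
    y = pd.Series(outcome, index=data.index) if not isinstance(outcome, pd.Series) else outcome
    if y.dtype == object:
        lab = sorted(y.unique())
        if len(lab) != 2:
            raise ValueError(f"outcome must be binary, got labels {lab}")
        # CI (the event of interest) coded 1 when present
        positive = "CI" if "CI" in lab else lab[1]
        y = (y == positive).astype(float)
    y = y.astype(float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes")
    X = _logistic_design(data, predictor, covariates)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise ValueError(
            f"logistic regression for {predictor!r} failed ({err}); "
            "likely separation or collinearity"
        ) from err
    if not fit.mle_retvals.get("converged", False):
        raise ValueError(
            f"logistic regression for {predictor!r} did not converge; "
            "check for separation or extreme predictor scaling"
        )
    b = float(fit.params[predictor])
    se = float(fit.bse[predictor])
    return ORResult(
        predictor=predictor,
        coef=b,
        odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - 1.96 * se)),
        ci_high=float(np.exp(b + 1.96 * se)),
        p_value=float(fit.pvalues[predictor]),
        covariates=tuple(covariates),
    )


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_auc_metrics(
    auc: pd.DataFrame,
    subjects: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "gender"),
    fdr: bool = True,
) -> list[TestResult]:
    """Compare per-subject metric AUCs between groups, covariate-adjusted.

    Fits AUC ~ group + covariates (OLS) per metric; the reported statistic
    is the group coefficient's t (group coded CI=1, NCI=0, so negative t
    means lower in the CI group). FDR is applied across the metrics.
    """
    missing = sorted(set(auc.index) - set(subjects.index))
    if missing:
        raise ValueError(f"subjects missing for AUC rows: {missing}")
    subs = subjects.loc[auc.index]
    na = auc.index[auc.isna().any(axis=1)].tolist()
    if na:
        raise ValueError(f"missing AUC values for subjects: {na}")
    group = (subs["group"] == "CI").astype(float)
    X = pd.DataFrame({"group": group})
    for cov in covariates:
        if cov == "gender":
            X["gender"] = (subs["gender"] == "M").astype(float)
        else:
            X[cov] = pd.to_numeric(subs[cov])
    X = sm.add_constant(X, has_constant="add")
    results = []
    for metric in auc.columns:
        fit = sm.OLS(auc[metric].astype(float), X).fit()
        summaries = {
            g: _summary(auc.loc[subs["group"] == g, metric].to_numpy(float), True)
            for g in ("CI", "NCI")
        }
        results.append(
            TestResult(
                variable=str(metric),
                test="linear_model_t",
                statistic=float(fit.tvalues["group"]),
                p_value=float(fit.pvalues["group"]),
                group_summaries=summaries,
            )
        )
    if fdr and results:
        adj = fdr_correct([r.p_value for r in results])
        for r, pa in zip(results, adj):
            r.p_adjusted = float(pa)
    return results


#: demographic/clinical summary variables and their routing; None = Shapiro-Wilk routing.
_COHORT_VARIABLES: tuple[tuple[str, str | None], ...] = (
    ("age", None),
    ("gender", "chi_square"),
    ("duration", None),
    ("education_years", None),
    ("updrs_total", None),
    ("updrs_i", None),
    ("updrs_ii", None),
    ("updrs_iii", None),
    ("hy", None),
    ("mmse", None),
    ("nmss", None),
    ("hama", None),
    ("hamd", None),
    ("etiv", None),
)


def cohort_table(subjects: pd.DataFrame) -> pd.DataFrame:
    """Demographic/clinical summary with per-variable group comparisons.

    One row per variable with group summaries (mean +/- sd or median + IQR
    per the normality routing; counts for gender), the test used, its
    statistic and p-value. Requires at least one subject in each group.
    """
    counts = subjects["group"].value_counts()
    for g in ("CI", "NCI"):
        if counts.get(g, 0) == 0:
            raise ValueError(f"group {g!r} is empty")
    rows = []
    n = len(subjects)
    rows.append(
        {
            "variable": "n",
            "CI": f"{counts['CI']} ({100 * counts['CI'] / n:.1f})",
            "NCI": f"{counts['NCI']} ({100 * counts['NCI'] / n:.1f})",
            "test": "",
            "statistic": np.nan,
            "p": np.nan,
        }
    )
    for var, force in _COHORT_VARIABLES:
        if var not in subjects.columns or subjects[var].isna().all():
            continue
        res = compare_variable(
            subjects[var], subjects["group"], variable=var, force_test=force
        )
        rows.append(
            {
                "variable": var,
                "CI": res.group_summaries.get("CI", ""),
                "NCI": res.group_summaries.get("NCI", ""),
                "test": res.test,
                "statistic": res.statistic,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
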