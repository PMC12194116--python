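"""Dose-response statistics for quantitative-ultrasound feature tables.

The analysis stage mirrors the multi-phase plan used for dose-finding in
percutaneous electrolysis: a Spearman rank-correlation screen of every
feature against the applied current, per-feature simple linear regressions,
a backward-elimination multiple regression that yields the composite
Muscle_Electrolysis_Dose index (alias UZ_eDosis), segmentation of doses into
low / medium / high ranges, and Kruskal-Wallis group comparison with
Bonferroni-corrected Mann-Whitney post hocs.

The composite index is a fixed linear combination of the three retained
geometric features,

    dose_hat = b0 + b_area * A_Area + b_number * A_Number + b_perim * A_Perimeter

with default coefficients (0.542, -316.88, -2.678, 20.284) taken from the
reference multiple-regression fit; applying it to a new feature vector gives
an estimated equivalent galvanic dose in mA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "DoseModel",
    "OLSResult",
    "BackwardElimResult",
    "GroupComparison",
    "StatReport",
    "spearman_rho",
    "simple_regression",
    "multiple_regression_backward",
    "muscle_electrolysis_dose",
    "segment_dose_groups",
    "kruskal_wallis",
    "pairwise_mannwhitney_bonferroni",
    "run_full_analysis",
]

GROUP_ORDER = ("low", "medium", "high")
PAIRS = (("low", "medium"), ("low", "high"), ("medium", "high"))


@dataclass(frozen=True)
class DoseModel:
    """Composite dose-index coefficients (mA per feature unit)."""

    intercept: float = 0.542
    coef_area: float = -316.88  # mA per cm^2
    coef_number: float = -2.678  # mA per count
    coef_perimeter: float = 20.284  # mA per cm


@dataclass(frozen=True)
class OLSResult:
    """Simple-regression summary in the conventional reporting layout."""

    r: float
    r2: float
    se_estimate: float  # sqrt(RSS / (n - 2))
    f: float
    p: float
    beta: float  # standardized slope
    b: float  # raw slope
    intercept: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class BackwardElimResult:
    """Final model of a backward-elimination multiple regression."""

    predictors: tuple[str, ...]
    params: pd.Series  # includes 'const'
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    r: float
    r2: float
    r2_adj: float
    f: float
    f_p: float
    eliminated: tuple[str, ...]  # in removal order


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal-Wallis + Bonferroni-adjusted pairwise Mann-Whitney results."""

    n: int
    h: float
    df: int
    p: float
    pairwise_p: dict[tuple[str, str], float]  # Bonferroni-adjusted, capped at 1


@dataclass(frozen=True)
class StatReport:
    """Full analysis output: one table per phase plus the composite column."""

    correlations: pd.DataFrame  # feature x (rho, p)
    simple_ols: pd.DataFrame  # feature x OLS summary columns
    backward: BackwardElimResult
    composite: pd.Series  # UZ_eDosis per sample
    group_comparison: pd.DataFrame  # feature x KW + pairwise columns
    dose_groups: pd.Series


def spearman_rho(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def simple_regression(x, y) -> OLSResult:
    """Least-squares fit of y on x with the ANOVA-style summary statistics."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("regressor is constant")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    b = float(fit.params[1])
    r2 = float(fit.rsquared)
    sy = float(np.std(y, ddof=1))
    sx = float(np.std(x, ddof=1))
    beta = b * sx / sy if sy > 0 else 0.0
    ci = fit.conf_int(alpha=0.05)
    se_est = float(np.sqrt(fit.ssr / (n - 2)))
    return OLSResult(
        r=float(np.sqrt(r2)),
        r2=r2,
        se_estimate=se_est,
        f=float(fit.fvalue),
        p=float(fit.f_pvalue),
        beta=beta,
        b=b,
        intercept=float(fit.params[0]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        n=n,
    )


def multiple_regression_backward(
    X: pd.DataFrame, y, p_remove: float = 0.10
) -> BackwardElimResult:
    """Backward elimination by largest partial-F p-value.

    Starting from the full model, the predictor with the largest p >= p_remove
    is dropped and the model refit, until every remaining predictor has
    p < p_remove.  For a single added/removed predictor the partial-F test is
    identical to the coefficient t-test, which is what is used here (matching
    the default removal rule of mainstream statistics packages).
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError("rank-deficient design matrix: collinear predictors")

    remaining = list(X.columns)
    eliminated: list[str] = []
    while True:
        fit = sm.OLS(y, sm.add_constant(X[remaining])).fit()
        pvals = fit.pvalues.drop("const")
        worst = pvals.idxmax()
        if len(remaining) > 1 and pvals[worst] >= p_remove:
            remaining.remove(worst)
            eliminated.append(worst)
            continue
        if len(remaining) == 1 and pvals[worst] >= p_remove and p_remove < 1.0:
            # even a single remaining predictor can be non-significant; keep it
            # in the report rather than returning an intercept-only model
            pass
        break

    return BackwardElimResult(
        predictors=tuple(remaining),
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        conf_int=fit.conf_int(alpha=0.05),
        r=float(np.sqrt(fit.rsquared)),
        r2=float(fit.rsquared),
        r2_adj=float(fit.rsquared_adj),
        f=float(fit.fvalue),
        f_p=float(fit.f_pvalue),
        eliminated=tuple(eliminated),
    )


def muscle_electrolysis_dose(
    a_area: float | np.ndarray,
    a_number: float | np.ndarray,
    a_perimeter: float | np.ndarray,
    model: DoseModel | None = None,
):
    """Composite galvanic-dose index (mA) from the three geometric features."""
    m = model or DoseModel()
    return (
        m.intercept
        + m.coef_area * np.asarray(a_area, dtype=float)
        + m.coef_number * np.asarray(a_number, dtype=float)
        + m.coef_perimeter * np.asarray(a_perimeter, dtype=float)
    )


def segment_dose_groups(doses, boundaries: tuple[float, float] = (1.0, 4.0)) -> pd.Series:
    """Label doses as low [0, b1], medium (b1, b2], high (b2, inf).

    The default boundaries (1, 4 mA) follow the dose ranges where minimal,
    progressive, and saturating responses are observed.
    """
    d = np.asarray(doses, dtype=float)
    if np.any(d < 0):
        raise ValueError("doses must be non-negative")
    b1, b2 = boundaries
    labels = np.where(d <= b1, "low", np.where(d <= b2, "medium", "high"))
    return pd.Series(pd.Categorical(labels, categories=list(GROUP_ORDER), ordered=True))


def kruskal_wallis(values, groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square asymptotic p.

    All-identical observations have zero rank variance; H is defined as 0
    (p = 1) in that case instead of the indeterminate tie-corrected form.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    samples = [values[groups == g] for g in labels]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need at least 2 non-empty groups")
    df = len(samples) - 1
    if np.ptp(values) == 0:
        return 0.0, df, 1.0
    h, p = sps.kruskal(*samples)
    return float(h), df, float(p)


def pairwise_mannwhitney_bonferroni(
    values, groups, n_comparisons: int = 3
) -> dict[tuple[str, str], float]:
    """Two-tailed Mann-Whitney U per group pair, Bonferroni-adjusted.

    The p-value uses the tie-corrected normal approximation without
    continuity correction; the adjusted value is min(1, 3 * p).  Identical
    groups (zero-variance case) are reported as p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    present = [g for g in GROUP_ORDER if np.any(groups == g)]
    if len(present) != 3:
        raise ValueError("need exactly 3 non-empty groups (low, medium, high)")
    out: dict[tuple[str, str], float] = {}
    for a, b in PAIRS:
        xa = values[groups == a]
        xb = values[groups == b]
        if np.ptp(np.concatenate([xa, xb])) == 0:
            raw = 1.0
        else:
            _, raw = sps.mannwhitneyu(
                xa, xb, alternative="two-sided", use_continuity=False,
                method="asymptotic",
            )
        out[(a, b)] = min(1.0, float(3 * raw))
    return out


#: feature columns expected by run_full_analysis, in reporting order
A_COLUMNS = (
    "A_Number", "A_Area", "A_Perimeter", "A_Convexity",
    "A_Homogeneity", "A_Contrast", "A_ASM",
)
B_COLUMNS = (
    "B_GLCM_Contrast", "B_GLCM_SumAverage", "B_GLCM_SoSVariance",
    "B_GLCM_DVariance", "B_GLCM_Correlation", "B_GLCM_IDMoment",
    "B_GLDS_Homogeneity", "B_GLDS_Contrast", "B_GLDS_ASM",
    "B_GLDS_Entropy", "B_GLDS_Mean", "B_haar_mean", "B_haar_variance",
)


def run_full_analysis(
    feature_table: pd.DataFrame,
    dose_column: str = "dose_mA",
    boundaries: tuple[float, float] = (1.0, 4.0),
    p_remove: float = 0.10,
    dose_model: DoseModel | None = None,
) -> StatReport:
    """Run the complete multi-phase dose-response analysis on a feature table.

    Phases: Spearman screen of every feature against dose; per-feature simple
    OLS (skipping features that are constant across the table); backward
    elimination on (A_Area, A_Number, A_Perimeter); the composite UZ_eDosis
    column evaluated with fixed coefficients; and low/medium/high group
    comparison (Kruskal-Wallis + Bonferroni-corrected pairwise Mann-Whitney)
    of every feature plus the composite.
    """
    df = feature_table.copy()
    required = {dose_column, "A_Area", "A_Number", "A_Perimeter"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise KeyError(f"feature table is missing columns: {missing}")
    dose = df[dose_column].to_numpy(dtype=float)
    features = [c for c in list(A_COLUMNS) + list(B_COLUMNS) if c in df.columns]

    corr_rows = {}
    ols_rows = {}
    for feat in features:
        vals = df[feat].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            corr_rows[feat] = {"rho": np.nan, "p": np.nan}
            continue
        rho, p = spearman_rho(dose, vals)
        corr_rows[feat] = {"rho": rho, "p": p}
        res = simple_regression(dose, vals)
        ols_rows[feat] = {
            "R": res.r, "R2": res.r2, "SE_estimate": res.se_estimate,
            "F": res.f, "p": res.p, "Beta": res.beta, "B": res.b,
            "CI95_low": res.ci_low, "CI95_high": res.ci_high,
        }
    correlations = pd.DataFrame.from_dict(corr_rows, orient="index")
    simple_ols = pd.DataFrame.from_dict(ols_rows, orient="index")

    backward = multiple_regression_backward(
        df[["A_Area", "A_Number", "A_Perimeter"]], dose, p_remove=p_remove
    )
    composite = pd.Series(
        muscle_electrolysis_dose(
            df["A_Area"], df["A_Number"], df["A_Perimeter"], dose_model
        ),
        index=df.index,
        name="UZ_eDosis",
    )

    group_labels = segment_dose_groups(dose, boundaries)
    groups = group_labels.to_numpy()
    comp_rows = {}
    for feat in features + ["UZ_eDosis"]:
        vals = composite.to_numpy() if feat == "UZ_eDosis" else df[feat].to_numpy(float)
        h, kdf, p = kruskal_wallis(vals, groups)
        row = {"N": len(vals), "H": h, "df": kdf, "p": p}
        if p < 0.05:
            pw = pairwise_mannwhitney_bonferroni(vals, groups)
            for pair, padj in pw.items():
                row[f"p_{pair[0]}_vs_{pair[1]}"] = padj
        comp_rows[feat] = row
    group_comparison = pd.DataFrame.from_dict(comp_rows, orient="index")

    return StatReport(
        correlations=correlations,
        simple_ols=simple_ols,
        backward=backward,
        composite=composite,
        group_comparison=group_comparison,
        dose_groups=group_labels,
    )
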