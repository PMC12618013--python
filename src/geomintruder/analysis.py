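"""Statistical analysis pipeline for intruder-task trial records.

Implements, on any trial-record table:

* subject x shape aggregation of error rate or mean confidence;
* the 11 x 2 mixed repeated-measures ANOVA (shape within, group between)
  with Greenhouse-Geisser correction of the within-subject effects;
* subject-wise linear slopes of performance on empirical complexity rank,
  with one-sample one-tailed group tests and a Welch between-group test;
* the subject-level multiple regression of mean confidence on group,
  mean error rate, and their interaction;
* shape-level cross-modal Pearson correlation (11 points, df = 9);
* the 44-point two-predictor model comparison with standardized betas and
  a one-tailed z-test on their difference.

ANOVA sums of squares come from pingouin; the Greenhouse-Geisser epsilon
is estimated here from the pooled (group-weighted) within-group covariance
of the 11 repeated measures, and the corrected p-values use the original F
with epsilon-scaled degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .geometry import FAMILY_ORDER

__all__ = [
    "SubjectShapeTable",
    "AnovaReport",
    "SlopeReport",
    "ModelComparisonReport",
    "tabulate",
    "mixed_anova",
    "gg_epsilon",
    "subjectwise_slopes",
    "confidence_regression",
    "crossmodal_correlation",
    "model_comparison",
]


@dataclass
class SubjectShapeTable:
    """Per-subject, per-family means: rows = subjects, columns = the 11
    families in complexity order; ``group`` aligns with the rows."""

    data: pd.DataFrame
    group: pd.Series
    measure: str

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, len(self.data.columns) + 1)


def tabulate(records: pd.DataFrame, measure: str = "error") -> SubjectShapeTable:
    """Aggregate trial records into a subject x family table of mean error
    rate (``measure="error"``) or mean confidence (``measure="confidence"``)."""
    if measure == "error":
        vals = 1.0 - records["correct"].astype(float)
    elif measure == "confidence":
        vals = records["confidence"].astype(float)
    else:
        raise ValueError("measure must be 'error' or 'confidence'")
    df = records.assign(_v=vals)
    wide = df.pivot_table(index="subject", columns="family", values="_v", aggfunc="mean")
    wide = wide.reindex(columns=list(FAMILY_ORDER))
    if wide.isna().any().any():
        gaps = [
            (s, c) for s in wide.index for c in wide.columns if pd.isna(wide.loc[s, c])
        ]
        raise ValueError(f"missing (subject, family) cells: {gaps[:10]}")
    group = df.groupby("subject")["group"].first().reindex(wide.index)
    return SubjectShapeTable(data=wide, group=group, measure=measure)


@dataclass
class AnovaReport:
    table: pd.DataFrame  # effect, F, df1, df2, eps, p_uncorrected, p_gg, np2

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k covariance of repeated
    measures; bounded in [1/(k-1), 1]."""
    k = cov.shape[0]
    # double-centered covariance == C S C' on orthonormal contrasts
    row = cov.mean(axis=0, keepdims=True)
    centered = cov - row - row.T + cov.mean()
    lam = np.linalg.eigvalsh(centered)
    num = lam.sum() ** 2
    den = (k - 1) * (lam**2).sum()
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def _pooled_within_cov(table: SubjectShapeTable) -> np.ndarray:
    covs, weights = [], []
    for _, idx in table.group.groupby(table.group).groups.items():
        sub = table.data.loc[idx].to_numpy()
        if sub.shape[0] < 2:
            raise ValueError("need at least 2 subjects per group")
        covs.append(np.cov(sub, rowvar=False))
        weights.append(sub.shape[0] - 1)
    return np.average(covs, axis=0, weights=weights)


def mixed_anova(table: SubjectShapeTable) -> AnovaReport:
    """11 x 2 mixed repeated-measures ANOVA: shape (within) x group
    (between), with GG-corrected p-values for the within effects."""
    import pingouin as pg

    eps = gg_epsilon(_pooled_within_cov(table))
    long = (
        table.data.rename_axis(index="subject", columns="family")
        .reset_index()
        .melt(id_vars="subject", var_name="family", value_name="y")
        .merge(table.group.rename("group"), left_on="subject", right_index=True)
    )
    aov = pg.mixed_anova(
        data=long,
        dv="y",
        within="family",
        subject="subject",
        between="group",
        correction=False,
    )
    rows = []
    for src, name in (("group", "group"), ("family", "shape"), ("Interaction", "interaction")):
        r = aov.loc[aov["Source"] == src].iloc[0]
        f, df1, df2 = float(r["F"]), float(r["DF1"]), float(r["DF2"])
        p_unc = float(stats.f.sf(f, df1, df2))
        if name == "group":
            e, p_gg = np.nan, p_unc
        else:
            e = eps
            p_gg = float(stats.f.sf(f, eps * df1, eps * df2))
        rows.append(
            {
                "effect": name,
                "F": f,
                "df1": df1,
                "df2": df2,
                "eps": e,
                "p_uncorrected": p_unc,
                "p_gg": p_gg,
                "np2": float(r["np2"]),
            }
        )
    return AnovaReport(table=pd.DataFrame(rows))


@dataclass
class SlopeReport:
    subject_slopes: pd.Series
    group_stats: pd.DataFrame  # group, n, mean_slope, t, df, p_one_tailed
    welch_t: float
    welch_df: float
    welch_p: float
    direction: str


def subjectwise_slopes(
    table: SubjectShapeTable,
    ranks: np.ndarray | None = None,
    direction: str = "increasing",
) -> SlopeReport:
    """OLS slope of each subject's profile on complexity rank, one-sample
    one-tailed group t-tests against zero (``direction`` gives the
    predicted sign: errors increase, confidence decreases), and a Welch
    two-sample t-test between groups."""
    x = np.asarray(ranks if ranks is not None else table.ranks, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 complexity levels")
    y = table.data.to_numpy()
    xc = x - x.mean()
    slopes = (y - y.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
    slopes = pd.Series(slopes, index=table.data.index, name="slope")
    alternative = "greater" if direction == "increasing" else "less"
    rows = []
    groups = list(dict.fromkeys(table.group))
    for g in groups:
        s = slopes[table.group == g]
        t, p = stats.ttest_1samp(s, 0.0, alternative=alternative)
        rows.append(
            {
                "group": g,
                "n": len(s),
                "mean_slope": float(s.mean()),
                "t": float(t),
                "df": len(s) - 1,
                "p_one_tailed": float(p),
            }
        )
    if len(groups) == 2:
        a, b = (slopes[table.group == g] for g in groups)
        wt = stats.ttest_ind(a, b, equal_var=False)
        welch_t, welch_p = float(wt.statistic), float(wt.pvalue)
        welch_df = float(wt.df)
    else:
        welch_t = welch_p = welch_df = float("nan")
    return SlopeReport(
        subject_slopes=slopes,
        group_stats=pd.DataFrame(rows),
        welch_t=welch_t,
        welch_df=welch_df,
        welch_p=welch_p,
        direction=direction,
    )


def confidence_regression(
    table_err: SubjectShapeTable, table_conf: SubjectShapeTable
) -> pd.DataFrame:
    """Subject-level multiple regression: mean confidence ~ group +
    mean error rate + group x error.  Returns the coefficient table with
    t statistics on n_subjects - 4 degrees of freedom."""
    if not table_err.data.index.equals(table_conf.data.index):
        raise ValueError("error and confidence tables must share subjects")
    err = table_err.data.mean(axis=1)
    conf = table_conf.data.mean(axis=1)
    groups = list(dict.fromkeys(table_err.group))
    gdum = (table_err.group == groups[-1]).astype(float)
    X = pd.DataFrame(
        {"group": gdum, "error_rate": err, "group_x_error": gdum * err},
        index=err.index,
    )
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("collinear predictors in confidence regression")
    fit = sm.OLS(conf, Xc).fit()
    out = pd.DataFrame(
        {
            "coef": fit.params,
            "t": fit.tvalues,
            "df": int(fit.df_resid),
            "p": fit.pvalues,
        }
    )
    out.attrs["reference_group"] = groups[0]
    return out


def crossmodal_correlation(
    means_a: np.ndarray, means_b: np.ndarray
) -> dict[str, float]:
    """Pearson correlation between two 11-shape mean-performance profiles
    (e.g., tactile vs visual error rates): R^2, df = n - 2, two-sided p."""
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D vectors")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a profile")
    r, p = stats.pearsonr(a, b)
    return {"r": float(r), "r2": float(r**2), "df": len(a) - 2, "p": float(p)}


@dataclass
class ModelComparisonReport:
    coef: pd.DataFrame  # predictor, beta_raw, beta_std, t, df, p
    z_diff: float
    p_diff_one_tailed: float
    n: int


def model_comparison(
    observed: np.ndarray,
    symbolic_difficulty: np.ndarray,
    perceptual_difficulty: np.ndarray,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> ModelComparisonReport:
    """Regress observed per-condition performance on the two model
    difficulty scores (44 points for the full grid).

    Standardized betas are the coefficients of the fully z-scored
    regression (equivalently raw beta * sd(x) / sd(y)); the one-tailed z
    for their difference (symbolic minus perceptual) is a Wald test on the
    standardized-fit coefficient covariance.  Set ``n_bootstrap`` > 0 for
    a paired-bootstrap p-value instead.
    """
    y = np.asarray(observed, dtype=float)
    x1 = np.asarray(symbolic_difficulty, dtype=float)
    x2 = np.asarray(perceptual_difficulty, dtype=float)
    n = len(y)
    if len(x1) != n or len(x2) != n:
        raise ValueError("predictors and outcome must be aligned")
    if np.abs(np.corrcoef(x1, x2)[0, 1]) > 1 - 1e-10:
        raise ValueError("predictors perfectly collinear")

    def z(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std(ddof=1)

    Xraw = sm.add_constant(np.column_stack([x1, x2]))
    fit_raw = sm.OLS(y, Xraw).fit()
    Xstd = sm.add_constant(np.column_stack([z(x1), z(x2)]))
    fit_std = sm.OLS(z(y), Xstd).fit()
    coef = pd.DataFrame(
        {
            "predictor": ["symbolic", "perceptual"],
            "beta_raw": fit_raw.params[1:],
            "beta_std": fit_std.params[1:],
            "t": fit_raw.tvalues[1:],
            "df": int(fit_raw.df_resid),
            "p": fit_raw.pvalues[1:],
        }
    )
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        diffs = np.empty(n_bootstrap)
        for i in range(n_bootstrap):
            idx = rng.integers(n, size=n)
            try:
                fb = sm.OLS(
                    z(y[idx]), sm.add_constant(np.column_stack([z(x1[idx]), z(x2[idx])]))
                ).fit()
                diffs[i] = fb.params[1] - fb.params[2]
            except Exception:
                diffs[i] = np.nan
        d0 = fit_std.params[1] - fit_std.params[2]
        sd = np.nanstd(diffs, ddof=1)
        z_diff = float(d0 / sd)
        p_one = float(stats.norm.sf(z_diff))
    else:
        V = fit_std.cov_params()
        var = V[1, 1] + V[2, 2] - 2 * V[1, 2]
        z_diff = float((fit_std.params[1] - fit_std.params[2]) / np.sqrt(var))
        p_one = float(stats.norm.sf(z_diff))
    return ModelComparisonReport(coef=coef, z_diff=z_diff, p_diff_one_tailed=p_one, n=n)
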