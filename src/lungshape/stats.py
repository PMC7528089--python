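"""Mode-score versus covariate association statistics.

Per shape mode: Pearson correlation and ordinary least-squares regression
against continuous covariates (age, BMI, imaged lung volume), whole-cohort
and stratified by sex; Welch's t-test for the sex contrast; one-way ANOVA
for user-supplied groupings.  No multiple-testing correction is applied by
default (alpha = 0.05 per test); Benjamini-Hochberg can be switched on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05

CONTINUOUS_COVARIATES = ("age", "bmi", "volume_L")


class CovariateError(ValueError):
    pass


def validate_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Check the covariate table: positive age/BMI/volume, F/M sex, unique ids."""
    required = {"subject_id", "age", "sex", "bmi", "volume_L"}
    missing = required - set(cov.columns)
    if missing:
        raise CovariateError(f"covariate table missing columns: {sorted(missing)}")
    if cov["subject_id"].duplicated().any():
        dups = cov.loc[cov["subject_id"].duplicated(), "subject_id"].tolist()
        raise CovariateError(f"duplicate subject ids: {dups}")
    if not set(cov["sex"].dropna().unique()) <= {"F", "M"}:
        raise CovariateError("sex must be coded F/M")
    for col in ("age", "bmi", "volume_L"):
        vals = cov[col].dropna()
        if (vals <= 0).any():
            raise CovariateError(f"{col} must be positive")
    return cov


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-based p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance input")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def pearson_permutation_p(x, y, n_permutations: int = 10_000, seed: int = 0) -> float:
    """Two-sided permutation p-value for the Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    n = x.size
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if abs(np.mean(xc[perm] * yc)) >= r_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def anova_oneway(groups) -> tuple[float, int, int, float]:
    """One-way ANOVA: (F, df_between, df_within, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    F, p = scipy.stats.f_oneway(*groups)
    df_between = len(groups) - 1
    df_within = sum(g.size for g in groups) - len(groups)
    return float(F), df_between, df_within, float(p)


def ols_fit(x, y) -> tuple[float, float, float]:
    """Simple OLS of y on x: (slope, intercept, signed R).

    Signed R is the correlation coefficient carrying the slope's sign, the
    usual convention when reporting simple-regression strength.
    """
    X = sm.add_constant(np.asarray(x, dtype=float))
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    r = float(np.sign(fit.params[1]) * np.sqrt(fit.rsquared))
    return float(fit.params[1]), float(fit.params[0]), r


@dataclass
class AssociationResult:
    mode: int
    covariate: str
    stratum: str  # all / F / M
    statistic: str  # pearson_r / welch_t
    value: float
    p_value: float
    n: int
    slope: float | None = None
    significant: bool = False


def association_table(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    modes: list[int] | None = None,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-mode associations with age, BMI, volume (all/F/M) and sex.

    ``scores``: subjects x mode columns ("mode1", ...), indexed by
    subject_id.  Subjects missing a covariate are dropped per test with a
    count recorded in the returned table's attrs.
    """
    covariates = validate_covariates(covariates)
    cov = covariates.set_index("subject_id")
    common = scores.index.intersection(cov.index)
    cov = cov.loc[common]
    scr = scores.loc[common]
    if modes is None:
        modes = [int(c.removeprefix("mode")) for c in scores.columns]
    results: list[AssociationResult] = []
    dropped = 0
    for mode in modes:
        s = scr[f"mode{mode}"]
        for covariate in CONTINUOUS_COVARIATES:
            for stratum in ("all", "F", "M"):
                sel = cov.index if stratum == "all" else cov.index[cov["sex"] == stratum]
                x = cov.loc[sel, covariate]
                y = s.loc[sel]
                keep = x.notna() & y.notna()
                dropped += int((~keep).sum())
                x, y = x[keep], y[keep]
                if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
                    continue
                r, p = pearson(x.to_numpy(), y.to_numpy())
                slope, _, _ = ols_fit(x.to_numpy(), y.to_numpy())
                results.append(
                    AssociationResult(
                        mode=mode, covariate=covariate, stratum=stratum,
                        statistic="pearson_r", value=r, p_value=p,
                        n=len(x), slope=slope,
                    )
                )
        f = s[cov["sex"] == "F"].dropna()
        m = s[cov["sex"] == "M"].dropna()
        if len(f) >= 2 and len(m) >= 2:
            t, _, p = welch_t(f.to_numpy(), m.to_numpy())
            results.append(
                AssociationResult(
                    mode=mode, covariate="sex", stratum="all",
                    statistic="welch_t", value=t, p_value=p, n=len(f) + len(m),
                )
            )
    table = pd.DataFrame([vars(r) for r in results])
    if bh_correction and len(table):
        table["p_value_bh"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["significant"] = table["p_value_bh"] < ALPHA
    else:
        table["significant"] = table["p_value"] < ALPHA
    table.attrs["n_dropped_missing"] = dropped
    return table


def anova_by_group(
    scores: pd.DataFrame, covariates: pd.DataFrame, group_column: str, mode: int
) -> tuple[float, int, int, float]:
    """One-way ANOVA of one mode's scores over a grouping column
    (e.g. recruitment centre or an age-band factor)."""
    cov = covariates.set_index("subject_id")
    common = scores.index.intersection(cov.index)
    s = scores.loc[common, f"mode{mode}"]
    g = cov.loc[common, group_column]
    groups = [s[g == level].to_numpy() for level in sorted(g.dropna().unique())]
    return anova_oneway(groups)
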