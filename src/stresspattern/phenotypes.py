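"""Phenotype statistics: pooling, outlier removal, ANOVA and contrasts.

The biometric analysis pools the chronically stressed treatments
(CMS, CMS-R -> CMSgroup) against the normally housed ones
(NH, NH-R -> NHgroup), removes technical-artifact outliers beyond two
standard deviations within strain-by-treatment cells, and tests each
measure with a two-way Type III ANOVA (strain x chronic-stress group)
under sum-to-zero contrasts, reporting eta-squared effect sizes.  Post
hoc contrasts use Welch's unequal-variance t-test.  The weekly fecal-CORT
time course is log-transformed and analysed as strain x week.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

CMS_TREATMENTS = ("CMS", "CMS-R")
NH_TREATMENTS = ("NH", "NH-R")
VALID_TREATMENTS = CMS_TREATMENTS + NH_TREATMENTS


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float


def pool_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Add the pooled chronic-stress grouping column.

    CMS and CMS-R animals become ``CMSgroup``; NH and NH-R become
    ``NHgroup``.  Returns a copy; row count unchanged.
    """
    unknown = set(table["treatment"]) - set(VALID_TREATMENTS)
    if unknown:
        raise ValueError(f"unknown treatment label(s): {sorted(unknown)}")
    out = table.copy()
    out["pooled_group"] = np.where(
        out["treatment"].isin(CMS_TREATMENTS), "CMSgroup", "NHgroup"
    )
    return out


def body_weight_change(table: pd.DataFrame) -> pd.Series:
    """Per-animal body-weight change in g (end minus start).

    Animals missing either weight are excluded with a warning reporting
    the count; the returned Series is indexed by animal id.
    """
    start = pd.to_numeric(table["body_weight_start_g"], errors="coerce")
    end = pd.to_numeric(table["body_weight_end_g"], errors="coerce")
    ok = start.notna() & end.notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} animals with missing body weights")
    change = (end - start)[ok]
    change.index = table.loc[ok, "animal_id"]
    change.name = "body_weight_change_g"
    return change


def remove_outliers(values, group_keys, k: float = 2.0) -> tuple[pd.Series, pd.Series]:
    """Single-pass removal of values beyond k standard deviations.

    Within each group, a value is dropped when ``|x - mean| > k * sd``
    with mean and sample sd (ddof=1) computed on the full group,
    including the candidate itself.  Groups with fewer than 3 members are
    left untouched.  Returns ``(kept, removed)`` Series preserving the
    original index.
    """
    values = pd.Series(np.asarray(values, dtype=float)) if not isinstance(
        values, pd.Series
    ) else values.astype(float)
    keys = pd.Series(list(group_keys), index=values.index)
    drop = pd.Series(False, index=values.index)
    for _, idx in keys.groupby(keys).groups.items():
        group = values.loc[idx]
        if len(group) < 3:
            continue
        mu, sd = group.mean(), group.std(ddof=1)
        if sd == 0:
            continue
        drop.loc[idx] = (group - mu).abs() > k * sd
    return values[~drop], values[drop]


def _check_cells(data: pd.DataFrame) -> None:
    levels_a = pd.unique(data["A"])
    levels_b = pd.unique(data["B"])
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least two levels")
    counts = data.groupby(["A", "B"], observed=True).size()
    for a in levels_a:
        for b in levels_b:
            if (a, b) not in counts.index:
                raise ValueError(f"empty design cell: ({a!r}, {b!r})")


def anova2_type3(response, factor_a, factor_b,
                 names: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Two-way Type III ANOVA with interaction under sum-to-zero coding.

    Returns a table with one row per term (factor A, factor B, A:B,
    Residual) and columns sum_sq, df, F, p, eta_sq, where eta-squared is
    the term's sum of squares over the corrected total sum of squares.
    Type III (partial) sums of squares are coding-dependent; sum-to-zero
    contrasts are used, matching the convention of car::Anova(type=3).
    A constant response returns all-zero sums of squares with p = 1.
    """
    data = pd.DataFrame(
        {
            "y": np.asarray(response, dtype=float),
            "A": np.asarray(factor_a, dtype=object),
            "B": np.asarray(factor_b, dtype=object),
        }
    )
    if data["y"].isna().any():
        raise ValueError("response contains missing values")
    _check_cells(data)
    ss_total = float(((data["y"] - data["y"].mean()) ** 2).sum())
    index = [names[0], names[1], f"{names[0]}:{names[1]}", "Residual"]
    if ss_total == 0.0:
        n_a, n_b = data["A"].nunique(), data["B"].nunique()
        dfs = [n_a - 1, n_b - 1, (n_a - 1) * (n_b - 1),
               len(data) - n_a * n_b]
        return pd.DataFrame(
            {"sum_sq": 0.0, "df": dfs, "F": 0.0, "p": 1.0, "eta_sq": 0.0}, index=index
        )
    model = smf.ols("y ~ C(A, Sum) * C(B, Sum)", data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=3)
    table = table.drop(index="Intercept")
    rename = {
        "C(A, Sum)": names[0],
        "C(B, Sum)": names[1],
        "C(A, Sum):C(B, Sum)": f"{names[0]}:{names[1]}",
    }
    table = table.rename(index=rename)
    out = pd.DataFrame(
        {
            "sum_sq": table["sum_sq"],
            "df": table["df"],
            "F": table["F"],
            "p": table["PR(>F)"],
            "eta_sq": table["sum_sq"] / ss_total,
        }
    )
    out.loc["Residual", ["F", "p"]] = np.nan
    return out.reindex(index)


def welch_t(a, b) -> WelchResult:
    """Welch's unequal-variance t-test with Welch–Satterthwaite df.

    Degenerate cases: both variances zero with equal means gives t = 0,
    p = 1; with unequal means p = 0 (with a warning), mirroring the limit
    of a vanishing standard error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0,
                               a.mean(), b.mean(), va, vb)
        warnings.warn("both groups have zero variance but different means; p = 0")
        t = np.inf if a.mean() > b.mean() else -np.inf
        return WelchResult(t, float(a.size + b.size - 2), 0.0, a.mean(), b.mean(), va, vb)
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        var_a=float(va),
        var_b=float(vb),
    )


def fcort_analysis(table: pd.DataFrame) -> pd.DataFrame:
    """Strain-by-week Type III ANOVA of log-transformed fecal CORT.

    Concentrations are natural-log transformed (base does not affect F or
    p); week is treated as a categorical fixed factor.  Non-positive
    concentrations are an error listing the offending rows.
    """
    bad = table[table["fcort"] <= 0]
    if not bad.empty:
        raise ValueError(
            f"non-positive fCORT values at rows {bad.index.tolist()[:10]}"
        )
    return anova2_type3(
        np.log(table["fcort"].to_numpy()),
        table["strain"].to_numpy(),
        table["week"].astype(str).to_numpy(),
        names=("strain", "week"),
    )


def phenotype_anova_table(table: pd.DataFrame, measures=None) -> pd.DataFrame:
    """Strain x pooled-group Type III ANOVA for each biometric measure.

    ``measures`` defaults to body-weight change plus the organ weights
    and plasma CORT (the latter after within-cell 2-SD outlier removal,
    mirroring the handling of radioimmunoassay artifacts).
    """
    pooled = pool_groups(table)
    if measures is None:
        measures = ["body_weight_change_g", "adrenal_mg", "thymus_mg",
                    "heart_mg", "brain_g", "plasma_cort_ng_ml"]
    rows = []
    for measure in measures:
        if measure == "body_weight_change_g":
            change = body_weight_change(pooled)
            sub = pooled.set_index("animal_id").loc[change.index]
            y, a, b = change.to_numpy(), sub["strain"], sub["pooled_group"]
        elif measure == "plasma_cort_ng_ml":
            keys = pooled["strain"] + "/" + pooled["treatment"]
            kept, _ = remove_outliers(pooled[measure], keys)
            sub = pooled.loc[kept.index]
            y, a, b = kept.to_numpy(), sub["strain"], sub["pooled_group"]
        else:
            y, a, b = pooled[measure].to_numpy(), pooled["strain"], pooled["pooled_group"]
        res = anova2_type3(y, a.to_numpy(), b.to_numpy(), names=("strain", "treatment"))
        res = res.reset_index(names="term")
        res.insert(0, "measure", measure)
        rows.append(res)
    return pd.concat(rows, ignore_index=True)
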