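"""Group-level statistical contrasts.

Implements the cohort-level tests around the deviation analysis:

* case-control ANCOVA on mean cortical thickness (age + sex covariates)
  and region-wise Welch t-tests with Benjamini-Hochberg FDR;
* ANCOVAs on log(TOC + 1) for clinical groupings, with a companion
  Mann-Whitney U on the raw counts and a Shapiro-Wilk normality check;
* Pearson correlation of TOC with age;
* two-way ANOVA of region-level outlier prevalence on lobe location
  (temporal vs extratemporal) x phenotype;
* linear regressions of TOC and mean thickness on amyloid SUVR, with
  and without age adjustment, plus the high/low SUVR median split;
* three-group comparisons by STS outlier status (one-way ANOVA with
  Bonferroni-adjusted pairwise t-tests; chi-squared for categoricals).

All models go through statsmodels/scipy; results are returned as
:class:`StatResult` records carrying the statistic, degrees of freedom,
raw and (where applicable) adjusted p-values and group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    name: str
    effect: float
    statistic: float
    stat_name: str
    df: tuple
    p: float
    p_adjusted: float | None = None
    adjust_method: str | None = None
    covariates: tuple = ()
    group_sizes: tuple = ()
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "test": self.name, "effect": self.effect,
            "statistic": self.statistic, "stat_name": self.stat_name,
            "df": "/".join(str(d) for d in self.df), "p": self.p,
            "p_adjusted": self.p_adjusted, "adjust_method": self.adjust_method,
            "covariates": "+".join(self.covariates),
            "group_sizes": "/".join(str(g) for g in self.group_sizes),
        }


def _ancova(frame: pd.DataFrame, response: str, factor: str,
            covariates: tuple[str, ...]) -> StatResult:
    terms = [f"C({factor})"] + list(covariates)
    model = smf.ols(f"{response} ~ " + " + ".join(terms), data=frame)
    try:
        fit = model.fit()
        table = sm.stats.anova_lm(fit, typ=2)
    except (np.linalg.LinAlgError, ValueError):
        return StatResult(name=f"ancova_{response}_{factor}", effect=float("nan"),
                          statistic=float("nan"), stat_name="F", df=(),
                          p=float("nan"), covariates=covariates,
                          extra={"estimable": False})
    row = table.loc[f"C({factor})"]
    sizes = tuple(int(v) for v in frame[factor].value_counts(sort=False))
    if not np.isfinite(row["F"]):
        return StatResult(name=f"ancova_{response}_{factor}", effect=float("nan"),
                          statistic=float("nan"), stat_name="F", df=(),
                          p=float("nan"), covariates=covariates,
                          group_sizes=sizes, extra={"estimable": False})
    means = frame.groupby(factor)[response].mean()
    return StatResult(
        name=f"ancova_{response}_{factor}",
        effect=float(means.max() - means.min()),
        statistic=float(row["F"]), stat_name="F",
        df=(int(row["df"]), int(table.loc["Residual", "df"])),
        p=float(row["PR(>F)"]), covariates=covariates, group_sizes=sizes,
        extra={"group_means": means.to_dict()},
    )


def casecontrol_mean_thickness(
    clinical_thickness: pd.DataFrame,
    control_thickness: pd.DataFrame,
    clinical_covariates: pd.DataFrame,
    control_covariates: pd.DataFrame,
) -> StatResult:
    """ANCOVA comparing mean-over-regions thickness between groups.

    Covariates: age and sex.  ``*_covariates`` need columns ``age`` and
    ``sex``.
    """
    if len(clinical_thickness) < 3 or len(control_thickness) < 3:
        raise ValueError("each group needs >= 3 subjects")
    frame = pd.DataFrame({
        "mean_thickness": np.concatenate([
            np.asarray(clinical_thickness, float).mean(axis=1),
            np.asarray(control_thickness, float).mean(axis=1)]),
        "group": ["clinical"] * len(clinical_thickness) + ["control"] * len(control_thickness),
        "age": np.concatenate([np.asarray(clinical_covariates["age"], float),
                               np.asarray(control_covariates["age"], float)]),
        "sex": list(clinical_covariates["sex"]) + list(control_covariates["sex"]),
    })
    res = _ancova(frame, "mean_thickness", "group", ("age", "C(sex)"))
    res.name = "casecontrol_mean_thickness"
    return res


def regionwise_ttests_fdr(
    clinical_thickness: pd.DataFrame,
    control_thickness: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region Welch two-tailed t-tests with Benjamini-Hochberg FDR.

    Returns one row per region: mean difference (clinical - control),
    ``t``, raw ``p``, BH ``q`` and a boolean ``significant`` (q < alpha).
    Zero-variance regions yield NA and are excluded from the BH step.
    """
    a = np.asarray(clinical_thickness, float)
    b = np.asarray(control_thickness, float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs >= 2 subjects")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=False)
    diff = a.mean(axis=0) - b.mean(axis=0)
    out = pd.DataFrame({
        "region": list(clinical_thickness.columns),
        "mean_diff": diff, "t": t, "p": p,
    }).set_index("region")
    valid = np.isfinite(p)
    q = np.full(len(p), np.nan)
    if valid.any():
        _, q_valid, _, _ = multipletests(p[valid], alpha=alpha, method="fdr_bh")
        q[valid] = q_valid
    out["q"] = q
    out["significant"] = (out["q"] < alpha).fillna(False)
    return out


def outliercount_group_test(
    toc: pd.Series,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    transform: str = "log1p",
) -> dict[str, StatResult]:
    """Group effect on the total outlier count.

    Primary: ANCOVA on transformed TOC (``log1p`` by default — counts
    can be 0) with the supplied covariates (typically age and sex; for
    phenotype/depression contrasts, disease stage as well).  Companions:
    Mann-Whitney U on the raw counts (two groups; exact enumeration for
    combined n < 20 without ties, normal approximation with tie
    correction otherwise) and a Shapiro-Wilk normality check of the raw
    TOC distribution.
    """
    if transform not in ("log1p", "none"):
        raise ValueError("transform must be 'log1p' or 'none'")
    toc_arr = np.asarray(toc, dtype=float)
    groups_arr = np.asarray(groups)
    levels, counts = np.unique(groups_arr, return_counts=True)
    if (counts < 3).any():
        small = [str(l) for l, c in zip(levels, counts) if c < 3]
        raise ValueError(f"group(s) with < 3 members: {small}")
    y = np.log1p(toc_arr) if transform == "log1p" else toc_arr
    frame = pd.DataFrame({"y": y, "grp": groups_arr})
    cov_terms: list[str] = []
    if covariates is not None:
        for c in covariates.columns:
            col = covariates[c]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                frame[c] = list(col)
                cov_terms.append(f"C({c})")
            else:
                frame[c] = np.asarray(col, float)
                cov_terms.append(c)
    results: dict[str, StatResult] = {}
    res = _ancova(frame, "y", "grp", tuple(cov_terms))
    res.name = f"toc_ancova_{transform}"
    results["ancova"] = res

    sw_stat, sw_p = sps.shapiro(toc_arr)
    results["shapiro"] = StatResult(
        name="toc_shapiro_wilk", effect=float("nan"), statistic=float(sw_stat),
        stat_name="W", df=(len(toc_arr),), p=float(sw_p))

    if len(levels) == 2:
        x0 = toc_arr[groups_arr == levels[0]]
        x1 = toc_arr[groups_arr == levels[1]]
        n_comb = len(x0) + len(x1)
        has_ties = len(np.unique(np.concatenate([x0, x1]))) < n_comb
        method = "exact" if (n_comb < 20 and not has_ties) else "asymptotic"
        u, p_u = sps.mannwhitneyu(x0, x1, alternative="two-sided", method=method)
        results["mannwhitney"] = StatResult(
            name="toc_mannwhitney", effect=float(np.median(x0) - np.median(x1)),
            statistic=float(u), stat_name="U", df=(), p=float(p_u),
            group_sizes=(len(x0), len(x1)), extra={"method": method})
    return results


def age_correlation(toc: pd.Series, age: pd.Series) -> StatResult:
    """Pearson correlation between total outlier count and age."""
    toc_arr = np.asarray(toc, float)
    age_arr = np.asarray(age, float)
    if len(toc_arr) < 3:
        raise ValueError("need >= 3 subjects")
    if np.std(toc_arr) == 0 or np.std(age_arr) == 0:
        return StatResult(name="toc_age_pearson", effect=float("nan"),
                          statistic=float("nan"), stat_name="r",
                          df=(len(toc_arr) - 2,), p=float("nan"),
                          extra={"estimable": False})
    r, p = sps.pearsonr(toc_arr, age_arr)
    return StatResult(name="toc_age_pearson", effect=float(r), statistic=float(r),
                      stat_name="r", df=(len(toc_arr) - 2,), p=float(p))


def location_phenotype_interaction(
    outliers: pd.DataFrame,
    phenotype: pd.Series,
    atlas: pd.DataFrame,
) -> dict[str, StatResult]:
    """Two-way ANOVA of regional prevalence on lobe location x phenotype.

    Within each phenotype group the per-region outlier prevalence is
    computed, labelled temporal/extratemporal from the atlas, and
    modelled as ``prevalence ~ location * phenotype`` over the region-
    level observations.  Returns the interaction term and the location
    main effect (the temporal > extratemporal contrast).
    """
    from .outliers import outlier_prevalence

    phen_arr = np.asarray(phenotype)
    levels = pd.unique(phen_arr)
    if len(levels) < 2:
        raise ValueError("phenotype must have >= 2 levels")
    lobe = atlas["lobe_group"].to_numpy()
    rows = []
    for lev in levels:
        sub = outliers.loc[np.asarray(phen_arr == lev)]
        if len(sub) == 0:
            raise ValueError(f"phenotype level {lev!r} has no subjects")
        prev = outlier_prevalence(sub)["prevalence_pct"].to_numpy()
        for j in range(len(prev)):
            rows.append({"prev": prev[j], "location": lobe[j], "phenotype": str(lev)})
    frame = pd.DataFrame(rows)
    fit = smf.ols("prev ~ C(location) * C(phenotype)", data=frame).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    df_res = int(table.loc["Residual", "df"])
    inter = table.loc["C(location):C(phenotype)"]
    loc = table.loc["C(location)"]
    return {
        "interaction": StatResult(
            name="prevalence_location_x_phenotype", effect=float("nan"),
            statistic=float(inter["F"]), stat_name="F",
            df=(int(inter["df"]), df_res), p=float(inter["PR(>F)"])),
        "location": StatResult(
            name="prevalence_location_main", effect=float(
                frame.loc[frame.location == "temporal", "prev"].mean()
                - frame.loc[frame.location == "extratemporal", "prev"].mean()),
            statistic=float(loc["F"]), stat_name="F",
            df=(int(loc["df"]), df_res), p=float(loc["PR(>F)"])),
    }


def lobe_prevalence_anova(outliers: pd.DataFrame, atlas: pd.DataFrame) -> StatResult:
    """One-way ANOVA: regional prevalence, temporal vs extratemporal."""
    from .outliers import outlier_prevalence

    prev = outlier_prevalence(outliers)["prevalence_pct"].to_numpy()
    lobe = atlas["lobe_group"].to_numpy()
    frame = pd.DataFrame({"prev": prev, "location": lobe})
    fit = smf.ols("prev ~ C(location)", data=frame).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    row = table.loc["C(location)"]
    return StatResult(
        name="lobe_prevalence_anova",
        effect=float(frame.loc[frame.location == "temporal", "prev"].mean()
                     - frame.loc[frame.location == "extratemporal", "prev"].mean()),
        statistic=float(row["F"]), stat_name="F",
        df=(int(row["df"]), int(table.loc["Residual", "df"])),
        p=float(row["PR(>F)"]),
        group_sizes=(int((lobe == "temporal").sum()), int((lobe == "extratemporal").sum())),
    )


def suvr_association(
    toc: pd.Series,
    mean_thickness: pd.Series,
    suvr: pd.Series,
    age: pd.Series | None = None,
) -> dict:
    """Linear regressions of TOC and mean thickness on amyloid SUVR.

    Reports slope, R^2 and p for each response, unadjusted and (when
    ``age`` is given) age-adjusted.  Also returns the high/low SUVR
    median-split labels (strictly above the median -> ``high``; ties go
    to ``low``).
    """
    suvr_arr = np.asarray(suvr, float)
    if np.ptp(suvr_arr) == 0:
        raise ValueError("SUVR is constant; association non-estimable")
    results: dict[str, StatResult] = {}
    for resp_name, resp in (("toc", np.asarray(toc, float)),
                            ("mean_thickness", np.asarray(mean_thickness, float))):
        designs = {"unadjusted": np.column_stack([np.ones_like(suvr_arr), suvr_arr])}
        if age is not None:
            designs["age_adjusted"] = np.column_stack(
                [np.ones_like(suvr_arr), suvr_arr, np.asarray(age, float)])
        for adj, Xd in designs.items():
            fit = sm.OLS(resp, Xd).fit()
            results[f"{resp_name}_{adj}"] = StatResult(
                name=f"suvr_{resp_name}_{adj}", effect=float(fit.params[1]),
                statistic=float(fit.tvalues[1]), stat_name="t",
                df=(int(fit.df_resid),), p=float(fit.pvalues[1]),
                covariates=("age",) if adj == "age_adjusted" else (),
                extra={"r_squared": float(fit.rsquared)})
    median = float(np.median(suvr_arr))
    labels = pd.Series(np.where(suvr_arr > median, "high", "low"),
                       index=toc.index if isinstance(toc, pd.Series) else None,
                       name="suvr_group")
    return {"results": results, "median": median, "split": labels}


def sts_status_comparisons(
    status: pd.Series,
    frame: pd.DataFrame,
    continuous: tuple[str, ...] = ("age",),
    categorical: tuple[str, ...] = ("sex",),
) -> dict[str, StatResult]:
    """Three-group contrasts by STS outlier status.

    Continuous variables: one-way ANOVA with Bonferroni-adjusted pairwise
    Welch t-tests; categorical variables: chi-squared on the contingency
    table (no continuity correction; df = levels - 1 x groups - 1).
    """
    status_arr = np.asarray(status)
    levels = [l for l in ("none", "unilateral", "bilateral") if l in status_arr]
    if len(levels) < 2:
        raise ValueError("need >= 2 STS status levels present")
    out: dict[str, StatResult] = {}
    sizes = tuple(int((status_arr == l).sum()) for l in levels)
    for col in continuous:
        vals = np.asarray(frame[col], float)
        groups = [vals[status_arr == l] for l in levels]
        f, p = sps.f_oneway(*groups)
        pairs = {}
        raw = []
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                _, pij = sps.ttest_ind(groups[i], groups[j], equal_var=False)
                raw.append(((levels[i], levels[j]), float(pij)))
        m = len(raw)
        for (pair, praw) in raw:
            pairs["|".join(pair)] = min(praw * m, 1.0)  # Bonferroni
        out[col] = StatResult(
            name=f"sts_status_anova_{col}", effect=float("nan"),
            statistic=float(f), stat_name="F",
            df=(len(levels) - 1, len(vals) - len(levels)), p=float(p),
            group_sizes=sizes, adjust_method="bonferroni",
            extra={"pairwise_p_adjusted": pairs})
    for col in categorical:
        tab = pd.crosstab(status_arr, np.asarray(frame[col]))
        chi2, p, dof, _ = sps.chi2_contingency(tab, correction=False)
        out[col] = StatResult(
            name=f"sts_status_chi2_{col}", effect=float("nan"),
            statistic=float(chi2), stat_name="chi2", df=(int(dof),),
            p=float(p), group_sizes=sizes)
    return out


def results_frame(results) -> pd.DataFrame:
    """Flatten StatResults (nested dicts allowed) into a tidy table."""
    rows = []

    def _walk(obj):
        if isinstance(obj, StatResult):
            rows.append(obj.to_row())
        elif isinstance(obj, dict):
            for v in obj.values():
                _walk(v)
    _walk(results)
    return pd.DataFrame(rows)
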