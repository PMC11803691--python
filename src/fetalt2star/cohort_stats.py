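"""Cohort-level statistics: GA-adjusted correlations, ANCOVA with estimated
marginal means, ANOVA, Mann-Whitney, Shapiro-Wilk gatekeeping, interaction
tests, and Benjamini-Hochberg FDR.

The analysis plan mirrors a two-group fetal cohort with gestational age (GA)
as the principal covariate:

* Spearman correlations of every metric with GA (pooled and per group);
* between-group comparisons — ANCOVA adjusting for GA where the metric is
  GA-correlated, one-way ANOVA otherwise, Mann-Whitney for the demographic
  covariates;
* partial Spearman correlations (rank-residualisation) for the
  brain-vs-placenta and texture-vs-T2* association panels, with an
  interaction test for group-dependent slopes;
* BH-FDR applied within each configured family of tests.

All tests are two-sided at α = 0.05; rows missing any variable of a given
test are dropped for that test only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .errors import DegenerateInputError, FormatError
from .io import GROUP_LABELS, CohortTable

__all__ = [
    "StatResult",
    "EmmResult",
    "StatsPlan",
    "spearman",
    "partial_spearman",
    "ancova_group",
    "anova_group",
    "interaction_test",
    "mann_whitney",
    "shapiro_gate",
    "bh_fdr",
    "run_statistics",
]

ALPHA = 0.05


@dataclass(frozen=True)
class StatResult:
    """One test: its effect estimate, raw and (optionally) FDR-adjusted p."""

    method: str
    estimate: float
    p_value: float
    n: int
    p_fdr: float | None = None
    adjusted_for: tuple[str, ...] = ()

    def with_fdr(self, p_fdr: float) -> "StatResult":
        return replace(self, p_fdr=float(p_fdr))


@dataclass(frozen=True)
class EmmResult:
    """Covariate-adjusted group means evaluated at one shared covariate value."""

    group_means: dict[str, float]
    se: dict[str, float]
    covariate_at: float


@dataclass(frozen=True)
class StatsPlan:
    """Which metrics get which between-group test, and the FDR families.

    ``ancova_metrics`` are compared with GA-adjusted ANCOVA (the metrics that
    correlate with GA); ``anova_metrics`` with plain one-way ANOVA;
    ``demographics`` with Mann-Whitney.  ``fdr_families`` maps a family name
    to the list of test keys corrected together.
    """

    ancova_metrics: tuple[str, ...] = (
        "brain_t2star_msec",
        "placenta_t2star_msec",
        "placenta_volume_mm3",
    )
    anova_metrics: tuple[str, ...] = (
        "placenta_texture",
        "placenta_max_thickness_mm",
        "placenta_morphology",
    )
    demographics: tuple[str, ...] = ("ga_weeks", "maternal_age_years")
    covariate: str = "ga_weeks"
    ga_correlation_metrics: tuple[str, ...] = (
        "placenta_t2star_msec",
        "brain_t2star_msec",
        "placenta_volume_mm3",
        "placenta_texture",
        "placenta_max_thickness_mm",
        "placenta_morphology",
    )


def _clean(*cols: np.ndarray) -> tuple[np.ndarray, ...]:
    arrs = [np.asarray(c, dtype=float) for c in cols]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise FormatError("paired vectors must have equal length")
    keep = np.ones(n, dtype=bool)
    for a in arrs:
        keep &= np.isfinite(a)
    return tuple(a[keep] for a in arrs)


def spearman(x, y) -> StatResult:
    """Spearman rank correlation (midranks for ties) with the t-approximation
    two-sided p-value."""
    x, y = _clean(x, y)
    n = x.size
    if n < 4:
        raise FormatError("spearman needs n >= 4 complete pairs, got %d" % n)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult(method="spearman", estimate=float("nan"), p_value=float("nan"), n=n)
    rho, _ = sps.spearmanr(x, y)
    p = _t_pvalue_for_corr(rho, df=n - 2)
    return StatResult(method="spearman", estimate=float(rho), p_value=p, n=n)


def _t_pvalue_for_corr(r: float, df: int) -> float:
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df))


def partial_spearman(x, y, z) -> StatResult:
    """Partial Spearman correlation of x and y given z.

    Midrank-transform all three vectors, residualise rank-x and rank-y on
    rank-z by OLS, and take the Pearson correlation of the residuals; the
    two-sided p uses a t distribution with n - 3 degrees of freedom.  A
    constant z degenerates to the plain Spearman correlation.
    """
    x, y, z = _clean(x, y, z)
    n = x.size
    if n < 5:
        raise FormatError("partial spearman needs n >= 5 complete triples, got %d" % n)
    if np.ptp(z) == 0:
        import warnings

        warnings.warn("covariate is constant; falling back to plain Spearman", stacklevel=2)
        res = spearman(x, y)
        return replace(res, method="partial_spearman", adjusted_for=())
    rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
    design = np.column_stack([np.ones(n), rz])
    ex = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    ey = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    denom = np.sqrt((ex**2).sum() * (ey**2).sum())
    if denom == 0:
        return StatResult(
            method="partial_spearman", estimate=float("nan"), p_value=float("nan"),
            n=n, adjusted_for=("z",),
        )
    rho = float((ex * ey).sum() / denom)
    p = _t_pvalue_for_corr(rho, df=n - 3)
    return StatResult(method="partial_spearman", estimate=rho, p_value=p, n=n, adjusted_for=("z",))


def _group_frame(df: pd.DataFrame, metric: str, covariate: str | None = None) -> pd.DataFrame:
    cols = ["group", metric] + ([covariate] if covariate else [])
    sub = df[cols].dropna()
    present = set(sub["group"])
    if not set(GROUP_LABELS) <= present:
        raise DegenerateInputError(
            "both groups %r required, found %r" % (GROUP_LABELS, sorted(present))
        )
    return sub


def ancova_group(
    table: CohortTable | pd.DataFrame, metric: str, covariate: str = "ga_weeks"
) -> tuple[StatResult, EmmResult]:
    """GA-adjusted group comparison: OLS metric ~ group + covariate.

    The group p-value is the t/F test on the group coefficient; estimated
    marginal means are model predictions for each group at the pooled
    covariate mean, with standard errors from the coefficient covariance.
    """
    df = table.to_dataframe() if isinstance(table, CohortTable) else table
    sub = _group_frame(df, metric, covariate)
    sub = sub.assign(_y=sub[metric], _cov=sub[covariate], _grp=(sub["group"] == "CHD").astype(int))
    model = smf.ols("_y ~ _grp + _cov", data=sub).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise FormatError("singular ANCOVA design (constant group or covariate)")
    beta_grp = float(model.params["_grp"])
    p = float(model.pvalues["_grp"])
    cov_at = float(sub["_cov"].mean())
    emm, se = {}, {}
    cov_params = model.cov_params()
    for gname, gcode in (("control", 0), ("CHD", 1)):
        vec = pd.Series({"Intercept": 1.0, "_grp": float(gcode), "_cov": cov_at})
        vec = vec.reindex(model.params.index).fillna(0.0)
        emm[gname] = float(vec @ model.params)
        se[gname] = float(np.sqrt(vec @ cov_params @ vec))
    result = StatResult(
        method="ancova", estimate=beta_grp, p_value=p, n=len(sub), adjusted_for=(covariate,)
    )
    return result, EmmResult(group_means=emm, se=se, covariate_at=cov_at)


def anova_group(table: CohortTable | pd.DataFrame, metric: str) -> StatResult:
    """One-way ANOVA group comparison (no covariates); estimate is the
    CHD - control mean difference."""
    df = table.to_dataframe() if isinstance(table, CohortTable) else table
    sub = _group_frame(df, metric)
    a = sub.loc[sub["group"] == "control", metric].to_numpy()
    b = sub.loc[sub["group"] == "CHD", metric].to_numpy()
    f, p = sps.f_oneway(a, b)
    return StatResult(
        method="anova", estimate=float(b.mean() - a.mean()), p_value=float(p), n=len(sub)
    )


def interaction_test(
    table: CohortTable | pd.DataFrame, y: str, x: str, covariate_for_ranks: str | None = None
) -> StatResult:
    """Group-by-x interaction: OLS y ~ x * group; returns the interaction
    coefficient and its p-value.

    When ``covariate_for_ranks`` is given, y and x are first rank-transformed
    and residualised on the ranked covariate, so the interaction is tested on
    the same adjusted scale as the partial Spearman panel.
    """
    df = table.to_dataframe() if isinstance(table, CohortTable) else table
    cols = ["group", y, x] + ([covariate_for_ranks] if covariate_for_ranks else [])
    sub = df[cols].dropna()
    if sub["group"].nunique() < 2:
        raise FormatError("group indicator is constant; interaction undefined")
    yv = sub[y].to_numpy(dtype=float)
    xv = sub[x].to_numpy(dtype=float)
    if covariate_for_ranks is not None:
        zv = sps.rankdata(sub[covariate_for_ranks].to_numpy(dtype=float))
        design = np.column_stack([np.ones(len(sub)), zv])
        ry = sps.rankdata(yv)
        rx = sps.rankdata(xv)
        yv = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
        xv = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
        # put residual ranks on a comparable unit scale
        yv = yv / max(yv.std(ddof=0), 1e-12)
        xv = xv / max(xv.std(ddof=0), 1e-12)
    frame = pd.DataFrame(
        {"_y": yv, "_x": xv, "_grp": (sub["group"] == "CHD").astype(int).to_numpy()}
    )
    model = smf.ols("_y ~ _x * _grp", data=frame).fit()
    return StatResult(
        method="interaction",
        estimate=float(model.params["_x:_grp"]),
        p_value=float(model.pvalues["_x:_grp"]),
        n=len(frame),
        adjusted_for=(covariate_for_ranks,) if covariate_for_ranks else (),
    )


def mann_whitney(x, y) -> StatResult:
    """Two-sided Mann-Whitney U test; exact enumeration for combined n ≤ 12,
    tie-corrected normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise FormatError("mann-whitney requires non-empty samples")
    method = "exact" if (x.size + y.size) <= 12 and not _has_ties(x, y) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return StatResult(
        method="mann_whitney", estimate=float(res.statistic), p_value=float(res.pvalue),
        n=x.size + y.size,
    )


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    combined = np.concatenate([x, y])
    return np.unique(combined).size < combined.size


def shapiro_gate(x) -> str:
    """Shapiro-Wilk normality gate deciding the reporting style.

    Returns ``"parametric"`` (report mean ± SD) when normality is not
    rejected at α = 0.05, else ``"nonparametric"`` (median [IQR]).  Samples
    with n < 3 or zero variance default to nonparametric.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3 or np.ptp(x) == 0:
        return "nonparametric"
    _, p = sps.shapiro(x)
    return "parametric" if p >= ALPHA else "nonparametric"


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise FormatError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# Full analysis plan
# ---------------------------------------------------------------------------


def _apply_fdr(tests: dict[str, StatResult], keys: Sequence[str]) -> None:
    keys = [k for k in keys if k in tests and np.isfinite(tests[k].p_value)]
    if not keys:
        return
    adj = bh_fdr([tests[k].p_value for k in keys])
    for k, q in zip(keys, adj):
        tests[k] = tests[k].with_fdr(q)


def run_statistics(table: CohortTable, plan: StatsPlan = StatsPlan()) -> dict:
    """Run the full cohort analysis plan and return a structured report.

    The report contains: GA correlations of every metric (pooled and per
    group), between-group comparisons (ANCOVA / ANOVA / Mann-Whitney as
    configured) with EMMs for the ANCOVA metrics, the brain-vs-placenta and
    texture-vs-T2* partial-correlation panels with interaction tests, the
    normality gate per metric, and BH-FDR within each family.
    """
    df = table.to_dataframe()
    for col in ("ga_weeks",):
        if col not in df.columns:
            raise FormatError("cohort table lacks required column %r" % col)
    sizes = table.group_sizes()
    two_groups = all(v >= 2 for v in sizes.values())

    report: dict = {
        "n": {"total": len(df), **sizes},
        "alpha": ALPHA,
        "notes": [],
        "ga_correlations": {},
        "group_comparisons": {},
        "emm": {},
        "association_panels": {},
        "reporting_style": {},
        "fdr_families": {},
    }
    if not two_groups:
        report["notes"].append(
            "between-group tests skipped: need >= 2 subjects per group, got %r" % sizes
        )

    # --- GA correlations (Table-1 analogue) -------------------------------
    ga_tests: dict[str, StatResult] = {}
    subsets = {"all": df}
    if two_groups:
        subsets["control"] = df[df["group"] == "control"]
        subsets["CHD"] = df[df["group"] == "CHD"]
    for metric in plan.ga_correlation_metrics:
        per = {}
        for name, sub in subsets.items():
            pair = sub[[metric, plan.covariate]].dropna()
            if len(pair) >= 4:
                res = spearman(pair[metric], pair[plan.covariate])
                per[name] = res
                if name == "all":
                    ga_tests[metric] = res
        report["ga_correlations"][metric] = per
    _apply_fdr(ga_tests, list(ga_tests))
    for metric, res in ga_tests.items():
        report["ga_correlations"][metric]["all"] = res
    report["fdr_families"]["ga_correlations_pooled"] = list(ga_tests)

    # --- Between-group comparisons (Table-2 analogue) ---------------------
    if two_groups:
        group_tests: dict[str, StatResult] = {}
        for metric in plan.demographics:
            a = df.loc[df["group"] == "control", metric]
            b = df.loc[df["group"] == "CHD", metric]
            group_tests[metric] = mann_whitney(a, b)
        for metric in plan.ancova_metrics:
            try:
                res, emm = ancova_group(df, metric, plan.covariate)
            except DegenerateInputError:
                continue
            group_tests[metric] = res
            report["emm"][metric] = emm
        for metric in plan.anova_metrics:
            try:
                group_tests[metric] = anova_group(df, metric)
            except DegenerateInputError:
                continue
        fdr_keys = [k for k in group_tests if k not in plan.demographics]
        # demographics (GA, maternal age) join the corrected family as in a
        # full comparisons table
        all_keys = list(group_tests)
        _apply_fdr(group_tests, all_keys)
        report["group_comparisons"] = group_tests
        report["fdr_families"]["group_comparisons"] = all_keys

    # --- Association panels (Fig. 4 / Fig. 6 analogues) -------------------
    panels = {
        "brain_vs_placenta": ("brain_t2star_msec", "placenta_t2star_msec"),
        "texture_vs_placenta_t2star": ("placenta_texture", "placenta_t2star_msec"),
    }
    for panel_name, (yvar, xvar) in panels.items():
        panel: dict[str, StatResult] = {}
        pooled = df[[yvar, xvar, plan.covariate]].dropna()
        if len(pooled) >= 5:
            panel["all"] = partial_spearman(pooled[yvar], pooled[xvar], pooled[plan.covariate])
        if two_groups:
            for gname in GROUP_LABELS:
                sub = df[df["group"] == gname][[yvar, xvar, plan.covariate]].dropna()
                if len(sub) >= 5:
                    panel[gname] = partial_spearman(sub[yvar], sub[xvar], sub[plan.covariate])
            try:
                panel["interaction"] = interaction_test(
                    df, y=yvar, x=xvar, covariate_for_ranks=plan.covariate
                )
            except FormatError:
                pass
        _apply_fdr(panel, [k for k in panel if k != "interaction"])
        report["association_panels"][panel_name] = panel
        report["fdr_families"][panel_name] = [k for k in panel if k != "interaction"]

    # --- Reporting style per metric ---------------------------------------
    for metric in plan.ga_correlation_metrics + plan.demographics:
        report["reporting_style"][metric] = shapiro_gate(df[metric].dropna())

    return report
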