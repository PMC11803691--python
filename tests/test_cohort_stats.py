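"""Statistical stage: rank correlations, ANCOVA/EMMs, U-test, FDR, gates.

Each operation is checked against an independent route: closed-form partial
correlation on ranks, exhaustive permutation enumeration, the O(m²) step-up
definition, pingouin, and statsmodels' multipletests.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fetalt2star.cohort_stats import (
    ancova_group,
    anova_group,
    bh_fdr,
    interaction_test,
    mann_whitney,
    partial_spearman,
    run_statistics,
    shapiro_gate,
    spearman,
)
from fetalt2star.errors import FormatError
from fetalt2star.synthetic import CohortSpec, generate_cohort


# ---------------------------------------------------------------------- ranks
def test_spearman_monotone_extremes():
    x = np.arange(1.0, 11.0)
    assert spearman(x, x**2).estimate == pytest.approx(1.0)
    assert spearman(x, -x).estimate == pytest.approx(-1.0)


def test_spearman_against_exhaustive_permutation_oracle():
    """n = 8: the permutation null of the rank statistic is enumerable; the
    t-approximation p must sit inside the exact permutation band."""
    rng = np.random.default_rng(1)
    x = rng.normal(size=8)
    y = rng.normal(size=8)
    res = spearman(x, y)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
            count += 1
    p_exact = count / total
    rho_oracle = np.corrcoef(rx, ry)[0, 1]
    assert res.estimate == pytest.approx(rho_oracle, abs=1e-12)
    assert res.p_value == pytest.approx(p_exact, abs=0.06)  # approximation band


def test_partial_spearman_closed_form_oracle():
    """ρ_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)) on ranks, n = 10."""
    rng = np.random.default_rng(3)
    x, y, z = rng.normal(size=(3, 10))
    rx, ry, rz = sps.rankdata(x), sps.rankdata(y), sps.rankdata(z)
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xz = np.corrcoef(rx, rz)[0, 1]
    r_yz = np.corrcoef(ry, rz)[0, 1]
    oracle = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    assert partial_spearman(x, y, z).estimate == pytest.approx(oracle, abs=1e-10)


def test_partial_spearman_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(4)
    df = pd.DataFrame(rng.normal(size=(40, 3)), columns=["x", "y", "z"])
    ours = partial_spearman(df.x, df.y, df.z)
    ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
    assert ours.estimate == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    pcol = "p_val" if "p_val" in ref.columns else "p-val"
    assert ours.p_value == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-8)


def test_partial_spearman_perfect_and_conditional_independence():
    rng = np.random.default_rng(5)
    x = rng.normal(size=30)
    z = rng.normal(size=30)
    assert partial_spearman(x, x, z).estimate == pytest.approx(1.0)
    # x ⟂ y given z: dependence only through shared z
    z2 = rng.normal(size=500)
    x2 = z2 + rng.normal(size=500)
    y2 = z2 + rng.normal(size=500)
    res = partial_spearman(x2, y2, z2)
    assert abs(res.estimate) < 0.1


def test_partial_spearman_constant_covariate_falls_back():
    rng = np.random.default_rng(6)
    x = rng.normal(size=20)
    y = x + rng.normal(size=20)
    with pytest.warns(UserWarning, match="constant"):
        res = partial_spearman(x, y, np.full(20, 3.0))
    plain = spearman(x, y)
    assert res.estimate == pytest.approx(plain.estimate)
    assert res.p_value == pytest.approx(plain.p_value)


# --------------------------------------------------------------------- ancova
def _confounded_cohort(seed, delta=-14.0):
    return generate_cohort(
        CohortSpec(seed=seed, placenta_chd_offset=delta, n_control=100, n_chd=100)
    )


def test_ancova_null_group_effect_within_3se():
    table, _ = generate_cohort(
        CohortSpec.null(seed=7, n_control=100, n_chd=100)
    )
    res, emm = ancova_group(table, "placenta_t2star_msec")
    se = abs(res.estimate / sps.t.ppf(1 - res.p_value / 2, res.n - 3)) if res.p_value < 1 else 10.0
    # direct SE from a refit for numerical safety
    df = table.to_dataframe()
    import statsmodels.formula.api as smf
    m = smf.ols("placenta_t2star_msec ~ C(group) + ga_weeks", data=df).fit()
    se = float(m.bse["C(group)[T.control]"])
    assert abs(res.estimate) < 3 * se


def test_ancova_recovers_effect_under_ga_confounding():
    """With GA confounding, the EMM difference recovers the generative CHD
    deficit while the raw mean difference is visibly biased."""
    table, truth = _confounded_cohort(seed=8)
    res, emm = ancova_group(table, "placenta_t2star_msec")
    emm_diff = emm.group_means["CHD"] - emm.group_means["control"]
    se_diff = np.sqrt(emm.se["CHD"] ** 2 + emm.se["control"] ** 2)
    assert abs(emm_diff - (-14.0)) < 3 * se_diff
    df = table.to_dataframe()
    raw_diff = (
        df.loc[df.group == "CHD", "placenta_t2star_msec"].mean()
        - df.loc[df.group == "control", "placenta_t2star_msec"].mean()
    )
    # CHD fetuses are scanned earlier; the negative GA slope inflates their
    # raw mean, biasing the unadjusted contrast upward by slope × GA gap
    assert raw_diff - (-14.0) > 3 * se_diff


def test_ancova_equals_anova_when_covariate_has_no_effect():
    spec = CohortSpec.null(seed=9, n_control=150, n_chd=150, placenta_chd_offset=-5.0)
    table, _ = generate_cohort(spec)
    res_ancova, _ = ancova_group(table, "placenta_t2star_msec")
    res_anova = anova_group(table, "placenta_t2star_msec")
    assert res_ancova.p_value == pytest.approx(res_anova.p_value, abs=0.05)
    assert res_ancova.estimate == pytest.approx(res_anova.estimate, abs=1.5)


def test_emm_invariant_to_covariate_recentering():
    table, _ = _confounded_cohort(seed=10)
    df = table.to_dataframe()
    _, emm0 = ancova_group(df, "placenta_t2star_msec")
    df2 = df.assign(ga_weeks=df.ga_weeks - 30.0)
    _, emm1 = ancova_group(df2, "placenta_t2star_msec")
    d0 = emm0.group_means["CHD"] - emm0.group_means["control"]
    d1 = emm1.group_means["CHD"] - emm1.group_means["control"]
    assert d0 == pytest.approx(d1, abs=1e-9)
    assert emm0.group_means["control"] == pytest.approx(emm1.group_means["control"], abs=1e-9)


# ---------------------------------------------------------------- interaction
def test_interaction_null_and_recovery():
    rng = np.random.default_rng(11)
    n = 200
    grp = np.repeat(["control", "CHD"], n // 2)
    x = rng.normal(size=n)
    for delta in (0.0, 0.8):
        slope = 1.0 + delta * (grp == "CHD")
        y = slope * x + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"group": grp, "x": x, "y": y,
                           "ga_weeks": rng.uniform(30, 38, n)})
        res = interaction_test(df, y="y", x="x")
        se = abs(res.estimate) / max(
            abs(sps.t.ppf(res.p_value / 2, n - 4)), 1e-9
        ) if 0 < res.p_value < 1 else 0.1
        import statsmodels.formula.api as smf
        m = smf.ols("y ~ x * C(group)", data=df).fit()
        se = float(m.bse["x:C(group)[T.control]"])
        assert abs(res.estimate - delta) < 3 * se


def test_interaction_requires_two_groups():
    df = pd.DataFrame({"group": ["CHD"] * 10, "x": np.arange(10.0), "y": np.arange(10.0)})
    with pytest.raises(FormatError):
        interaction_test(df, y="y", x="x")


# -------------------------------------------------------------- mann-whitney
def test_mann_whitney_identical_samples_near_mean_u():
    x = np.arange(20.0)
    res = mann_whitney(x, x + 0.0)
    assert res.p_value > 0.9  # U at its null mean


def test_mann_whitney_separated_exact_enumeration():
    """All x below all y with n = 5/5: U = 0 and exact two-sided p = 2/252."""
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = x + 10.0
    res = mann_whitney(x, y)
    assert res.estimate == 0.0
    assert res.p_value == pytest.approx(2 / 252, abs=1e-12)


def test_mann_whitney_exact_vs_asymptotic_branches_agree():
    rng = np.random.default_rng(10)
    x = rng.normal(size=6)
    y = rng.normal(0.3, 1.0, size=6)  # combined n = 12: exact branch
    exact = mann_whitney(x, y).p_value
    approx = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    assert exact == pytest.approx(approx, abs=0.01)


def test_mann_whitney_empty_sample_raises():
    with pytest.raises(FormatError):
        mann_whitney([], [1.0, 2.0])


# -------------------------------------------------------------------- shapiro
def test_shapiro_gate_calibration():
    rng = np.random.default_rng(13)
    assert shapiro_gate(rng.normal(size=500)) == "parametric"
    assert shapiro_gate(rng.lognormal(0, 1.5, size=500)) == "nonparametric"
    assert shapiro_gate(np.full(10, 2.0)) == "nonparametric"
    assert shapiro_gate([1.0, 2.0]) == "nonparametric"


# ------------------------------------------------------------------------ fdr
def oracle_bh(p):
    """O(m²) application of the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_idx in range(m):
        i = order[rank_idx]
        candidates = []
        for rank_j in range(rank_idx, m):
            j = order[rank_j]
            candidates.append(p[j] * m / (rank_j + 1))
        q[i] = min(min(candidates), 1.0)
    return q


def test_bh_fdr_hand_examples_and_oracle():
    assert bh_fdr([0.03]) == pytest.approx([0.03])
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    rng = np.random.default_rng(14)
    for _ in range(5):
        p = rng.uniform(size=rng.integers(1, 25))
        np.testing.assert_allclose(bh_fdr(p), oracle_bh(p), atol=1e-12)


def test_bh_fdr_matches_statsmodels_and_is_order_invariant():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(15)
    p = rng.uniform(size=12)
    ours = bh_fdr(p)
    _, ref, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(ours, ref, atol=1e-12)
    perm = rng.permutation(12)
    np.testing.assert_allclose(bh_fdr(p[perm]), ours[perm], atol=1e-12)


def test_bh_fdr_monotone_along_sorted_p_and_rejects_bad_input():
    rng = np.random.default_rng(16)
    p = np.sort(rng.uniform(size=10))
    q = bh_fdr(p)
    assert np.all(np.diff(q) >= -1e-15)
    assert np.all(q >= p)
    with pytest.raises(FormatError):
        bh_fdr([0.5, 1.2])


# --------------------------------------------------------------- full report
def test_run_statistics_report_is_complete():
    table, _ = generate_cohort(CohortSpec(seed=17))
    report = run_statistics(table)
    assert set(report["group_comparisons"]) >= {
        "ga_weeks", "maternal_age_years", "brain_t2star_msec", "placenta_t2star_msec",
        "placenta_volume_mm3", "placenta_texture", "placenta_max_thickness_mm",
        "placenta_morphology",
    }
    assert set(report["emm"]) == {
        "brain_t2star_msec", "placenta_t2star_msec", "placenta_volume_mm3"
    }
    for metric, per in report["ga_correlations"].items():
        assert {"all", "control", "CHD"} <= set(per)
    for name in ("brain_vs_placenta", "texture_vs_placenta_t2star"):
        assert {"all", "control", "CHD", "interaction"} <= set(report["association_panels"][name])
    # every FDR-corrected entry satisfies p_fdr >= p
    for res in report["group_comparisons"].values():
        assert res.p_fdr is not None and res.p_fdr >= res.p_value - 1e-15


def test_run_statistics_recovers_generative_signs():
    table, _ = generate_cohort(CohortSpec(seed=18))
    report = run_statistics(table)
    gc = report["group_comparisons"]
    assert gc["placenta_t2star_msec"].estimate < 0  # CHD deficit
    assert gc["brain_t2star_msec"].estimate < 0
    assert gc["placenta_texture"].estimate < 0
    assert gc["placenta_morphology"].estimate > 0
    assert report["ga_correlations"]["placenta_t2star_msec"]["all"].estimate < 0
    assert report["ga_correlations"]["brain_t2star_msec"]["all"].estimate < 0
    assert report["ga_correlations"]["placenta_volume_mm3"]["all"].estimate > 0
    assert report["association_panels"]["brain_vs_placenta"]["all"].estimate > 0
    assert report["association_panels"]["texture_vs_placenta_t2star"]["all"].estimate > 0


def test_run_statistics_single_group_skips_between_group_tests():
    table, _ = generate_cohort(CohortSpec(seed=19))
    controls = tuple(r for r in table.records if r.group == "control")
    from fetalt2star.io import CohortTable

    report = run_statistics(CohortTable(records=controls))
    assert report["group_comparisons"] == {}
    assert any("skipped" in note for note in report["notes"])
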