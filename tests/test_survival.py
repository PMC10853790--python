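"""Activity profiling, telomere distances, stratification, KM and log-rank."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hkcre.intervals import RegionSet
from hkcre.survival import (
    accounting_from_reported,
    activity_profile,
    distance_to_chrom_end,
    healthy_cancer_expression,
    km_estimate,
    logrank_calibration,
    logrank_test,
    methylation_expression_contrast,
    prepare_clinical,
    stratify_mean_expression,
    threshold_accounting,
    znorm_by_project,
)


# --- activity_profile -------------------------------------------------------

def _cellset(rows):
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def test_activity_percentage_full_precision():
    merged = pd.DataFrame(
        [("chr1", 100, 600, "r0")], columns=["chrom", "start", "end", "region_id"]
    )
    validate = {f"v{i}": _cellset([("chr1", 100, 600)]) for i in range(20)}
    validate["v20"] = _cellset([("chr2", 0, 100)])  # inactive cell
    cancer = {"c0": _cellset([("chr2", 0, 100)])}
    out = activity_profile(merged, validate, cancer)
    assert out.loc[0, "pct_healthy_validate"] == pytest.approx(100 * 20 / 21)
    # truncated to two decimals this is the reported 95.23
    assert int(out.loc[0, "pct_healthy_validate"] * 100) / 100 == 95.23
    assert out.loc[0, "pct_cancer"] == 0.0


def test_activity_invariant_to_duplicated_raw_regions():
    merged = pd.DataFrame(
        [("chr1", 100, 600, "r0")], columns=["chrom", "start", "end", "region_id"]
    )
    single = {"v0": _cellset([("chr1", 100, 600)]), "v1": _cellset([("chr2", 0, 9)])}
    doubled = {
        "v0": _cellset([("chr1", 100, 600), ("chr1", 150, 550)]),
        "v1": _cellset([("chr2", 0, 9)]),
    }
    cancer = {"c0": _cellset([("chr2", 0, 9)])}
    a = activity_profile(merged, single, cancer)
    b = activity_profile(merged, doubled, cancer)
    assert a.loc[0, "pct_healthy_validate"] == b.loc[0, "pct_healthy_validate"]


def test_empty_cohort_is_error():
    merged = pd.DataFrame(
        [("chr1", 0, 10, "r0")], columns=["chrom", "start", "end", "region_id"]
    )
    with pytest.raises(ValueError):
        activity_profile(merged, {}, {"c": _cellset([("chr1", 0, 10)])})


# --- threshold accounting ---------------------------------------------------

def test_accounting_identity():
    profiles = pd.DataFrame(
        {
            "pct_healthy_validate": [100.0, 95.0, 80.0, 100.0],
            "pct_cancer": [100.0, 20.0, 95.0, 89.9],
        }
    )
    acc = threshold_accounting(profiles, 0.90)
    assert acc["pass_healthy"] == 3
    assert acc["pass_cancer"] == 2
    assert acc["pass_cancer"] + acc["fail_cancer"] == acc["total"]


def test_reported_accounting_recovers_published_failure_count():
    from hkcre.reference import HKCP_VALIDATION_REPORTED as R

    acc = accounting_from_reported(R["pass_healthy"], R["pct_healthy"], R["pass_cancer"])
    assert acc["fail_cancer"] == R["fail_cancer"]


def test_all_active_means_no_failures():
    profiles = pd.DataFrame(
        {"pct_healthy_validate": [100.0] * 3, "pct_cancer": [100.0] * 3}
    )
    assert threshold_accounting(profiles, 0.90)["fail_cancer"] == 0


# --- telomere distance ------------------------------------------------------

def test_distance_to_chrom_end_reference_rows():
    from hkcre.reference import CHR19_LENGTH_BP, INACTIVE_HKCP_TABLE

    for gene in ("ZNF135", "ZNF667", "ZNF154", "ZIK1"):
        row = INACTIVE_HKCP_TABLE.set_index("gene").loc[gene]
        assert distance_to_chrom_end(int(row["tss"]), CHR19_LENGTH_BP) == int(
            row["printed_distance_to_chrom_end"]
        )
    assert distance_to_chrom_end(100, 100) == 0
    with pytest.raises(ValueError):
        distance_to_chrom_end(101, 100)


def test_bundle_silenced_promoters_ranked_inactive(pipeline_result, truth):
    table = pipeline_result.inactive_table
    silenced_genes = set(
        truth.loci.set_index("locus_id").loc[truth.cancer_silenced, "gene_id"]
    )
    assert silenced_genes <= set(table["gene_id"].dropna())
    assert (table["pct_cancer"].diff().dropna() >= 0).all()


# --- expression contrasts ---------------------------------------------------

def test_identical_matrices_correlate_perfectly(rng):
    expr = pd.DataFrame(
        rng.uniform(0, 5, size=(10, 6)), index=[f"g{i}" for i in range(10)]
    )
    res = healthy_cancer_expression(expr, expr.copy(), inactive_genes=["g0"])
    assert res["pearson_r"] == pytest.approx(1.0)
    assert res["flagged_genes"] == []


def test_constant_cohort_has_missing_correlation(rng):
    expr = pd.DataFrame(
        rng.uniform(0, 5, size=(5, 4)), index=[f"g{i}" for i in range(5)]
    )
    const = pd.DataFrame(1.0, index=expr.index, columns=["a", "b"])
    res = healthy_cancer_expression(expr, const)
    assert np.isnan(res["pearson_r"])


def test_methylation_contrast_identical_groups_ns():
    table = pd.DataFrame(
        {
            "label": ["Normal"] * 4 + ["Cancer"] * 4,
            "promoter_methylation": [0.1, 0.2, 0.3, 0.4] * 2,
            "tpm": [1.0, 2.0, 3.0, 4.0] * 2,
        }
    )
    res = methylation_expression_contrast(table)
    assert res["methylation"]["symbol"] == "ns"
    assert res["expression"]["symbol"] == "ns"


def test_bundle_cancer_methylated_and_silenced(bundle):
    res = methylation_expression_contrast(bundle.depmap_like)
    assert res["methylation"]["median_cancer"] > res["methylation"]["median_normal"]
    assert res["expression"]["median_cancer"] < res["expression"]["median_normal"]
    assert res["methylation"]["p_value"] <= 1e-4
    assert res["expression"]["p_value"] <= 1e-4


# --- z-normalization and stratification -------------------------------------

def test_znorm_per_project_zero_mean(rng):
    expr = pd.DataFrame(
        rng.uniform(1, 10, size=(20, 3)),
        columns=["g1", "g2", "g3"],
        index=[f"s{i}" for i in range(20)],
    )
    projects = pd.Series(["P1"] * 10 + ["P2"] * 10, index=expr.index)
    z = znorm_by_project(expr, projects)
    for p in ("P1", "P2"):
        sub = z.loc[projects == p]
        np.testing.assert_allclose(sub.mean(), 0, atol=1e-12)
        np.testing.assert_allclose(sub.std(ddof=1), 1, atol=1e-12)


def test_znorm_removes_project_location_and_scale(rng):
    base = rng.normal(size=10)
    expr = pd.DataFrame(
        {"g": np.concatenate([base, 100 + 7 * base])},
        index=[f"s{i}" for i in range(20)],
    )
    projects = pd.Series(["A"] * 10 + ["B"] * 10, index=expr.index)
    z = znorm_by_project(expr, projects)
    np.testing.assert_allclose(
        z.loc[projects == "A", "g"].to_numpy(),
        z.loc[projects == "B", "g"].to_numpy(),
        atol=1e-10,
    )


def test_znorm_zero_variance_names_gene_and_project():
    expr = pd.DataFrame({"g1": [1.0, 1.0], "g2": [1.0, 2.0]}, index=["a", "b"])
    projects = pd.Series(["P"] * 2, index=expr.index)
    with pytest.raises(ValueError, match="P.*g1"):
        znorm_by_project(expr, projects)


def test_quartile_stratification_counts():
    z = pd.DataFrame({"g": np.arange(8, dtype=float)}, index=[f"s{i}" for i in range(8)])
    strata = stratify_mean_expression(z, quantile=0.75)
    assert (strata == "HIGH").sum() == 2
    # ties inflate HIGH only
    z_const = pd.DataFrame({"g": np.ones(8)}, index=z.index)
    strata = stratify_mean_expression(z_const, quantile=0.75)
    assert (strata == "HIGH").all()


def test_high_count_bounds(rng):
    n = 37
    z = pd.DataFrame({"g": rng.normal(size=n)}, index=[f"s{i}" for i in range(n)])
    strata = stratify_mean_expression(z, quantile=0.75)
    n_high = (strata == "HIGH").sum()
    assert np.ceil((1 - 0.75) * n) <= n_high <= n


def test_prepare_clinical_mapping():
    clin = pd.DataFrame(
        {
            "sample_id": ["a", "b"],
            "project": ["P", "P"],
            "vital_status": ["Alive", "Dead"],
            "days_to_death": [np.nan, 120.0],
            "days_to_last_follow_up": [500.0, np.nan],
        }
    )
    out = prepare_clinical(clin)
    assert list(out["deceased"]) == [False, True]
    assert list(out["overall_survival"]) == [500.0, 120.0]


# --- Kaplan-Meier -----------------------------------------------------------

def test_km_hand_computed_product_limit():
    curves = km_estimate([1.0, 2.0, 3.0], [True, True, True])
    c = curves[0]
    np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3, 0.0])
    assert c.at(0.5) == 1.0
    assert c.at(1.5) == pytest.approx(2 / 3)


def test_km_no_events_stays_at_one():
    curves = km_estimate([5.0, 8.0, 2.0], [False, False, False])
    c = curves[0]
    assert len(c.event_times) == 0
    assert c.at(100.0) == 1.0


def test_km_censoring_shrinks_risk_set():
    # events at 1 and 3; censored at 2 leaves the risk set before 3
    curves = km_estimate([1.0, 2.0, 3.0], [True, False, True])
    c = curves[0]
    np.testing.assert_allclose(c.at_risk, [3, 1])
    np.testing.assert_allclose(c.survival, [2 / 3, 0.0])


def test_km_matches_lifelines_on_random_data(rng):
    from lifelines import KaplanMeierFitter

    t = rng.exponential(100, size=80)
    d = rng.random(80) < 0.7
    curves = km_estimate(t, d)
    c = curves[0]
    kmf = KaplanMeierFitter().fit(t, event_observed=d)
    for et, s in zip(c.event_times, c.survival):
        assert s == pytest.approx(kmf.predict(et), abs=1e-12)


def test_km_monotone_and_starts_at_one(rng):
    t = rng.exponential(50, size=60)
    d = rng.random(60) < 0.5
    strata = rng.integers(0, 2, size=60)
    curves = km_estimate(t, d, strata)
    for c in curves.values():
        assert (np.diff(c.survival) <= 1e-12).all()
        assert c.at(0.0) <= 1.0
        assert c.at(-1.0) == 1.0


# --- log-rank ---------------------------------------------------------------

def test_logrank_identical_strata_is_null():
    t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    d = np.array([True] * 6)
    strata = np.array(["a"] * 3 + ["b"] * 3)
    chi2, p = logrank_test(t, d, strata)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_lifelines(rng):
    from lifelines.statistics import logrank_test as ll_logrank

    t = rng.exponential(100, size=100)
    d = rng.random(100) < 0.8
    strata = rng.integers(0, 2, size=100)
    chi2, p = logrank_test(t, d, strata)
    ref = ll_logrank(t[strata == 0], t[strata == 1],
                     event_observed_A=d[strata == 0], event_observed_B=d[strata == 1])
    assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
    assert p == pytest.approx(ref.p_value, rel=1e-9)


def test_logrank_power_under_planted_hazard():
    power = logrank_calibration(
        n_samples=400, hazard_ratio=3.0, n_replicates=100, seed=7
    )
    assert power >= 0.80


def test_logrank_requires_two_populated_strata():
    with pytest.raises(ValueError):
        logrank_test([1, 2, 3], [True, True, True], ["a", "a", "a"])


def test_joint_survival_on_bundle_detects_planted_hazard(pipeline_result):
    surv = pipeline_result.survival
    assert surv["logrank_p"] < 0.05
    assert surv["n_high"] + surv["n_low"] == len(surv["strata"])
    # HIGH stratum (high suppressor expression) survives longer
    high = surv["km_curves"]["HIGH"]
    low = surv["km_curves"]["LOW"]
    t = max(high.event_times[-1], low.event_times[-1]) if len(high.event_times) else 0
    assert high.at(t) >= low.at(t)
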