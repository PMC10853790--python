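"""Cancer activity profiling and survival analysis.

Activity of a consensus region in a held-out cohort is defined as >= 1 bp
overlap with any significant raw region of that cell type.  Regions whose
core promoter is inactive in most cancer cell lines are ranked and joined to
their genes; patient cohorts are stratified by the mean per-project
z-normalized expression of a gene set and compared with an internally
implemented Kaplan-Meier product-limit estimator and two-sample log-rank
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .intervals import find_overlaps

__all__ = [
    "ActivityProfile",
    "SurvivalRecord",
    "KmCurve",
    "activity_profile",
    "threshold_accounting",
    "accounting_from_reported",
    "rank_inactive",
    "distance_to_chrom_end",
    "healthy_cancer_expression",
    "methylation_expression_contrast",
    "znorm_by_project",
    "stratify_mean_expression",
    "prepare_clinical",
    "km_estimate",
    "logrank_test",
    "logrank_calibration",
]


@dataclass(frozen=True)
class ActivityProfile:
    region_id: str
    pct_healthy_validate: float
    pct_cancer: float
    class_label: str | None = None


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    project: str
    overall_survival: float
    deceased: bool
    strata: str

    def __post_init__(self):
        if self.overall_survival < 0:
            raise ValueError("overall_survival must be >= 0")


@dataclass
class KmCurve:
    """Product-limit survival estimate over the observed event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """S(t): step function, right-continuous, S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def activity_profile(
    merged_hk: pd.DataFrame,
    validate_sets: dict,
    cancer_sets: dict,
) -> pd.DataFrame:
    """Percentage of validation-healthy and cancer cell types each region is active in."""
    if not validate_sets or not cancer_sets:
        raise ValueError("both cohorts must be non-empty")
    out = merged_hk[["chrom", "start", "end", "region_id"]].copy()
    for name, sets in (("pct_healthy_validate", validate_sets), ("pct_cancer", cancer_sets)):
        active = np.zeros(len(merged_hk), dtype=int)
        pos_of = {idx: j for j, idx in enumerate(merged_hk.index)}
        for cell_id, rs in sets.items():
            pairs = find_overlaps(merged_hk, rs.df, min_overlap_bp=1)
            hit = {pos_of[ia] for ia, _ in pairs}
            for j in hit:
                active[j] += 1
        out[name] = 100.0 * active / len(sets)
    if "class_label" in merged_hk.columns:
        out["class_label"] = merged_hk["class_label"]
    return out


def threshold_accounting(profiles: pd.DataFrame, hk_fraction: float) -> dict:
    """How many regions keep housekeeping-level activity in each cohort."""
    cut = 100.0 * hk_fraction
    total = len(profiles)
    pass_healthy = int((profiles["pct_healthy_validate"] >= cut).sum())
    pass_cancer = int((profiles["pct_cancer"] >= cut).sum())
    return {
        "total": total,
        "pass_healthy": pass_healthy,
        "pass_cancer": pass_cancer,
        "fail_cancer": total - pass_cancer,
    }


def accounting_from_reported(pass_healthy: int, pct_healthy: float, pass_cancer: int) -> dict:
    """Recover the cohort total and cancer-failure count from reported summaries.

    Given that ``pass_healthy`` regions are ``pct_healthy`` percent of the
    cohort, the total is pass_healthy / (pct_healthy/100) rounded to the
    nearest integer, and fail_cancer = total - pass_cancer.
    """
    total = round(pass_healthy / (pct_healthy / 100.0))
    return {"total": total, "fail_cancer": total - pass_cancer}


def rank_inactive(
    profiles: pd.DataFrame,
    gene_assoc: pd.DataFrame,
    chrom_sizes,
    max_cancer_pct: float,
) -> pd.DataFrame:
    """Regions active in fewer than ``max_cancer_pct`` % of cancer cells, with genes.

    ``gene_assoc`` columns: region_id, gene_id, tss, chrom.  Output rows are
    ranked by ascending cancer activity, then by distance from the gene TSS
    to its chromosome end.  The boundary is exclusive (strictly below the
    threshold).
    """
    sel = profiles[profiles["pct_cancer"] < max_cancer_pct].reset_index(drop=True)
    if sel.empty:
        return pd.DataFrame(
            columns=list(profiles.columns) + ["gene_id", "tss", "distance_to_chrom_end"]
        )
    joined = sel.merge(gene_assoc, on="region_id", how="left", suffixes=("", "_gene"))
    joined["distance_to_chrom_end"] = [
        distance_to_chrom_end(int(t), chrom_sizes[c]) if pd.notna(t) else np.nan
        for t, c in zip(joined["tss"], joined["chrom"])
    ]
    joined = joined.sort_values(
        ["pct_cancer", "distance_to_chrom_end"], kind="mergesort"
    ).reset_index(drop=True)
    return joined


def distance_to_chrom_end(tss_position: int, chrom_length: int) -> int:
    """Base pairs from a TSS to the end of its chromosome."""
    if not 0 <= tss_position <= chrom_length:
        raise ValueError(
            f"tss_position {tss_position} outside [0, {chrom_length}]"
        )
    return chrom_length - tss_position


def healthy_cancer_expression(
    expr_healthy: pd.DataFrame,
    expr_cancer: pd.DataFrame,
    genes=None,
    inactive_genes=None,
) -> dict:
    """Per-gene cohort medians, their correlation, and silenced-gene flags.

    Both matrices are log-normalized genes x samples on shared gene ids.
    Genes in ``inactive_genes`` whose cancer median falls below their healthy
    median are flagged.  Correlation is Pearson across genes; a constant
    cohort yields a missing (NaN) correlation.
    """
    shared = expr_healthy.index.intersection(expr_cancer.index)
    if genes is not None:
        shared = shared.intersection(pd.Index(genes))
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes for the correlation")
    med_h = expr_healthy.loc[shared].median(axis=1)
    med_c = expr_cancer.loc[shared].median(axis=1)
    if med_h.std() == 0 or med_c.std() == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(med_h, med_c)[0, 1])
    flagged = []
    if inactive_genes is not None:
        for g in inactive_genes:
            if g in shared and med_c[g] < med_h[g]:
                flagged.append(g)
    return {
        "median_healthy": med_h,
        "median_cancer": med_c,
        "pearson_r": r,
        "flagged_genes": sorted(flagged),
    }


def methylation_expression_contrast(
    table: pd.DataFrame,
    meth_col: str = "promoter_methylation",
    expr_col: str = "tpm",
    label_col: str = "label",
) -> dict:
    """Normal-vs-Cancer contrast of promoter methylation and expression.

    Unpaired two-sided rank-sum tests with the conventional significance
    symbols.  Both groups must be non-empty.
    """
    groups = table.groupby(label_col)
    if not {"Normal", "Cancer"} <= set(groups.groups):
        raise ValueError("table must contain both 'Normal' and 'Cancer' samples")
    normal = groups.get_group("Normal")
    cancer = groups.get_group("Cancer")
    out = {}
    for name, col in (("methylation", meth_col), ("expression", expr_col)):
        a = normal[col].dropna()
        b = cancer[col].dropna()
        if a.tolist() == b.tolist():
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        out[name] = {
            "median_normal": float(a.median()),
            "median_cancer": float(b.median()),
            "p_value": p,
            "symbol": _symbol(p),
        }
    return out


def _symbol(p: float) -> str:
    from .gene_assoc import significance_symbol

    return significance_symbol(p)


def znorm_by_project(
    expr: pd.DataFrame,
    project_labels: pd.Series,
    gene_set=None,
) -> pd.DataFrame:
    """Z-transform each gene within each project (samples x genes layout).

    Uses the sample standard deviation (ddof=1).  Projects with fewer than
    two samples or a zero-variance gene within a project are errors.
    """
    if gene_set is not None:
        expr = expr[list(gene_set)]
    out = expr.astype(float).copy()
    for project, samples in project_labels.groupby(project_labels):
        idx = samples.index
        if len(idx) < 2:
            raise ValueError(f"project {project} has fewer than 2 samples")
        sub = out.loc[idx]
        sd = sub.std(ddof=1)
        zero = sd[sd == 0]
        if len(zero):
            raise ValueError(
                f"zero variance in project {project} for gene(s) {list(zero.index)}"
            )
        out.loc[idx] = (sub - sub.mean()) / sd
    return out


def stratify_mean_expression(
    z_matrix: pd.DataFrame,
    gene_set=None,
    quantile: float = 0.75,
) -> pd.Series:
    """HIGH/LOW strata from the per-sample mean of z-scored expression.

    A sample is HIGH when its mean expression is at or above the empirical
    ``quantile`` of all samples (inclusive, so ties inflate the HIGH group).
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    sub = z_matrix if gene_set is None else z_matrix[list(gene_set)]
    mean_expr = sub.mean(axis=1)
    cut = float(np.quantile(mean_expr.to_numpy(), quantile))
    return pd.Series(
        np.where(mean_expr >= cut, "HIGH", "LOW"), index=z_matrix.index, name="strata"
    )


def prepare_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Derive overall survival and the deceased flag from a clinical table.

    ``vital_status == 'Alive'`` -> censored at days_to_last_follow_up;
    otherwise the event time is days_to_death.
    """
    out = clinical.copy()
    alive = out["vital_status"] == "Alive"
    out["deceased"] = ~alive
    out["overall_survival"] = np.where(
        alive, out["days_to_last_follow_up"], out["days_to_death"]
    ).astype(float)
    return out


def km_estimate(times, deceased, strata=None) -> dict:
    """Kaplan-Meier product-limit curves, one per stratum.

    S(t) = prod over distinct event times t_i <= t of (1 - d_i / n_i), where
    n_i counts subjects still at risk just before t_i and d_i the deaths at
    t_i; censored subjects leave the risk set after their censoring time.
    """
    times = np.asarray(times, dtype=float)
    deceased = np.asarray(deceased, dtype=bool)
    if np.any(times < 0):
        raise ValueError("survival times must be >= 0")
    if strata is None:
        strata = np.zeros(len(times), dtype=int)
    strata = np.asarray(strata)
    curves = {}
    for s in pd.unique(strata):
        mask = strata == s
        if not mask.any():
            raise ValueError(f"stratum {s} is empty")
        t, d = times[mask], deceased[mask]
        order = np.argsort(t, kind="mergesort")
        t, d = t[order], d[order]
        event_times = np.unique(t[d])
        n_total = len(t)
        at_risk = np.empty(len(event_times), dtype=int)
        n_events = np.empty(len(event_times), dtype=int)
        for i, et in enumerate(event_times):
            at_risk[i] = n_total - np.searchsorted(t, et, side="left")
            n_events[i] = int(np.sum(d & (t == et)))
        with np.errstate(divide="ignore", invalid="ignore"):
            surv = np.cumprod(1.0 - n_events / at_risk)
        curves[s] = KmCurve(event_times, at_risk, n_events, surv)
    return curves


def logrank_test(times, deceased, strata) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square, p-value, 1 df).

    At each distinct event time the observed deaths in group 1 are compared
    with the expectation under the hypergeometric null given the pooled risk
    set; tied event times are handled natively by the hypergeometric
    variance.
    """
    times = np.asarray(times, dtype=float)
    deceased = np.asarray(deceased, dtype=bool)
    strata = np.asarray(strata)
    labels = pd.unique(strata)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 strata, got {len(labels)}")
    g1 = strata == labels[0]
    if g1.sum() == 0 or (~g1).sum() == 0:
        raise ValueError("a stratum has no subjects")

    event_times = np.unique(times[deceased])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = times >= et
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = (deceased & (times == et)).sum()
        d1 = (deceased & (times == et) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def logrank_calibration(
    n_samples: int = 200,
    hazard_ratio: float = 1.0,
    n_replicates: int = 1000,
    alpha: float = 0.05,
    censor_time: float = 2000.0,
    base_hazard: float = 1e-3,
    seed: int = 0,
) -> float:
    """Rejection rate of the log-rank test over simulated replicates.

    Under ``hazard_ratio`` 1 this estimates the type-I error; above 1, the
    power.  Each replicate draws exponential event times for two equal-sized
    strata (the second with hazard multiplied by ``hazard_ratio``) with
    administrative censoring at ``censor_time``.
    """
    rng = np.random.default_rng(seed)
    half = n_samples // 2
    strata = np.array([0] * half + [1] * (n_samples - half))
    rejections = 0
    for _ in range(n_replicates):
        haz = np.where(strata == 0, base_hazard, base_hazard * hazard_ratio)
        t = rng.exponential(1.0 / haz)
        deceased = t < censor_time
        t = np.minimum(t, censor_time)
        _, p = logrank_test(t, deceased, strata)
        if p < alpha:
            rejections += 1
    return rejections / n_replicates
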