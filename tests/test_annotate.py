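"""Feature annotators vs quadratic/brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hkcre.annotate import (
    annotate_conservation,
    annotate_dntss,
    annotate_histone,
    annotate_methylation,
    preprocess_histone,
)

from conftest import random_region_frame


# --- preprocess_histone -----------------------------------------------------

def test_preprocess_matches_independent_log1p_standardize(rng):
    peaks = pd.DataFrame(
        {"chrom": "chr1", "start": range(0, 1000, 100), "end": range(50, 1050, 100),
         "signal": rng.uniform(0, 100, size=10)}
    )
    out = preprocess_histone(peaks)["signal"].to_numpy()
    x = np.log(peaks["signal"].to_numpy() + 1.0)
    expected = (x - x.mean()) / x.std()
    np.testing.assert_allclose(out, expected, atol=1e-12)
    assert abs(out.mean()) < 1e-12
    assert out.std() == pytest.approx(1.0)


def test_preprocess_constant_sample_falls_back_to_centering():
    peaks = pd.DataFrame(
        {"chrom": "chr1", "start": [0, 100], "end": [50, 150], "signal": [3.0, 3.0]}
    )
    out = preprocess_histone(peaks)["signal"]
    assert (out == 0).all()


def test_preprocess_rejects_negative_signal():
    peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [50], "signal": [-1.0]})
    with pytest.raises(ValueError):
        preprocess_histone(peaks)


# --- annotate_histone -------------------------------------------------------

def _hist_oracle(regions, peak_tables, flank, min_ov):
    """All-pairs mean of qualifying normalized peak signals."""
    vals = []
    for _, r in regions.iterrows():
        s, e = r["start"] - flank, r["end"] + flank
        sigs = []
        for peaks in peak_tables:
            for _, p in peaks.iterrows():
                if p["chrom"] != r["chrom"]:
                    continue
                ov = min(e, p["end"]) - max(s, p["start"])
                if ov >= min_ov:
                    sigs.append(p["signal"])
        vals.append(np.mean(sigs) if sigs else 0.0)
    return np.array(vals)


def test_single_qualifying_peak_gives_its_signal():
    regions = pd.DataFrame([("chr1", 1000, 1500)], columns=["chrom", "start", "end"])
    peaks = pd.DataFrame(
        [("chr1", 900, 1600, 2.5)], columns=["chrom", "start", "end", "signal"]
    )
    out = annotate_histone(regions, {"h3k27ac": [peaks]}, flank_bp=250, min_overlap_bp=250)
    assert out.loc[0, "h3k27ac"] == 2.5


def test_249bp_overlap_is_excluded():
    regions = pd.DataFrame([("chr1", 1000, 1500)], columns=["chrom", "start", "end"])
    # extended region is [750, 1750); peak overlapping exactly 249 bp fails
    peaks = pd.DataFrame(
        [("chr1", 1750 - 249, 2500, 9.9)], columns=["chrom", "start", "end", "signal"]
    )
    out = annotate_histone(regions, {"m": [peaks]}, flank_bp=250, min_overlap_bp=250)
    assert out.loc[0, "m"] == 0.0
    peaks250 = peaks.assign(start=1750 - 250)
    out = annotate_histone(regions, {"m": [peaks250]}, flank_bp=250, min_overlap_bp=250)
    assert out.loc[0, "m"] == 9.9


def test_histone_annotation_matches_quadratic_oracle(rng):
    for _ in range(25):
        regions = random_region_frame(rng, int(rng.integers(1, 15)), max_pos=5_000)
        tables = [
            random_region_frame(rng, int(rng.integers(1, 20)), max_pos=5_000).assign(
                signal=rng.normal(size=1).repeat(1)[0]
            )
            for _ in range(int(rng.integers(1, 4)))
        ]
        tables = [t.assign(signal=rng.normal(size=len(t))) for t in tables]
        flank = int(rng.integers(0, 300))
        min_ov = int(rng.integers(1, 200))
        out = annotate_histone(regions, {"m": tables}, flank, min_ov)["m"].to_numpy()
        np.testing.assert_allclose(out, _hist_oracle(regions, tables, flank, min_ov), atol=1e-12)


def test_histone_annotation_invariant_to_peak_order(rng):
    regions = random_region_frame(rng, 8, max_pos=3_000)
    peaks = random_region_frame(rng, 30, max_pos=3_000).assign(
        signal=rng.normal(size=30)
    )
    a = annotate_histone(regions, {"m": [peaks]}, 100, 50)
    b = annotate_histone(regions, {"m": [peaks.sample(frac=1, random_state=0)]}, 100, 50)
    np.testing.assert_allclose(a["m"], b["m"], atol=1e-12)


# --- annotate_dntss ---------------------------------------------------------

def test_dntss_center_hit_and_tiebreak():
    regions = pd.DataFrame(
        [("chr1", 100, 200), ("chr1", 900, 1100)], columns=["chrom", "start", "end"]
    )
    tss = pd.DataFrame(
        {"chrom": ["chr1"] * 3, "tss": [150, 900, 1200], "gene_id": ["g1", "g2", "g3"]}
    )
    out = annotate_dntss(regions, tss)
    assert out.loc[0, "dntss_bp"] == 0 and out.loc[0, "nearest_gene"] == "g1"
    # center 1000: distances 100 (g2) and 200 (g3)
    assert out.loc[1, "dntss_bp"] == 100 and out.loc[1, "nearest_gene"] == "g2"


def test_dntss_equidistant_prefers_smaller_position():
    regions = pd.DataFrame([("chr1", 990, 1010)], columns=["chrom", "start", "end"])
    tss = pd.DataFrame({"chrom": ["chr1", "chr1"], "tss": [900, 1100],
                        "gene_id": ["far_b", "far_a"]})
    out = annotate_dntss(regions, tss)
    assert out.loc[0, "nearest_gene"] == "far_b"


def test_dntss_matches_exhaustive_argmin(rng):
    for _ in range(30):
        regions = random_region_frame(rng, int(rng.integers(1, 12)), max_pos=20_000)
        n_tss = int(rng.integers(1, 15))
        tss = pd.DataFrame(
            {
                "chrom": [f"chr{i+1}" for i in rng.integers(0, 2, size=n_tss)],
                "tss": rng.integers(0, 20_000, size=n_tss),
                "gene_id": [f"g{i}" for i in range(n_tss)],
            }
        )
        if not set(regions["chrom"]) <= set(tss["chrom"]):
            continue
        out = annotate_dntss(regions, tss)
        for i, r in regions.iterrows():
            c = (r["start"] + r["end"]) // 2
            sub = tss[tss["chrom"] == r["chrom"]].copy()
            sub["d"] = (sub["tss"] - c).abs()
            sub = sub.sort_values(["d", "tss", "gene_id"])
            assert out.loc[i, "dntss_bp"] == sub.iloc[0]["d"]
            assert out.loc[i, "nearest_gene"] == sub.iloc[0]["gene_id"]


def test_dntss_missing_chromosome_is_error():
    regions = pd.DataFrame([("chr9", 0, 10)], columns=["chrom", "start", "end"])
    tss = pd.DataFrame({"chrom": ["chr1"], "tss": [5], "gene_id": ["g"]})
    with pytest.raises(ValueError, match="chr9"):
        annotate_dntss(regions, tss)


# --- annotate_conservation --------------------------------------------------

def test_conservation_unweighted_mean():
    regions = pd.DataFrame([("chr1", 4_500, 5_500)], columns=["chrom", "start", "end"])
    track = pd.DataFrame(
        [("chr1", 0, 10_000, 0.8)], columns=["chrom", "start", "end", "score"]
    )
    assert annotate_conservation(regions, track, 500).iloc[0] == pytest.approx(0.8)
    track2 = pd.DataFrame(
        [("chr1", 0, 5_000, 0.2), ("chr1", 5_000, 10_000, 1.0)],
        columns=["chrom", "start", "end", "score"],
    )
    assert annotate_conservation(regions, track2, 500).iloc[0] == pytest.approx(0.6)


def test_conservation_no_overlap_is_missing():
    regions = pd.DataFrame([("chr1", 100, 200)], columns=["chrom", "start", "end"])
    track = pd.DataFrame(
        [("chr1", 5_000, 6_000, 0.9)], columns=["chrom", "start", "end", "score"]
    )
    assert np.isnan(annotate_conservation(regions, track, 500).iloc[0])


def test_conservation_matches_bruteforce(rng):
    for _ in range(30):
        regions = random_region_frame(rng, int(rng.integers(1, 10)), max_pos=5_000)
        track = random_region_frame(rng, int(rng.integers(1, 25)), max_pos=5_000).assign(
            score=rng.uniform(0, 1, size=None)
        )
        track["score"] = rng.uniform(0, 1, size=len(track))
        hw = int(rng.integers(50, 600))
        got = annotate_conservation(regions, track, hw)
        for i, r in regions.iterrows():
            c = (r["start"] + r["end"]) // 2
            lo, hi = max(c - hw, 0), c + hw
            scores = [
                t["score"]
                for _, t in track.iterrows()
                if t["chrom"] == r["chrom"] and min(hi, t["end"]) - max(lo, t["start"]) >= 1
            ]
            if scores:
                assert got[i] == pytest.approx(np.mean(scores))
            else:
                assert np.isnan(got[i])


# --- annotate_methylation ---------------------------------------------------

def test_methylation_window_halfopen_and_mean():
    regions = pd.DataFrame([("chr1", 900, 1100)], columns=["chrom", "start", "end"])
    # center 1000, window [500, 1500)
    cpg = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "pos": [500, 1000, 1499, 1500],
            "cellA": [0.0, 0.0, 0.0, 1.0],
            "cellB": [0.0, 0.0, 0.0, 1.0],
        }
    )
    out = annotate_methylation(regions, cpg, window_bp=1_000)
    assert out.loc[0, "cpg_count"] == 3       # 1500 is outside the half-open window
    assert out.loc[0, "methylation_mean"] == 0.0


def test_methylation_zero_sites_undefined_mean():
    regions = pd.DataFrame([("chr2", 900, 1100)], columns=["chrom", "start", "end"])
    cpg = pd.DataFrame({"chrom": ["chr1"], "pos": [1000], "cellA": [0.5]})
    out = annotate_methylation(regions, cpg, 1_000)
    assert out.loc[0, "cpg_count"] == 0
    assert np.isnan(out.loc[0, "methylation_mean"])


def test_methylation_matches_bruteforce(rng):
    regions = random_region_frame(rng, 10, max_pos=10_000)
    cpg = pd.DataFrame(
        {
            "chrom": [f"chr{i+1}" for i in rng.integers(0, 2, size=200)],
            "pos": rng.integers(0, 10_000, size=200),
            "cellA": rng.uniform(0, 1, 200),
            "cellB": rng.uniform(0, 1, 200),
        }
    )
    out = annotate_methylation(regions, cpg, 800)
    for i, r in regions.iterrows():
        c = (r["start"] + r["end"]) // 2
        sub = cpg[(cpg["chrom"] == r["chrom"]) & (cpg["pos"] >= c - 400) & (cpg["pos"] < c + 400)]
        assert out.loc[i, "cpg_count"] == len(sub)
        if len(sub):
            assert out.loc[i, "methylation_mean"] == pytest.approx(
                sub[["cellA", "cellB"]].to_numpy().mean()
            )


# --- planted contrasts on the bundle ---------------------------------------

def test_hk_promoters_cpg_rich_and_unmethylated_vs_ns(bundle, truth, pipeline_result):
    merged = pipeline_result.merged
    hk_cp = merged.loc[pipeline_result.hk_cp_ids]
    ns = pipeline_result.negative_samples
    m_hk = annotate_methylation(hk_cp, bundle.cpg_table, 1_000)
    m_ns = annotate_methylation(ns, bundle.cpg_table, 1_000)
    p_count = stats.mannwhitneyu(
        m_hk["cpg_count"], m_ns["cpg_count"], alternative="greater"
    ).pvalue
    assert p_count < 0.01
    meth_hk = m_hk["methylation_mean"].dropna()
    meth_ns = m_ns["methylation_mean"].dropna()
    p_meth = stats.mannwhitneyu(meth_hk, meth_ns, alternative="less").pvalue
    assert p_meth < 0.01


def test_promoter_h3k4me3_exceeds_enhancer_h3k4me3(pipeline_result, truth):
    from hkcre.synthetic import _match_mask

    annot = pipeline_result.annotations
    merged = pipeline_result.merged
    m = _match_mask(merged, truth.loci, 100)
    klass = np.where(m.any(1), truth.loci["klass"].to_numpy()[m.argmax(1)], "none")
    k4me3 = annot["h3k4me3"].to_numpy()
    promoter = k4me3[klass == "HK_CP"]
    enhancer = k4me3[np.isin(klass, ["HK_other", "CTS"])]
    assert stats.mannwhitneyu(promoter, enhancer, alternative="greater").pvalue < 0.01
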