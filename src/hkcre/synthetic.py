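"""Synthetic miniature dataset with planted ground truth.

The generator emulates the statistical structure of the real multi-omics
corpus the pipeline targets, at desk scale: a small genome with loci that
are active in essentially all healthy cell types (housekeeping, HK), loci
active in only a few (cell-type-specific, CTS), and signal-free decoys that
mimic the negative background; promoter-like vs enhancer-like histone
signatures; dense unmethylated CpG clusters at housekeeping promoters;
aberrant promoter methylation with reduced expression in cancer; and
patient cohorts whose survival hazard differs between expression strata.

Everything is a deterministic function of (config, seed).  What the
generator deliberately does *not* model is documented in docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .intervals import ChromSizes, RegionSet
from . import io as hio

__all__ = ["SyntheticConfig", "TruthTable", "SyntheticBundle", "generate", "evaluate_recovery"]

MARKS = ["h3k27ac", "h3k4me3", "h3k4me1"]


@dataclass
class SyntheticConfig:
    """Scale and effect sizes of the planted dataset."""

    n_chroms: int = 2
    chrom_length_bp: int = 10_000_000
    locus_spacing_bp: int = 8_000       # minimum spacing between planted loci
    chrom_margin_bp: int = 50_000       # keep loci away from chromosome ends

    n_train_cells: int = 20             # healthy cell types used for discovery
    n_validate_cells: int = 7           # healthy cell types held out for validation
    n_cancer_cells: int = 6

    n_genes: int = 200
    n_hk_cp: int = 60                   # HK loci planted at gene TSSs (promoter class)
    n_hk_other: int = 40                # HK loci away from any TSS
    n_cts: int = 400
    n_decoys: int = 100
    n_hkg: int = 40                     # HK_CP genes catalogued as housekeeping genes
    n_cancer_silenced: int = 10         # HK_CP loci methylated/silenced in cancer

    region_length_bp: int = 500
    jitter_bp: int = 10                 # positional jitter of a locus across cell types
    cts_max_cells: int = 3
    hk_fraction: float = 0.90           # minimum healthy presence of an HK locus
    hk_presence_prob: float = 0.97      # per-cell activity probability of an HK locus

    n_histone_samples: int = 3          # ChIP samples per mark
    peak_width_bp: int = 700
    n_background_peaks: int = 250       # noise peaks per ChIP sample

    n_atlas_cells: int = 10             # methylation-atlas cell types (CpG columns)
    cpg_sites_per_promoter: int = 15
    n_background_cpg: int = 4_000

    n_healthy_expr_samples: int = 12
    n_cancer_expr_samples: int = 8
    cancer_min_fold_down: float = 4.0   # minimum TPM fold reduction of silenced genes

    n_projects: int = 4                 # patient cohorts
    samples_per_project: int = 80
    hazard_ratio: float = 3.0           # LOW/HIGH hazard ratio of survival times
    base_hazard: float = 1e-3           # events per day for the HIGH stratum
    censor_time_days: float = 3_000.0

    def __post_init__(self) -> None:
        if self.n_train_cells < 5:
            raise ValueError("need at least 5 healthy training cell types")
        if self.n_hk_cp + self.n_hkg == 0 or self.n_hkg > self.n_hk_cp:
            raise ValueError("n_hkg must be <= n_hk_cp")
        if self.n_cancer_silenced > self.n_hk_cp:
            raise ValueError("cancer_silenced loci must be a subset of HK_CP loci")
        if not 0 < self.hk_fraction <= 1:
            raise ValueError("hk_fraction must lie in (0, 1]")

    def pipeline_config(self, **overrides) -> PipelineConfig:
        """A PipelineConfig scaled to this miniature genome.

        The negative-sample count is reduced from the full-genome default:
        a 20 Mb toy genome only holds a few hundred inter-CRE gaps of 3 kb
        or more.
        """
        defaults = dict(ns_count=400, hk_fraction=self.hk_fraction)
        defaults.update(overrides)
        return PipelineConfig(**defaults)


@dataclass
class TruthTable:
    """Planted ground truth: loci, presence design and cancer silencing."""

    loci: pd.DataFrame                 # locus_id, chrom, position, klass, gene_id
    presence: pd.DataFrame             # loci x cell types, boolean
    cancer_silenced: list              # locus ids (subset of HK_CP)
    suppressor_genes: list             # genes of the silenced promoters used downstream
    hkg_genes: list

    def loci_of_class(self, *klasses) -> pd.DataFrame:
        return self.loci[self.loci["klass"].isin(klasses)]


@dataclass
class SyntheticBundle:
    """All generated tables, coordinate-consistent with one ChromSizes."""

    chrom_sizes: ChromSizes
    cell_regions: dict                 # cell id -> RegionSet (with ABC scores)
    train_cells: list
    validate_cells: list
    cancer_cells: list
    histone_peaks: dict                # mark -> {sample id -> peak DataFrame}
    tss_table: pd.DataFrame            # gene_id, biotype, chrom, tss, strand, is_hkg
    conservation: pd.DataFrame         # chrom, start, end, score
    cpg_table: pd.DataFrame            # chrom, pos, one column per atlas cell
    expr_healthy: pd.DataFrame         # genes x samples, TPM
    expr_cancer: pd.DataFrame
    depmap_like: pd.DataFrame          # sample_id, label, gene_id, promoter_methylation, tpm
    tcga_expr: pd.DataFrame            # samples x suppressor genes, TPM
    clinical: pd.DataFrame             # sample_id, project, vital_status, days_to_*
    term_sets: dict                    # term -> gene list (planted asymmetric enrichment)

    def write(self, outdir: str | Path) -> None:
        """Write the bundle as plain BED/TSV files into a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.chrom_sizes.to_file(outdir / "chrom.sizes")
        cells_dir = outdir / "cells"
        cells_dir.mkdir(exist_ok=True)
        for cell, rs in self.cell_regions.items():
            hio.write_regions(rs, cells_dir / f"{cell}.tsv")
        for mark, samples in self.histone_peaks.items():
            mark_dir = outdir / "histone" / mark
            mark_dir.mkdir(parents=True, exist_ok=True)
            for sample, peaks in samples.items():
                peaks.to_csv(mark_dir / f"{sample}.tsv", sep="\t", index=False)
        self.tss_table.to_csv(outdir / "tss.tsv", sep="\t", index=False)
        self.conservation.to_csv(outdir / "conservation.bedgraph.tsv", sep="\t", index=False)
        self.cpg_table.to_csv(outdir / "cpg_methylation.tsv", sep="\t", index=False)
        self.expr_healthy.to_csv(outdir / "expr_healthy_tpm.tsv", sep="\t")
        self.expr_cancer.to_csv(outdir / "expr_cancer_tpm.tsv", sep="\t")
        self.depmap_like.to_csv(outdir / "cellline_meth_expr.tsv", sep="\t", index=False)
        self.tcga_expr.to_csv(outdir / "cohort_expr_tpm.tsv", sep="\t")
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
        with open(outdir / "cohorts.txt", "w") as fh:
            for group, cells in (
                ("train", self.train_cells),
                ("validate", self.validate_cells),
                ("cancer", self.cancer_cells),
            ):
                for c in cells:
                    fh.write(f"{group}\t{c}\n")


def _place_loci(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign every planted locus and free gene a distinct genomic slot."""
    slots = []
    for i in range(cfg.n_chroms):
        chrom = f"chr{i + 1}"
        lo = cfg.chrom_margin_bp
        hi = cfg.chrom_length_bp - cfg.chrom_margin_bp
        positions = np.arange(lo, hi, cfg.locus_spacing_bp)
        slots.extend((chrom, int(p)) for p in positions)
    n_free_genes = cfg.n_genes - cfg.n_hk_cp
    needed = cfg.n_hk_cp + cfg.n_hk_other + cfg.n_cts + cfg.n_decoys + n_free_genes
    if needed > len(slots):
        raise ValueError(
            f"infeasible geometry: {needed} loci do not fit in "
            f"{len(slots)} available slots; enlarge the genome or spacing"
        )
    pick = rng.choice(len(slots), size=needed, replace=False)
    # jitter within the slot so positions are continuous, not lattice-quantized
    wiggle = cfg.locus_spacing_bp // 3
    chosen = [
        (c, int(p + rng.integers(-wiggle, wiggle + 1))) for c, p in (slots[i] for i in pick)
    ]
    klasses = (
        ["HK_CP"] * cfg.n_hk_cp
        + ["HK_other"] * cfg.n_hk_other
        + ["CTS"] * cfg.n_cts
        + ["decoy"] * cfg.n_decoys
        + ["free_gene"] * n_free_genes
    )
    df = pd.DataFrame(chosen, columns=["chrom", "position"])
    df["klass"] = klasses
    return df


def generate(config: SyntheticConfig | None = None, seed: int = 0):
    """Generate a full bundle plus its truth table; deterministic in (config, seed)."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    chrom_sizes = ChromSizes(
        {f"chr{i + 1}": cfg.chrom_length_bp for i in range(cfg.n_chroms)}
    )

    layout = _place_loci(cfg, rng)
    is_locus = layout["klass"] != "free_gene"
    loci = layout[is_locus].reset_index(drop=True).copy()
    loci["locus_id"] = [f"locus_{i:04d}" for i in range(len(loci))]

    # --- genes: HK_CP loci sit at gene TSSs; free genes get their own slots ---
    genes = []
    hk_cp_rows = loci[loci["klass"] == "HK_CP"]
    free_rows = layout[layout["klass"] == "free_gene"]
    gid = 0
    for _, row in hk_cp_rows.iterrows():
        genes.append((f"g{gid:04d}", row["chrom"], int(row["position"]), row["locus_id"]))
        gid += 1
    for _, row in free_rows.iterrows():
        genes.append((f"g{gid:04d}", row["chrom"], int(row["position"]), None))
        gid += 1
    gene_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "tss", "at_locus"])
    gene_df["strand"] = rng.choice(["+", "-"], size=len(gene_df))
    # TSS offset from the promoter center, well inside the association radius
    at_promoter = gene_df["at_locus"].notna()
    gene_df.loc[at_promoter, "tss"] += rng.integers(-100, 101, size=at_promoter.sum())

    hk_cp_gene_ids = gene_df.loc[at_promoter, "gene_id"].tolist()
    hkg_genes = sorted(rng.choice(hk_cp_gene_ids, size=cfg.n_hkg, replace=False))
    biotype = np.where(
        gene_df["gene_id"].isin(hkg_genes),
        "protein_coding",
        rng.choice(
            ["protein_coding", "lncRNA", "pseudogene", "misc_RNA"],
            size=len(gene_df),
            p=[0.80, 0.12, 0.06, 0.02],
        ),
    )
    gene_df["biotype"] = biotype
    gene_df["is_hkg"] = gene_df["gene_id"].isin(hkg_genes)
    tss_table = gene_df[["gene_id", "biotype", "chrom", "tss", "strand", "is_hkg"]].copy()

    loci = loci.merge(
        gene_df.loc[at_promoter, ["at_locus", "gene_id"]].rename(
            columns={"at_locus": "locus_id"}
        ),
        on="locus_id",
        how="left",
    )

    # --- per-cell presence design ---
    train = [f"healthy_{i:02d}" for i in range(cfg.n_train_cells)]
    validate = [f"validate_{i:02d}" for i in range(cfg.n_validate_cells)]
    cancer = [f"cancer_{i:02d}" for i in range(cfg.n_cancer_cells)]
    all_cells = train + validate + cancer
    col_of = {c: j for j, c in enumerate(all_cells)}
    pres = np.zeros((len(loci), len(all_cells)), dtype=bool)

    silenced = sorted(
        rng.choice(loci.loc[loci["klass"] == "HK_CP", "locus_id"],
                   size=cfg.n_cancer_silenced, replace=False)
    )
    silenced_set = set(silenced)

    def _mark(i: int, cells: list, n_present: int) -> None:
        for c in rng.choice(cells, size=n_present, replace=False):
            pres[i, col_of[c]] = True

    for i, (lid, klass) in enumerate(zip(loci["locus_id"], loci["klass"])):
        if klass in ("HK_CP", "HK_other"):
            # HK loci are active in essentially every healthy cell; binomial
            # presence floored at the HK definition keeps the invariant while
            # letting counts plateau under cell-type subsampling
            for cohort in (train, validate):
                lo = math.ceil(cfg.hk_fraction * len(cohort))
                n = max(int(rng.binomial(len(cohort), cfg.hk_presence_prob)), lo)
                _mark(i, cohort, n)
            if lid in silenced_set:
                n = int(rng.integers(0, 2))  # nearly absent from cancer cells
            else:
                lo = math.ceil(cfg.hk_fraction * len(cancer))
                n = int(rng.integers(lo, len(cancer) + 1))
            _mark(i, cancer, n)
        elif klass == "CTS":
            _mark(i, train, int(rng.integers(1, cfg.cts_max_cells + 1)))
            for cohort in (validate, cancer):
                _mark(i, cohort, int(rng.integers(0, cfg.cts_max_cells + 1)))
        else:  # decoy: a couple of healthy training cells only
            _mark(i, train, int(rng.integers(1, 3)))
    presence = pd.DataFrame(pres, index=loci["locus_id"], columns=all_cells)

    # --- per-cell region tables with ABC scores ---
    half = cfg.region_length_bp // 2
    locus_pos = dict(zip(loci["locus_id"], loci["position"]))
    locus_chrom = dict(zip(loci["locus_id"], loci["chrom"]))
    locus_gene = dict(zip(loci["locus_id"], loci["gene_id"]))
    cell_regions = {}
    for cell in all_cells:
        active = presence.index[presence[cell].to_numpy()]
        rows = []
        for lid in active:
            jitter = int(rng.integers(-cfg.jitter_bp, cfg.jitter_bp + 1))
            start = locus_pos[lid] - half + jitter
            score = 0.015 + float(rng.exponential(0.05))
            gene = locus_gene.get(lid)
            rows.append(
                (
                    locus_chrom[lid],
                    start,
                    start + cfg.region_length_bp,
                    score,
                    gene if isinstance(gene, str) else "",
                    lid,
                )
            )
        # sub-threshold ABC rows that the significance filter must discard
        for _ in range(30):
            chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
            start = int(rng.integers(0, cfg.chrom_length_bp - cfg.region_length_bp))
            rows.append(
                (chrom, start, start + cfg.region_length_bp,
                 float(rng.uniform(0.001, 0.0149)), "", "")
            )
        df = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "score", "target_gene", "source_locus"]
        )
        df["cell_type"] = cell
        cell_regions[cell] = RegionSet(df)

    # --- histone ChIP peaks -------------------------------------------------
    # log-space mean signal per (class, mark); promoter-like loci carry
    # H3K27ac+H3K4me3, enhancer-like loci H3K27ac+H3K4me1; decoys only ever
    # see background noise.
    signal_mu = {
        "HK_CP": {"h3k27ac": 3.0, "h3k4me3": 3.0, "h3k4me1": None},
        "HK_other": {"h3k27ac": 2.2, "h3k4me3": None, "h3k4me1": 3.0},
        "CTS": {"h3k27ac": 2.2, "h3k4me3": None, "h3k4me1": 3.0},
        "decoy": {"h3k27ac": None, "h3k4me3": None, "h3k4me1": None},
    }
    histone_peaks: dict = {}
    pw = cfg.peak_width_bp
    for mark in MARKS:
        samples = {}
        for s in range(cfg.n_histone_samples):
            rows = []
            for _, row in loci.iterrows():
                mu = signal_mu[row["klass"]][mark]
                if mu is None:
                    continue
                center = int(row["position"]) + int(rng.integers(-50, 51))
                sig = float(np.exp(rng.normal(mu, 0.3)))
                rows.append((row["chrom"], center - pw // 2, center + pw - pw // 2, sig))
            for _ in range(cfg.n_background_peaks):
                chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
                start = int(rng.integers(0, cfg.chrom_length_bp - pw))
                rows.append((chrom, start, start + pw, float(np.exp(rng.normal(0.5, 0.5)))))
            samples[f"{mark}_s{s}"] = pd.DataFrame(
                rows, columns=["chrom", "start", "end", "signal"]
            )
        histone_peaks[mark] = samples

    # --- conservation track -------------------------------------------------
    cons_rows = []
    for _, row in loci.iterrows():
        high = row["klass"] in ("HK_CP", "HK_other")
        score = float(np.clip(rng.normal(0.85 if high else 0.3, 0.05), 0, 1))
        p = int(row["position"])
        cons_rows.append((row["chrom"], p - 600, p + 600, score))
    for _ in range(2_000):
        chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
        start = int(rng.integers(0, cfg.chrom_length_bp - 500))
        cons_rows.append(
            (chrom, start, start + 500, float(np.clip(rng.normal(0.1, 0.05), 0, 1)))
        )
    conservation = pd.DataFrame(cons_rows, columns=["chrom", "start", "end", "score"])

    # --- CpG methylation atlas ---------------------------------------------
    atlas_cols = [f"atlas_{i:02d}" for i in range(cfg.n_atlas_cells)]
    cpg_rows = []
    for _, row in loci.iterrows():
        if row["klass"] != "HK_CP":
            continue
        p = int(row["position"])
        offsets = rng.integers(-450, 451, size=cfg.cpg_sites_per_promoter)
        for off in offsets:
            fracs = rng.uniform(0.0, 0.15, size=cfg.n_atlas_cells)
            cpg_rows.append((row["chrom"], p + int(off), *fracs))
    for _ in range(cfg.n_background_cpg):
        chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
        pos = int(rng.integers(0, cfg.chrom_length_bp))
        fracs = rng.uniform(0.3, 0.9, size=cfg.n_atlas_cells)
        cpg_rows.append((chrom, pos, *fracs))
    cpg_table = pd.DataFrame(cpg_rows, columns=["chrom", "pos", *atlas_cols])
    cpg_table = cpg_table.sort_values(["chrom", "pos"]).reset_index(drop=True)

    # --- expression matrices (TPM) ------------------------------------------
    gene_ids = tss_table["gene_id"].tolist()
    hkg_set = set(hkg_genes)
    hk_cp_set = set(hk_cp_gene_ids)
    silenced_genes = sorted(locus_gene[l] for l in silenced)
    suppressors = silenced_genes[:4]

    # gene-intrinsic baselines shared between cohorts; silencing divides the
    # cancer level by at least cancer_min_fold_down on top of the baseline
    gene_mu, gene_dropout = {}, {}
    for g in gene_ids:
        if g in hkg_set:
            base, dropout = 4.0, 0.0
        elif g in hk_cp_set:
            base, dropout = 2.0, 0.3
        else:
            base, dropout = 1.5, 0.4
        gene_mu[g] = float(rng.normal(base, 0.6))
        gene_dropout[g] = dropout
    silence_factor = {
        g: cfg.cancer_min_fold_down * float(rng.uniform(1.0, 2.5))
        for g in silenced_genes
    }

    def _expr_matrix(sample_names: list, cancer_mode: bool) -> pd.DataFrame:
        data = np.zeros((len(gene_ids), len(sample_names)))
        for i, g in enumerate(gene_ids):
            x = np.exp(rng.normal(gene_mu[g], 0.4, size=len(sample_names)))
            x[rng.random(len(sample_names)) < gene_dropout[g]] = 0.0
            if cancer_mode and g in silence_factor:
                x = x / silence_factor[g]
            data[i] = x
        return pd.DataFrame(data, index=gene_ids, columns=sample_names)

    expr_healthy = _expr_matrix(
        [f"healthy_expr_{i:02d}" for i in range(cfg.n_healthy_expr_samples)], False
    )
    expr_cancer = _expr_matrix(
        [f"cancer_expr_{i:02d}" for i in range(cfg.n_cancer_expr_samples)], True
    )

    # --- cell-line promoter methylation vs expression ------------------------
    dep_rows = []
    for g in suppressors:
        for i in range(10):
            dep_rows.append(
                (f"line_n{i:02d}", "Normal", g,
                 float(rng.uniform(0.0, 0.1)), float(np.exp(rng.normal(3.5, 0.3))))
            )
        for i in range(30):
            dep_rows.append(
                (f"line_c{i:02d}", "Cancer", g,
                 float(rng.uniform(0.5, 0.9)), float(np.exp(rng.normal(1.0, 0.5))))
            )
    depmap_like = pd.DataFrame(
        dep_rows, columns=["sample_id", "label", "gene_id", "promoter_methylation", "tpm"]
    )

    # --- patient cohorts: expression, strata truth and survival --------------
    sample_ids, projects, latent = [], [], []
    for p in range(cfg.n_projects):
        for s in range(cfg.samples_per_project):
            sample_ids.append(f"P{p:02d}_s{s:03d}")
            projects.append(f"P{p:02d}")
            latent.append(rng.normal())
    latent = np.array(latent)
    project_offset = {f"P{p:02d}": rng.normal(2.0, 0.8) for p in range(cfg.n_projects)}
    tcga = {}
    for g in suppressors:
        vals = [
            np.exp(project_offset[pr] + 0.9 * u + rng.normal(0, 0.3))
            for pr, u in zip(projects, latent)
        ]
        tcga[g] = vals
    tcga_expr = pd.DataFrame(tcga, index=sample_ids)

    high = latent >= np.quantile(latent, 0.75)
    hazard = np.where(high, cfg.base_hazard, cfg.base_hazard * cfg.hazard_ratio)
    event_time = rng.exponential(1.0 / hazard)
    deceased = event_time < cfg.censor_time_days
    observed = np.minimum(event_time, cfg.censor_time_days)
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "project": projects,
            "vital_status": np.where(deceased, "Dead", "Alive"),
            "days_to_death": np.where(deceased, observed.round(1), np.nan),
            "days_to_last_follow_up": np.where(deceased, np.nan, observed.round(1)),
        }
    )

    # --- planted asymmetric functional terms ---------------------------------
    nonhkg_assoc = sorted(hk_cp_set - hkg_set)
    other_genes = sorted(set(gene_ids) - hk_cp_set)

    def _draw(pool, n):
        return sorted(rng.choice(sorted(pool), size=min(n, len(pool)), replace=False))

    term_sets = {
        "hk_metabolism": _draw(hkg_set, 30) + _draw(other_genes, 5),
        "transcription_regulation": nonhkg_assoc[:15] + _draw(other_genes, 5),
        "shared_housekeeping": _draw(hkg_set, 15) + nonhkg_assoc[:10],
        "unrelated_process": _draw(other_genes, 30),
    }

    truth = TruthTable(
        loci=loci[["locus_id", "chrom", "position", "klass", "gene_id"]],
        presence=presence,
        cancer_silenced=silenced,
        suppressor_genes=suppressors,
        hkg_genes=list(hkg_genes),
    )
    bundle = SyntheticBundle(
        chrom_sizes=chrom_sizes,
        cell_regions=cell_regions,
        train_cells=train,
        validate_cells=validate,
        cancer_cells=cancer,
        histone_peaks=histone_peaks,
        tss_table=tss_table,
        conservation=conservation,
        cpg_table=cpg_table,
        expr_healthy=expr_healthy,
        expr_cancer=expr_cancer,
        depmap_like=depmap_like,
        tcga_expr=tcga_expr,
        clinical=clinical,
        term_sets=term_sets,
    )
    return bundle, truth


def _match_mask(called: pd.DataFrame, loci: pd.DataFrame, slack_bp: int):
    """Boolean (calls x loci) match matrix: locus position within slack of the call."""
    m = np.zeros((len(called), len(loci)), dtype=bool)
    c_chrom = called["chrom"].to_numpy()
    c_start = called["start"].to_numpy()
    c_end = called["end"].to_numpy()
    for j, row in enumerate(loci.itertuples(index=False)):
        same = c_chrom == row.chrom
        m[:, j] = same & (c_start - slack_bp <= row.position) & (row.position < c_end + slack_bp)
    return m


def evaluate_recovery(
    called_regions: pd.DataFrame,
    truth: TruthTable,
    slack_bp: int = 100,
) -> pd.DataFrame:
    """Per-class precision/recall of called regions against planted loci.

    A call matches a planted locus when the locus position falls within
    ``slack_bp`` of the call interval.  HK calls (``is_hk`` True) are scored
    against planted HK loci (promoter and non-promoter alike), non-HK calls
    against CTS loci; the decoy row reports how many decoys are touched by
    any call at all (precision is reported as NaN there).
    """
    if slack_bp < 0:
        raise ValueError("slack_bp must be >= 0")
    rows = {}
    specs = {
        "HK": (("HK_CP", "HK_other"), "hk"),
        "CTS": (("CTS",), "cts"),
        "decoy": (("decoy",), "any"),
    }
    for name, (klasses, mode) in specs.items():
        loci = truth.loci_of_class(*klasses)
        if mode == "hk":
            calls = called_regions[called_regions.get("is_hk", False) == True]  # noqa: E712
        elif mode == "cts":
            calls = called_regions[called_regions.get("is_hk", True) == False]  # noqa: E712
        else:
            calls = called_regions
        if len(calls) == 0 or len(loci) == 0:
            rows[name] = {"precision": np.nan if len(calls) == 0 else 0.0,
                          "recall": 0.0 if len(loci) else np.nan,
                          "n_calls": len(calls), "n_loci": len(loci)}
            continue
        m = _match_mask(calls, loci, slack_bp)
        precision = float(m.any(axis=1).mean()) if mode != "any" else np.nan
        recall = float(m.any(axis=0).mean())
        rows[name] = {
            "precision": precision,
            "recall": recall,
            "n_calls": len(calls),
            "n_loci": len(loci),
        }
    return pd.DataFrame(rows).T
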