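"""Negative-sample-guided filtering and rule-based CRE class assignment.

The filtering step embeds regions and negative samples (NS) in a shared
feature space (three histone marks + log distance to nearest TSS), clusters
them with Louvain on a kNN graph, and recursively dissects any cluster whose
NS fraction is suspiciously high, removing regions from sub-clusters
dominated by NS.

Classification maps each surviving cluster's mean feature profile to one of
nine reference CRE classes defined by a (histone signature, distance
category) combination: core promoters (CP), promoters (P), enhancers at
short/long/super-long distance (ESD/ELD/ESLD), inactive short-distance
enhancers (ESDi), low-signal regions at medium/long distance (OMD/OLD), and
an H3K4me1-negative group.
"""

from __future__ import annotations

import random
import warnings

import igraph as ig
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .config import PipelineConfig

__all__ = [
    "SIGNATURES",
    "feature_matrix",
    "embed_pca",
    "cluster_louvain",
    "iterative_ns_filter",
    "classify_regions",
    "class_percentages",
]

FEATURES = ["h3k27ac", "h3k4me3", "h3k4me1", "dntss_bp"]

#: symbolic levels of a discretized mark, low to high
_LEVELS = ["zero", "-", "+/-", "+", "++"]

#: distance categories, near to far
_DISTANCE_CATEGORIES = ["very_short", "short", "intermediate", "long", "very_long"]

#: reference class signatures: (H3K27ac, H3K4me3, H3K4me1, distance category, reference count)
SIGNATURES = {
    "CP": ("+", "+", "-", "very_short", 28_968),
    "P": ("++", "++", "-", "short", 24_233),
    "ESD": ("+", "+/-", "++", "intermediate", 11_445),
    "ELD": ("+/-", "-", "+", "long", 32_564),
    "ESLD": ("+", "-", "+", "very_long", 8_063),
    "ESDi": ("-", "-", "+", "intermediate", 5_975),
    "OMD": ("-", "-", "-", "intermediate", 5_109),
    "OLD": ("-", "-", "-", "long", 19_563),
    "H3K4me1_negative": ("+/-", "+/-", "zero", "short", 745),
}


def feature_matrix(
    annotations: pd.DataFrame,
    features=FEATURES,
    strict: bool = True,
) -> pd.DataFrame:
    """Column-standardized feature matrix (mean 0, variance 1).

    ``dntss_bp`` is log(1+d)-transformed before z-scoring.  A zero-variance
    column is an error when ``strict``; otherwise it is centered only (the
    tolerant mode used inside recursive sub-clustering, where a feature can
    collapse to a constant).
    """
    unknown = [f for f in features if f not in annotations.columns]
    if unknown:
        raise ValueError(f"missing feature column(s): {unknown}")
    mat = annotations[list(features)].astype(float).copy()
    if "dntss_bp" in mat.columns:
        mat["dntss_bp"] = np.log1p(mat["dntss_bp"])
    for col in mat.columns:
        x = mat[col].to_numpy()
        sd = x.std()
        if sd == 0:
            if strict:
                raise ValueError(f"feature {col!r} has zero variance")
            mat[col] = x - x.mean()
        else:
            mat[col] = (x - x.mean()) / sd
    return mat


def embed_pca(matrix: pd.DataFrame, n_pcs: int, fit_on: pd.DataFrame | None = None):
    """Project onto the top principal axes.

    Fits on ``fit_on`` when given (e.g. NS rows only) and projects ``matrix``;
    otherwise fits on ``matrix`` itself.  Returns (embedding, explained
    variance ratios) — the variance report replaces interactive PC selection.
    """
    n_pcs = min(n_pcs, matrix.shape[1])
    pca = PCA(n_components=n_pcs, svd_solver="full")
    if fit_on is None:
        emb = pca.fit_transform(matrix.to_numpy())
    else:
        pca.fit(fit_on.to_numpy())
        emb = pca.transform(matrix.to_numpy())
    return emb, pca.explained_variance_ratio_


def cluster_louvain(
    embedding: np.ndarray,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Louvain community detection on a mutualized kNN graph.

    Edges connect each point to its ``k_neighbors`` nearest neighbors
    (symmetrized by union, weight 1).  igraph's multilevel modularity
    optimization is run under a seeded RNG, so labels are deterministic for a
    fixed seed.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = len(embedding)
    if n == 0:
        return np.array([], dtype=int)
    if k_neighbors < 2:
        raise ValueError("k_neighbors must be >= 2")
    # coincident points must co-cluster by definition: collapse duplicates
    # before building the graph and broadcast labels back afterwards
    unique, inverse = np.unique(embedding, axis=0, return_inverse=True)
    m = len(unique)
    if m == 1:
        return np.zeros(n, dtype=int)
    k = min(k_neighbors, m - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(unique)
    _, idx = nn.kneighbors(unique)
    edges = set()
    for i in range(m):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=m, edges=sorted(edges), directed=False)
    state = random.getstate()
    try:
        random.seed(seed)  # python-igraph draws from Python's random module
        part = g.community_multilevel(resolution=resolution)
    finally:
        random.setstate(state)
    membership = np.asarray(part.membership, dtype=int)
    return membership[inverse]


def iterative_ns_filter(
    annotations_regions: pd.DataFrame,
    annotations_ns: pd.DataFrame | None,
    config: PipelineConfig | None = None,
    features=FEATURES,
) -> pd.Index:
    """Remove regions indistinguishable from negative samples.

    Jointly standardize, embed and cluster regions + NS.  Any cluster whose
    NS fraction exceeds ``ns_suspicious_frac`` is re-analyzed on its own;
    within the recursion, regions in sub-clusters whose NS fraction exceeds
    ``ns_remove_frac`` are dropped.  Recursion continues until no suspicious
    cluster remains or ``max_filter_depth`` is hit (then the ambiguous
    cluster is retained with a warning).  Returns the surviving row index of
    ``annotations_regions``.
    """
    config = config or PipelineConfig()
    if annotations_ns is None or len(annotations_ns) == 0:
        return annotations_regions.index

    keep: set = set()

    def _analyze(reg: pd.DataFrame, ns: pd.DataFrame, depth: int) -> None:
        if len(ns) == 0:
            keep.update(reg.index)
            return
        if len(reg) == 0:
            return
        pooled = pd.concat(
            [reg[list(features)], ns[list(features)]], ignore_index=False
        )
        n_points = len(pooled)
        min_splittable = max(config.knn + 2, 10)
        mat = feature_matrix(pooled, features, strict=False)
        if config.pca_fit_on == "ns" and len(ns) >= 2:
            emb, _ = embed_pca(mat, config.n_pcs, fit_on=mat.iloc[len(reg):])
        else:
            emb, _ = embed_pca(mat, config.n_pcs)
        labels = cluster_louvain(emb, config.knn, config.louvain_resolution, config.rng_seed)
        is_ns = np.zeros(n_points, dtype=bool)
        is_ns[len(reg):] = True
        for c in np.unique(labels):
            members = labels == c
            ns_frac = is_ns[members].mean()
            reg_ids = pooled.index[members & ~is_ns]
            ns_ids = pooled.index[members & is_ns]
            if ns_frac <= config.ns_suspicious_frac:
                keep.update(reg_ids)
            elif depth >= 1 and ns_frac > config.ns_remove_frac:
                continue  # dominated by NS: drop its regions
            elif depth + 1 > config.max_filter_depth:
                warnings.warn(
                    "max filter depth reached; retaining ambiguous cluster", stacklevel=2
                )
                keep.update(reg_ids)
            elif members.sum() < min_splittable or len(np.unique(labels)) == 1:
                # cannot be subdivided further: apply the removal rule directly
                if ns_frac > config.ns_remove_frac:
                    continue
                keep.update(reg_ids)
            else:
                _analyze(reg.loc[reg_ids], ns.loc[ns_ids], depth + 1)

    _analyze(annotations_regions, annotations_ns, 0)
    return annotations_regions.index[[i in keep for i in annotations_regions.index]]


def _discretize_mark(z: float, raw_absent: bool, config: PipelineConfig) -> str:
    if raw_absent:
        return "zero"
    if z >= config.z_doubleplus:
        return "++"
    if z >= config.z_plus:
        return "+"
    if z > -config.z_plus:
        return "+/-"
    return "-"


def _distance_category(median_dntss: float, config: PipelineConfig) -> str:
    for cat, edge in zip(_DISTANCE_CATEGORIES, config.distance_bins_bp):
        if median_dntss < edge:
            return cat
    return _DISTANCE_CATEGORIES[-1]


def classify_regions(
    cluster_profiles: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.Series:
    """Assign each cluster the nearest reference class.

    ``cluster_profiles`` must carry per-cluster mean z-scores (``h3k27ac``,
    ``h3k4me3``, ``h3k4me1``), the median distance ``dntss_bp`` and optional
    boolean ``<mark>_absent`` columns flagging clusters with no raw signal at
    all (discretized to the 'zero' level).

    Matching cost is the Hamming distance on the three discretized marks plus
    ``distance_category_weight`` times the ordinal difference of the distance
    category; the distance term carries extra weight because it is what
    separates otherwise-similar promoter-like signatures.  Ties go to the
    signature with the larger reference count.
    """
    config = config or PipelineConfig()
    if len(cluster_profiles) == 0:
        raise ValueError("no cluster profiles supplied")
    marks = ["h3k27ac", "h3k4me3", "h3k4me1"]
    labels = {}
    for cluster_id, row in cluster_profiles.iterrows():
        prof = [
            _discretize_mark(
                float(row[m]), bool(row.get(f"{m}_absent", False)), config
            )
            for m in marks
        ]
        cat = _distance_category(float(row["dntss_bp"]), config)
        cat_ord = _DISTANCE_CATEGORIES.index(cat)
        best_label, best_cost = None, None
        for label, (k27, k4me3, k4me1, sig_cat, count) in SIGNATURES.items():
            cost = sum(a != b for a, b in zip(prof, (k27, k4me3, k4me1)))
            cost += config.distance_category_weight * abs(
                cat_ord - _DISTANCE_CATEGORIES.index(sig_cat)
            )
            key = (cost, -count)
            if best_cost is None or key < best_cost:
                best_cost, best_label = key, label
        labels[cluster_id] = best_label
    return pd.Series(labels, name="class_label")


def class_percentages(counts: dict | pd.Series) -> pd.Series:
    """Percentage of total per class, rounded to two decimals."""
    counts = pd.Series(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total count must be > 0")
    return (100.0 * counts / total).round(2)
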