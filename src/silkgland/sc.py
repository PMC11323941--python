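"""Single-cell analysis: QC, normalization, clustering, markers, part calls.

Normalization is negative-binomial Pearson residuals with a fixed dispersion
(a regularized-residual transform in the SCTransform spirit); clustering is
k-means on top principal components with silhouette-based model selection.
Cluster-to-part assignment tests marker overlap with the bulk gene-set part
lists by hypergeometric enrichment.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ValidationError

NB_THETA = 100.0  # fixed NB size parameter for Pearson residuals


def qc_filter(cells: ExpressionMatrix, min_genes: int = 300, min_counts: int = 500,
              min_cells_per_sample: int = 500):
    """Remove low-complexity cells, then under-populated samples.

    Cells with fewer than ``min_genes`` expressed genes and/or less than
    ``min_counts`` total transcripts are removed (strict inequalities:
    a cell at exactly the threshold is kept).  Samples must retain more
    than ``min_cells_per_sample`` cells to survive.
    """
    counts = cells.values
    n_genes = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    keep = (n_genes >= min_genes) & (totals >= min_counts)
    kept = cells.subset_units(cells.units[keep])
    if kept.n_units == 0:
        raise ValidationError("QC removed all cells")
    if kept.unit_meta is not None and "sample" in kept.unit_meta:
        sizes = kept.unit_meta["sample"].value_counts()
        good = sizes.index[sizes > min_cells_per_sample]
        keep_units = kept.unit_meta.index[kept.unit_meta["sample"].isin(good)]
        kept = kept.subset_units([u for u in kept.units if u in set(keep_units)])
        if kept.n_units == 0:
            raise ValidationError("QC removed all samples")
    cell_table = pd.DataFrame({
        "cell_id": kept.units,
        "sample": kept.unit_meta["sample"].to_numpy() if kept.unit_meta is not None
        and "sample" in kept.unit_meta else "s1",
        "n_genes_detected": (kept.values > 0).sum(axis=0).to_numpy(),
        "total_counts": kept.values.sum(axis=0).to_numpy(),
    }).set_index("cell_id")
    return kept, cell_table


def normalize_cells(cells: ExpressionMatrix, theta: float = NB_THETA) -> ExpressionMatrix:
    """NB Pearson residuals with fixed dispersion, clipped to ±sqrt(n_cells).

    mu_gc = depth_c * rate_g with rate_g the gene's share of all counts;
    r = (x - mu) / sqrt(mu + mu^2/theta).
    """
    X = cells.values.to_numpy(dtype=float)
    depth = X.sum(axis=0)
    total = depth.sum()
    rate = X.sum(axis=1) / total
    mu = np.outer(rate, depth)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X - mu) / np.sqrt(mu + mu * mu / theta)
    r[~np.isfinite(r)] = 0.0
    clip = np.sqrt(X.shape[1])
    np.clip(r, -clip, clip, out=r)
    values = pd.DataFrame(r, index=cells.genes, columns=cells.units)
    return cells.with_values(values, "normalized")


def cluster_cells(cells: ExpressionMatrix, k: int | str = "auto",
                  n_pcs: int = 30, seed: int = 0,
                  k_range: tuple[int, int] = (4, 16),
                  silhouette_sample: int = 1000) -> pd.Series:
    """k-means over top principal components of the normalized matrix.

    ``k='auto'`` selects k in ``k_range`` by maximum mean silhouette
    (computed on a seeded subsample for tractability).  Deterministic for a
    fixed seed.
    """
    if cells.layer != "normalized":
        raise ValidationError("cluster_cells expects the normalized layer")
    n_cells = cells.n_units
    if isinstance(k, int) and k > n_cells:
        raise ValidationError(f"k={k} exceeds the number of cells ({n_cells})")
    X = cells.values.to_numpy(dtype=float).T  # cells x genes
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=int(seed)).fit_transform(X)
    if k == "auto":
        best_k, best_score = None, -np.inf
        for kk in range(k_range[0], min(k_range[1], n_cells - 1) + 1):
            labels = KMeans(n_clusters=kk, n_init=10, random_state=int(seed)).fit_predict(pcs)
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(
                pcs, labels,
                sample_size=min(silhouette_sample, n_cells),
                random_state=int(seed),
            )
            if score > best_score:
                best_k, best_score = kk, score
        k = best_k
    labels = KMeans(n_clusters=int(k), n_init=10, random_state=int(seed)).fit_predict(pcs)
    # relabel clusters by decreasing size -> contiguous ids from 0
    order = pd.Series(labels).value_counts().index.to_list()
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[v] for v in labels])
    return pd.Series(labels, index=cells.units, name="cluster")


def rank_markers(units: ExpressionMatrix, labels: pd.Series,
                 counts: ExpressionMatrix | None = None,
                 alpha: float = 0.05) -> dict[object, pd.DataFrame]:
    """One-vs-rest Wilcoxon rank-sum markers per group.

    The test runs on the matrix passed in (normalized values for cells,
    depth-normalized counts for spots); the log2 fold change uses
    depth-normalized counts with a pseudocount of 1 when ``counts`` is
    given, else the test matrix itself.  Markers: BH-adjusted p < ``alpha``
    and log2FC > 0, ranked by adjusted p.
    """
    labels = labels.loc[units.units]
    groups = labels.value_counts()
    if len(groups) < 2:
        raise ValidationError("rank_markers needs >= 2 groups")
    test_X = units.values.to_numpy(dtype=float)
    if counts is not None:
        depth = counts.values.sum(axis=0)
        norm = counts.values.div(depth, axis=1) * depth.median()
        fc_X = norm.to_numpy(dtype=float)
    else:
        fc_X = test_X
    out: dict[object, pd.DataFrame] = {}
    lab_arr = labels.to_numpy()
    for group in groups.index:
        if groups[group] < 2:
            warnings.warn(f"group {group!r} has a single unit; excluded", stacklevel=2)
            continue
        in_g = lab_arr == group
        a, b = test_X[:, in_g], test_X[:, ~in_g]
        with np.errstate(invalid="ignore"):
            stat, p = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
        p = np.where(np.isnan(p), 1.0, p)
        padj = multipletests(p, method="fdr_bh")[1]
        mean_in = fc_X[:, in_g].mean(axis=1)
        mean_out = fc_X[:, ~in_g].mean(axis=1)
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        table = pd.DataFrame({
            "p": p, "padj": padj, "log2fc": log2fc,
            "mean_in": mean_in, "mean_out": mean_out,
        }, index=units.genes)
        markers = table[(table["padj"] < alpha) & (table["log2fc"] > 0)]
        out[group] = markers.sort_values("padj", kind="mergesort")
        out[group].attrs["all_genes"] = table
    return out


def assign_clusters_to_parts(markers: dict, geneset_table: pd.DataFrame,
                             top_n: int = 100, alpha: float = 0.05,
                             part_col: str = "plsda_part") -> pd.DataFrame:
    """Assign each cluster to tail/sac/duct by marker-list enrichment.

    For each cluster and part, the overlap of the cluster's top markers
    with the part's gene list is tested against the gene-set universe by a
    hypergeometric test; BH across the parts within a cluster; the
    smallest-p part wins if adjusted p < ``alpha``, ties map to "none".
    """
    universe = geneset_table.index
    M = len(universe)
    parts = ("tail", "sac", "duct")
    part_sets = {p: set(geneset_table.index[geneset_table[part_col] == p]) for p in parts}
    rows = []
    for cluster, table in markers.items():
        top = [g for g in table.index[:top_n] if g in set(universe)]
        if not top:
            warnings.warn(f"cluster {cluster!r}: empty marker list", stacklevel=2)
            rows.append(dict(cluster=cluster, part="none",
                             **{f"p_{p}": np.nan for p in parts}))
            continue
        N = len(top)
        pvals = []
        for p in parts:
            n = len(part_sets[p])
            k = len(part_sets[p].intersection(top))
            pvals.append(float(stats.hypergeom.sf(k - 1, M, n, N)))
        padj = multipletests(pvals, method="fdr_bh")[1]
        best = np.min(padj)
        winners = [parts[i] for i in range(len(parts)) if padj[i] == best]
        if best < alpha and len(winners) == 1:
            assigned = winners[0]
        else:
            assigned = "none"
        rows.append(dict(cluster=cluster, part=assigned,
                         **{f"p_{p}": padj[i] for i, p in enumerate(parts)}))
    return pd.DataFrame(rows).set_index("cluster")


def run_single_cell_stage(cells: ExpressionMatrix, geneset_table: pd.DataFrame,
                          k: int | str = "auto", seed: int = 0) -> dict:
    """QC -> normalize -> cluster -> markers -> part assignment."""
    kept, cell_table = qc_filter(cells)
    norm = normalize_cells(kept)
    clusters = cluster_cells(norm, k=k, seed=seed)
    markers = rank_markers(norm, clusters, counts=kept)
    parts = assign_clusters_to_parts(markers, geneset_table)
    cell_table = cell_table.copy()
    cell_table["cluster"] = clusters
    cell_table["part"] = clusters.map(parts["part"]).fillna("none")
    return dict(matrix=kept, normalized=norm, cell_table=cell_table,
                clusters=clusters, markers=markers, cluster_parts=parts)
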