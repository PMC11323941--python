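"""Gland-specific gene-set inference from bulk RNA-seq.

The four-step filter: (1) keep genes loading toward the gland-bearing side
of a head-vs-body PCA; (2) keep genes loading toward the gland in a
gland-vs-body PCA, plus configured rescue genes; (3) PCA on tail/sac/duct
samples, keep genes whose two-component loading lies further than a cutoff
from the origin and label them by loading quadrant; (4) PLS-DA on the same
samples with cross-validated Q² and a second quadrant labelling.  A
one-vs-rest differential-expression step with stringent thresholds tops the
gene set up per part.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ValidationError

# Default cutoff on the two-component loading distance.  With loadings
# defined as cov(gene, unit-variance PC score), a structureless gene at NB
# dispersion alpha has log2-scale noise sd ~ sqrt(alpha)/ln2 and a
# two-component R^2 ~ Beta(1, (n_samples-3)/2); the default is the ~99th
# percentile of that null at alpha = 0.1, n = 15:
# 0.456 * sqrt(0.536) ~= 0.33.  Convention-bound: retune when the loading
# convention or the noise level differs.
DISTANCE_CUTOFF = 0.33


# ---------------------------------------------------------------------------
# Transformations


def compute_tpm(counts: ExpressionMatrix, lengths: pd.Series | None = None) -> ExpressionMatrix:
    """Transcripts per million: 1e6 * (count/length) / sum(count/length)."""
    lengths = lengths if lengths is not None else counts.gene_lengths
    if lengths is None:
        raise ValidationError("gene lengths are required for TPM")
    lengths = lengths.reindex(counts.genes)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValidationError("all gene lengths must be present and > 0")
    rate = counts.values.div(lengths, axis=0)
    depth = rate.sum(axis=0)
    zero = depth[depth == 0]
    if len(zero):
        raise ValidationError(f"zero-depth unit(s): {zero.index.tolist()}")
    tpm = rate.div(depth, axis=1) * 1e6
    return counts.with_values(tpm, "tpm")


def tpm_prefilter(counts: ExpressionMatrix, min_tpm: float = 4.0) -> ExpressionMatrix:
    """Keep genes with TPM > ``min_tpm`` in at least one sample."""
    tpm = compute_tpm(counts)
    keep = (tpm.values > min_tpm).any(axis=1)
    return counts.subset_genes(counts.genes[keep])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with a nonzero geometric mean."""
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValidationError("no gene has nonzero counts in every unit")
    logs = np.log(arr[positive])
    log_geo = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def vst(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Variance-flattening transform: log2(count / size_factor + 1).

    Size factors are DESeq-style median-of-ratios.  This is a deliberately
    simple stand-in for a parametric variance-stabilizing transform: it
    preserves the rank structure and flattens the mean-variance trend,
    which is all the downstream PCA/PLS filter relies on.
    """
    if counts.n_units < 2:
        raise ValidationError("VST needs at least two units")
    if not counts.values.to_numpy().any():
        raise ValidationError("all-zero count matrix")
    sf = size_factors(counts.values)
    transformed = np.log2(counts.values.div(sf, axis=1) + 1.0)
    return counts.with_values(transformed, "vst")


# ---------------------------------------------------------------------------
# PCA machinery

def _pca_loadings(values: pd.DataFrame, n_components: int = 2):
    """Covariance-mode PCA of units over genes.

    Returns (scores: units x k, loadings: genes x k) where loadings are
    eigenvector * sqrt(eigenvalue), i.e. the covariance between each gene
    and the unit-variance component score.  Genes with zero variance get
    zero loadings.
    """
    X = values.to_numpy(dtype=float).T  # units x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValidationError("degenerate PCA: zero variance")
    # SVD of the centered matrix; eigvals of covariance are s^2/(n-1)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(s))
    n = X.shape[0]
    sd = s[:k] / np.sqrt(n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = U[:, :k] * np.sqrt(n - 1)          # unit-variance scores
    loadings = Vt[:k].T * sd[None, :]               # genes x k
    loadings[Xc.var(axis=0) == 0, :] = 0.0          # constant genes load 0
    scores_df = pd.DataFrame(scores, index=values.columns,
                             columns=[f"PC{i+1}" for i in range(k)])
    load_df = pd.DataFrame(loadings, index=values.index,
                           columns=[f"PC{i+1}" for i in range(k)])
    return scores_df, load_df


def pca_quadrant_label(pc1: float, pc2: float) -> str:
    """Part label from step-3 PCA loading coordinates.

    tail (PC1 < 0, PC2 >= 0), sac (PC1 >= 0, PC2 >= 0), duct (PC2 < 0).
    """
    if pc2 < 0:
        return "duct"
    return "tail" if pc1 < 0 else "sac"


def plsda_quadrant_label(lv1: float, lv2: float) -> str:
    """Part label from PLS-DA loading coordinates.

    tail (LV1 < 0), sac (LV1 >= 0, LV2 <= 0), duct (LV1 >= 0, LV2 > 0).
    """
    if lv1 < 0:
        return "tail"
    return "duct" if lv2 > 0 else "sac"


def _rotate2(df: pd.DataFrame, theta: float) -> pd.DataFrame:
    # counterclockwise rotation of row vectors by theta
    c, s = np.cos(theta), np.sin(theta)
    rot = df.to_numpy() @ np.array([[c, s], [-s, c]])
    return pd.DataFrame(rot, index=df.index, columns=df.columns)


def _class_centroids(scores: pd.DataFrame, tissues: pd.Series) -> pd.DataFrame:
    return scores.groupby(tissues.to_numpy()).mean()


def pca_sign_filter(matrix: ExpressionMatrix, group_pos: str, group_neg: str,
                    rescue: list[str] | None = None) -> pd.Index:
    """Step-1/2 sign filter: genes loading toward ``group_pos`` on PC1.

    PC1 is oriented so that the ``group_pos`` (gland-side) samples have a
    positive mean score; genes with strictly positive PC1 loading are
    retained.  ``rescue`` genes are force-included.
    """
    meta = matrix.unit_meta
    units = meta.index[meta["tissue"].isin([group_pos, group_neg])]
    for g in (group_pos, group_neg):
        if (meta.loc[units, "tissue"] == g).sum() < 2:
            raise ValidationError(f"need >= 2 samples in group {g!r}")
    sub = matrix.subset_units(units)
    scores, loadings = _pca_loadings(sub.values, n_components=1)
    pos_mean = scores.loc[meta.loc[units, "tissue"] == group_pos, "PC1"].mean()
    sign = 1.0 if pos_mean >= 0 else -1.0
    keep = matrix.genes[(sign * loadings["PC1"]).to_numpy() > 0]
    if rescue:
        extra = [g for g in rescue if g in matrix.genes and g not in set(keep)]
        keep = keep.append(pd.Index(extra))
    return keep


@dataclass
class GeneSetResult:
    """Per-gene record of the four-step filter."""

    table: pd.DataFrame          # flags, coordinates, labels per gene
    pca_scores: pd.DataFrame
    plsda: "PlsdaModel | None" = None
    de_tables: dict = field(default_factory=dict)

    @property
    def gene_set(self) -> pd.Index:
        return self.table.index[self.table["in_gene_set"]]

    def part_genes(self, part: str, which: str = "plsda") -> pd.Index:
        col = f"{which}_part"
        return self.table.index[self.table[col] == part]


def gland_gene_set(matrix: ExpressionMatrix, cutoff: float = DISTANCE_CUTOFF) -> GeneSetResult:
    """Step 3: two-component PCA over tail/sac/duct and distance cutoff.

    Axes are oriented so tail replicates score negative on PC1 and duct
    replicates negative on PC2.  Genes further than ``cutoff`` from the
    loading origin enter the gene set, labelled tail (PC1 < 0, PC2 >= 0),
    sac (PC1 >= 0, PC2 >= 0) or duct (PC2 < 0).
    """
    meta = matrix.unit_meta
    for part in ("tail", "sac", "duct"):
        if (meta["tissue"] == part).sum() < 2:
            raise ValidationError(f"need >= 2 replicates of {part}")
    units = meta.index[meta["tissue"].isin(["tail", "sac", "duct"])]
    sub = matrix.subset_units(units)
    scores, loadings = _pca_loadings(sub.values, n_components=2)
    tissues = meta.loc[units, "tissue"]
    # The two-component plane is rotation-ambiguous; align it to the class
    # geometry the quadrant rule presupposes: duct straight down (PC2 < 0),
    # tail upper-left, sac upper-right.
    cent = _class_centroids(scores, tissues)
    theta = -np.pi / 2 - np.arctan2(cent.loc["duct", "PC2"], cent.loc["duct", "PC1"])
    scores = _rotate2(scores, theta)
    loadings = _rotate2(loadings, theta)
    cent = _class_centroids(scores, tissues)
    if cent.loc["tail", "PC1"] > cent.loc["sac", "PC1"]:
        scores["PC1"] *= -1
        loadings["PC1"] *= -1
    dist = np.hypot(loadings["PC1"], loadings["PC2"])
    in_set = dist > cutoff
    pc1 = loadings["PC1"].to_numpy()
    pc2 = loadings["PC2"].to_numpy()
    sel = in_set.to_numpy()
    part = np.array([
        pca_quadrant_label(a, b) if keep else "none"
        for a, b, keep in zip(pc1, pc2, sel)
    ], dtype=object)
    table = pd.DataFrame({
        "PC1": pc1, "PC2": pc2, "distance": dist,
        "in_gene_set": sel, "pca_part": part,
    }, index=matrix.genes)
    return GeneSetResult(table=table, pca_scores=scores)


# ---------------------------------------------------------------------------
# PLS-DA


@dataclass
class PlsdaModel:
    """Two-component PLS-DA with cross-validated predictive relevance."""

    loadings: pd.DataFrame       # genes x 2 (LV1, LV2)
    scores: pd.DataFrame         # samples x 2
    classes: list
    q2: float
    gene_part: pd.Series = field(default=None)


def _one_hot(labels: pd.Series) -> tuple[np.ndarray, list]:
    classes = sorted(labels.unique())
    Y = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        Y[labels.to_numpy() == c, j] = 1.0
    return Y, classes


def plsda(matrix: ExpressionMatrix, labels: pd.Series | None = None,
          n_components: int = 2, cv_folds: int = 7) -> PlsdaModel:
    """PLS-DA of tail/sac/duct samples on the gene set.

    Q² = 1 − PRESS/TSS under stratified cross-validation.  Gene part labels
    use the loading-quadrant rule tail (LV1 < 0), sac (LV1 >= 0, LV2 <= 0),
    duct (LV1 >= 0, LV2 > 0), with axes oriented so tail samples score
    negative on LV1 and duct samples positive on LV2.
    """
    if labels is None:
        labels = matrix.unit_meta["tissue"]
    labels = labels.loc[matrix.units]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValidationError("PLS-DA needs >= 2 classes")
    if (counts < 3).any():
        raise ValidationError("PLS-DA needs >= 3 samples per class")
    X = matrix.values.to_numpy(dtype=float).T
    Y, classes = _one_hot(labels)

    folds = min(cv_folds, counts.min())
    if folds < cv_folds:
        warnings.warn(
            f"reducing CV folds from {cv_folds} to {folds} (smallest class)",
            stacklevel=2,
        )
    press, tss = 0.0, 0.0
    skf = StratifiedKFold(n_splits=folds, shuffle=False)
    for train, test in skf.split(X, labels.to_numpy()):
        model = PLSRegression(n_components=n_components, scale=False)
        model.fit(X[train], Y[train])
        pred = model.predict(X[test])
        press += float(((Y[test] - pred) ** 2).sum())
        tss += float(((Y[test] - Y[train].mean(axis=0)) ** 2).sum())
    q2 = 1.0 - press / tss

    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(X, Y)
    scores = pd.DataFrame(model.x_scores_, index=matrix.units, columns=["LV1", "LV2"])
    loadings = pd.DataFrame(model.x_loadings_, index=matrix.genes, columns=["LV1", "LV2"])
    if scores.loc[labels == "tail", "LV1"].mean() > 0:
        scores["LV1"] *= -1
        loadings["LV1"] *= -1
    if "duct" in set(labels) and scores.loc[labels == "duct", "LV2"].mean() < 0:
        scores["LV2"] *= -1
        loadings["LV2"] *= -1

    # Gene classification needs the canonical class geometry (tail on the
    # negative LV1 side, sac lower-right, duct upper-right), which a PLS fit
    # only determines up to an in-plane rotation.  Rotate a copy of the
    # loadings for labelling; the model keeps the raw (orthogonal-score) fit.
    rot_scores, rot_loadings = scores, loadings
    if {"tail", "sac", "duct"} <= set(labels):
        cent = _class_centroids(scores, labels)
        sac_dir = cent.loc["sac"].to_numpy()
        duct_dir = cent.loc["duct"].to_numpy()
        bisector = sac_dir / np.linalg.norm(sac_dir) + duct_dir / np.linalg.norm(duct_dir)
        theta = -np.arctan2(bisector[1], bisector[0])
        rot_scores = _rotate2(scores, theta)
        rot_loadings = _rotate2(loadings, theta)
        cent = _class_centroids(rot_scores, labels)
        if cent.loc["duct", "LV2"] < cent.loc["sac", "LV2"]:
            rot_scores = rot_scores.assign(LV2=-rot_scores["LV2"])
            rot_loadings = rot_loadings.assign(LV2=-rot_loadings["LV2"])
    part = [
        plsda_quadrant_label(a, b)
        for a, b in zip(rot_loadings["LV1"], rot_loadings["LV2"])
    ]
    return PlsdaModel(
        loadings=loadings, scores=scores, classes=classes, q2=q2,
        gene_part=pd.Series(part, index=matrix.genes, name="plsda_part"),
    )


# ---------------------------------------------------------------------------
# Differential expression


def differential_expression(counts: ExpressionMatrix, part: str,
                            alpha: float = 0.001, min_fc: float = 4.0,
                            cap: int = 100) -> pd.DataFrame:
    """One-vs-rest DE for one gland part with stringent thresholds.

    Welch t-test on VST values, BH adjustment, size-factor-normalized fold
    change; retain adjusted p < ``alpha`` and fold change > ``min_fc``,
    capped to the top ``cap`` genes by adjusted p (ties: |log2FC| then id).
    """
    meta = counts.unit_meta
    gland = meta.index[meta["tissue"].isin(["tail", "sac", "duct"])]
    sub = counts.subset_units(gland)
    in_part = sub.unit_meta["tissue"] == part
    if in_part.sum() < 2 or (~in_part).sum() < 2:
        raise ValidationError("need >= 2 replicates on each side of the contrast")
    sf = size_factors(sub.values)
    norm = sub.values.div(sf, axis=1)
    mean_in = norm.loc[:, in_part.to_numpy()].mean(axis=1)
    mean_out = norm.loc[:, (~in_part).to_numpy()].mean(axis=1)
    pseudo = 0.5
    fc = (mean_in + pseudo) / (mean_out + pseudo)
    log2fc = np.log2(fc)
    v = vst(sub).values
    a = v.loc[:, in_part.to_numpy()].to_numpy()
    b = v.loc[:, (~in_part).to_numpy()].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({
        "t": t, "p": p, "padj": padj, "fold_change": fc, "log2fc": log2fc,
    }, index=counts.genes)
    hits = table[(table["padj"] < alpha) & (table["fold_change"] > min_fc)].copy()
    hits["abs_l2fc"] = hits["log2fc"].abs()
    hits["gene_id"] = hits.index
    hits = hits.sort_values(
        by=["padj", "abs_l2fc", "gene_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    hits = hits.drop(columns=["abs_l2fc", "gene_id"]).head(cap)
    hits["rank"] = np.arange(1, len(hits) + 1)
    return hits


# ---------------------------------------------------------------------------
# Four-step driver


def run_geneset_stage(counts: ExpressionMatrix,
                      cutoff: float = DISTANCE_CUTOFF,
                      rescue: tuple = ("MaSp4", "SpiCE-LMa4"),
                      min_tpm: float = 4.0) -> GeneSetResult:
    """TPM prefilter, steps 1-4 and per-part DE, in order.

    Step 1 contrasts body (gland-bearing side) against head; step 2 the
    pooled gland parts against body.  Returns a :class:`GeneSetResult`
    whose table carries all flags, coordinates and labels; the PLS-DA model
    and the DE tables hang off the result.
    """
    filtered = tpm_prefilter(counts, min_tpm=min_tpm)
    v = vst(filtered)

    step1 = pca_sign_filter(v, group_pos="body", group_neg="head")
    meta2 = v.unit_meta.copy()
    meta2.loc[meta2["tissue"].isin(["tail", "sac", "duct"]), "tissue"] = "gland"
    v2 = ExpressionMatrix(values=v.values.loc[step1], layer="vst", unit_meta=meta2)
    step2 = pca_sign_filter(v2, group_pos="gland", group_neg="body", rescue=list(rescue))

    gland_units = v.unit_meta.index[v.unit_meta["tissue"].isin(["tail", "sac", "duct"])]
    v3 = ExpressionMatrix(
        values=v.values.loc[step2, gland_units], layer="vst",
        unit_meta=v.unit_meta.loc[gland_units],
    )
    result = gland_gene_set(v3, cutoff=cutoff)

    gs = result.gene_set
    v4 = ExpressionMatrix(
        values=v.values.loc[gs, gland_units], layer="vst",
        unit_meta=v.unit_meta.loc[gland_units],
    )
    model = plsda(v4)
    result.plsda = model

    full = pd.DataFrame(index=counts.genes)
    full["kept_tpm"] = full.index.isin(filtered.genes)
    full["kept_step1"] = full.index.isin(step1)
    full["kept_step2"] = full.index.isin(step2)
    for col in ("PC1", "PC2", "distance"):
        full[col] = result.table[col]
    full["in_gene_set"] = result.table["in_gene_set"].reindex(full.index, fill_value=False)
    full["pca_part"] = result.table["pca_part"].reindex(full.index, fill_value="none")
    full["plsda_part"] = "none"
    full.loc[model.gene_part.index, "plsda_part"] = model.gene_part
    full.loc[~full["in_gene_set"], "plsda_part"] = "none"

    de_tables = {}
    for part in ("tail", "sac", "duct"):
        de = differential_expression(counts.subset_genes(filtered.genes), part)
        de_tables[part] = de
        full[f"de_{part}"] = full.index.isin(de.index)

    result.table = full
    result.de_tables = de_tables
    return result
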