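"""Spatial transcriptomics: zones, perimeter ordering, deconvolution.

Zone-A cross sections are ordered proximo-distally by perimeter, spots are
assigned to the nearest same-zone region, per-spot cell-type proportions are
estimated by non-negative least squares against single-cell signatures, and
positional-class summaries reproduce the gradient analyses.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .containers import ExpressionMatrix, ValidationError, validate_spot_table

PROXIMAL_MAX = 500.0   # px, strict: below is proximal
DISTAL_MIN = 1000.0    # px, strict: above is distal


def spot_qc(spatial: ExpressionMatrix, spots: pd.DataFrame,
            min_genes: int = 300, min_counts: int = 500):
    """Spot-level QC with the same thresholds as the single-cell filter."""
    counts = spatial.values
    n_genes = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    keep = (n_genes >= min_genes) & (totals >= min_counts)
    kept = spatial.subset_units(spatial.units[keep])
    spots = spots[spots["spot_id"].isin(kept.units)].reset_index(drop=True)
    return kept, spots


def split_zoneA_regions(spots: pd.DataFrame,
                        proximal_max: float = PROXIMAL_MAX,
                        distal_min: float = DISTAL_MIN) -> pd.DataFrame:
    """Assign positional classes from region perimeters.

    Zone-A regions: perimeter < ``proximal_max`` -> A-proximal,
    > ``distal_min`` -> A-distal, otherwise A-middle (boundary values fall
    in the middle).  Zone B and C spots get their zone as class.
    """
    spots = spots.copy()
    zone_a = spots["zone"] == "A"
    missing = spots.loc[zone_a & spots["perimeter"].isna(), "region_id"].unique()
    if len(missing):
        raise ValidationError(
            f"zone-A regions lacking perimeter: {sorted(missing)}"
        )
    per = spots["perimeter"]
    cls = np.where(per < proximal_max, "A-proximal",
                   np.where(per > distal_min, "A-distal", "A-middle"))
    spots["positional_class"] = np.where(
        zone_a, cls, spots["zone"].map({"B": "B", "C": "C"}).fillna("none")
    )
    return validate_spot_table(spots)


def assign_spots_to_regions(spots: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Assign each zoned spot to the nearest region centroid of its zone.

    Distances are Euclidean in pixel coordinates within the same section;
    ties resolve to the lexicographically lowest region id.  Spots with a
    zone but no same-zone region in their section become unassigned.
    """
    spots = spots.copy()
    assigned = []
    for _, spot in spots.iterrows():
        cands = regions[(regions["section"] == spot["section"]) &
                        (regions["zone"] == spot["zone"])]
        if not len(cands):
            if spot["zone"] in ("A", "B", "C", "duct"):
                warnings.warn(
                    f"spot {spot['spot_id']}: no region of zone {spot['zone']} "
                    f"in section {spot['section']}", stacklevel=2,
                )
            assigned.append((None, np.nan))
            continue
        d = np.hypot(cands["x"] - spot["x"], cands["y"] - spot["y"])
        best = d.min()
        winners = cands.loc[d == best, "region_id"].sort_values()
        rid = winners.iloc[0]
        assigned.append((rid, float(cands.set_index("region_id").loc[rid, "perimeter"])))
    spots["region_id"] = [a[0] for a in assigned]
    spots["perimeter"] = [a[1] for a in assigned]
    return spots


def depth_normalize(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Counts scaled to the median unit depth."""
    depth = matrix.values.sum(axis=0)
    zero = depth[depth == 0]
    if len(zero):
        raise ValidationError(f"zero-depth units: {zero.index[:5].tolist()}")
    return matrix.values.div(depth, axis=1) * float(depth.median())


def expression_perimeter_trend(spots: pd.DataFrame, counts: ExpressionMatrix,
                               marker_sets: dict[str, list]) -> pd.DataFrame:
    """OLS of region-mean marker expression against region perimeter.

    For each marker set, zone-A spots are averaged per region (mean of the
    set's depth-normalized expression), then a linear model of region mean
    vs perimeter gives slope, intercept, Pearson r and p.  Constant
    expression is flagged (r undefined).
    """
    zone_a = spots[spots["zone"] == "A"]
    regions = zone_a.groupby("region_id")["perimeter"].first()
    if len(regions) < 3:
        raise ValidationError("need >= 3 zone-A regions for a trend")
    norm = depth_normalize(counts)
    rows = []
    for name, genes in marker_sets.items():
        genes = [g for g in genes if g in counts.genes]
        per_spot = norm.loc[genes].mean(axis=0)
        region_mean = (
            per_spot.loc[zone_a["spot_id"]].groupby(zone_a["region_id"].to_numpy()).mean()
        )
        x = regions.loc[region_mean.index].to_numpy(dtype=float)
        y = region_mean.to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            rows.append(dict(marker_set=name, slope=0.0, intercept=float(y[0]),
                             r=np.nan, p=np.nan, n=len(y), undefined=True))
            continue
        fit = stats.linregress(x, y)
        rows.append(dict(marker_set=name, slope=fit.slope, intercept=fit.intercept,
                         r=fit.rvalue, p=fit.pvalue, n=len(y), undefined=False))
    return pd.DataFrame(rows).set_index("marker_set")


def hematoxylin_perimeter_correlation(table: pd.DataFrame, zone: str = "A",
                                      value_col: str = "hematoxylin",
                                      perimeter_col: str = "perimeter"):
    """Pearson correlation of hematoxylin vs perimeter in one zone.

    Returns ``(r, p, n)``; zero variance in either variable yields
    ``(nan, nan, n)`` (undefined, flagged by the nan).
    """
    sub = table[table["zone"] == zone][[value_col, perimeter_col]].dropna()
    n = len(sub)
    if n < 3:
        raise ValidationError("need >= 3 observations with both values")
    x = sub[perimeter_col].to_numpy(dtype=float)
    y = sub[value_col].to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return np.nan, np.nan, n
    r, p = stats.pearsonr(y, x)
    return float(r), float(p), n


def build_signatures(cells: ExpressionMatrix, labels: pd.Series,
                     spatial_counts: ExpressionMatrix,
                     marker_log2fc: pd.DataFrame | None = None,
                     min_log2fc: float = 2.0, min_counts: int = 200,
                     min_spots: int = 50) -> pd.DataFrame:
    """Cell-type signature matrix on the deconvolution gene set.

    A gene is kept iff its best per-cluster average log2FC is strictly
    greater than ``min_log2fc`` AND it has at least ``min_counts`` total
    spatial counts AND is detected in at least ``min_spots`` spots.  The
    signature is the per-type mean of depth-normalized single-cell counts.
    """
    labels = labels.loc[cells.units]
    if marker_log2fc is None:
        norm = depth_normalize(cells)
        fcs = {}
        for group in labels.unique():
            in_g = (labels == group).to_numpy()
            mean_in = norm.loc[:, in_g].mean(axis=1)
            mean_out = norm.loc[:, ~in_g].mean(axis=1)
            fcs[group] = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        marker_log2fc = pd.DataFrame(fcs)
    best_fc = marker_log2fc.max(axis=1)
    sp_total = spatial_counts.values.sum(axis=1)
    sp_detected = (spatial_counts.values > 0).sum(axis=1)
    keep = (
        (best_fc.reindex(cells.genes).fillna(-np.inf) > min_log2fc)
        & (sp_total.reindex(cells.genes).fillna(0) >= min_counts)
        & (sp_detected.reindex(cells.genes).fillna(0) >= min_spots)
    )
    if not keep.any():
        raise ValidationError(
            "empty signature gene set "
            f"(log2FC>{min_log2fc}: {(best_fc > min_log2fc).sum()}, "
            f"counts>={min_counts}: {(sp_total >= min_counts).sum()}, "
            f"spots>={min_spots}: {(sp_detected >= min_spots).sum()})"
        )
    genes = cells.genes[keep.to_numpy()]
    norm = depth_normalize(cells).loc[genes]
    sig = {}
    for group in sorted(labels.unique(), key=str):
        sig[group] = norm.loc[:, (labels == group).to_numpy()].mean(axis=1)
    signatures = pd.DataFrame(sig)
    signatures = signatures[~(signatures == 0).all(axis=1)]
    return signatures


def deconvolve_spots(spatial_counts: ExpressionMatrix, signatures: pd.DataFrame):
    """Per-spot NNLS of depth-normalized expression on signature columns.

    Coefficients are renormalized to the simplex; an all-zero solution
    falls back to uniform proportions and is flagged.  Returns a
    proportions DataFrame (spots x types) and a per-spot diagnostics frame
    (residual norm, degenerate flag).
    """
    if signatures.shape[1] < 2:
        raise ValidationError("need >= 2 cell types to deconvolve")
    S = signatures.to_numpy(dtype=float)
    if np.linalg.matrix_rank(S) < S.shape[1]:
        corr = np.corrcoef(S.T)
        pairs = [
            (signatures.columns[i], signatures.columns[j])
            for i in range(S.shape[1]) for j in range(i + 1, S.shape[1])
            if corr[i, j] > 1.0 - 1e-9
        ]
        raise ValidationError(f"rank-deficient signature matrix; collinear: {pairs}")
    genes = signatures.index.intersection(spatial_counts.genes)
    S = signatures.loc[genes].to_numpy(dtype=float)
    Y = depth_normalize(spatial_counts).loc[genes].to_numpy(dtype=float)
    props, resid, degen = [], [], []
    k = S.shape[1]
    for j in range(Y.shape[1]):
        coef, rnorm = nnls(S, Y[:, j])
        total = coef.sum()
        if total <= 0:
            props.append(np.full(k, 1.0 / k))
            degen.append(True)
        else:
            props.append(coef / total)
            degen.append(False)
        resid.append(rnorm)
    proportions = pd.DataFrame(props, index=spatial_counts.units,
                               columns=signatures.columns)
    diagnostics = pd.DataFrame(
        {"residual_norm": resid, "degenerate": degen}, index=spatial_counts.units
    )
    return proportions, diagnostics


def class_proportions(proportions: pd.DataFrame, spots: pd.DataFrame,
                      classes: tuple = ("A-proximal", "A-middle", "A-distal", "B", "C")
                      ) -> pd.DataFrame:
    """Mean cell-type proportion per positional class (rows sum to 1)."""
    spot_class = spots.set_index("spot_id")["positional_class"]
    rows = {}
    for cls in classes:
        ids = spot_class.index[spot_class == cls]
        ids = proportions.index.intersection(ids)
        if not len(ids):
            warnings.warn(f"class {cls!r} has no spots; omitted", stacklevel=2)
            continue
        rows[cls] = proportions.loc[ids].mean(axis=0)
    return pd.DataFrame(rows).T


def run_spatial_stage(spatial: ExpressionMatrix, spots: pd.DataFrame,
                      regions: pd.DataFrame, sc_result: dict) -> dict:
    """QC, classes, region assignment, signatures, deconvolution, summaries."""
    spatial, spots = spot_qc(spatial, spots)
    spots = assign_spots_to_regions(spots, regions)
    spots = split_zoneA_regions(spots)
    zone_markers = rank_markers_by_zone(spatial, spots)
    signatures = build_signatures(
        sc_result["matrix"],
        sc_result["clusters"],
        spatial,
    )
    proportions, diagnostics = deconvolve_spots(spatial, signatures)
    per_class = class_proportions(proportions, spots)
    hema = hematoxylin_perimeter_correlation(
        spots.groupby("region_id").agg(
            zone=("zone", "first"), perimeter=("perimeter", "first"),
            hematoxylin=("hematoxylin", "mean"),
        ).reset_index()
    )
    return dict(matrix=spatial, spots=spots, signatures=signatures,
                proportions=proportions, diagnostics=diagnostics,
                class_proportions=per_class, zone_markers=zone_markers,
                hematoxylin_correlation=hema)


def rank_markers_by_zone(spatial: ExpressionMatrix, spots: pd.DataFrame):
    """Zone marker tables (A/B/C) from depth-normalized spot expression."""
    from .sc import rank_markers

    zoned = spots[spots["zone"].isin(["A", "B", "C"])]
    sub = spatial.subset_units(zoned["spot_id"])
    norm = sub.with_values(depth_normalize(sub), "normalized")
    labels = pd.Series(zoned["zone"].to_numpy(), index=zoned["spot_id"])
    return rank_markers(norm, labels, counts=sub)
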