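"""Fiber-layer inference from urea solubilization series and histology.

Relative abundance profiles across 2/4/8 M urea classify each identified
protein as 2M-enriched (outer), 4M-peaking (middle) or 8M-enriched (core);
the formic-acid-dissolved control separates layering from intrinsic
solubility; vesicle-lumen H&E matching maps lumen layers to zones; and the
final layer model joins zone-of-origin with the urea class.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .containers import SpectraTable, ValidationError, validate_histo_table
from .proteomics import percent_total_spectra

LAYER_OF_UREA_CLASS = {
    "enriched-8M": "core",
    "peak-4M": "middle",
    "enriched-2M": "outer",
}
UREA_CLASS_OF_LAYER = {v: k for k, v in LAYER_OF_UREA_CLASS.items()}
LAYER_OF_ZONE = {"A": "core", "B": "middle", "C": "outer"}


def relative_urea_profiles(fiber: SpectraTable, proteins: list[str],
                           preparation: str = "intact"):
    """Percent of total spectra over the identified set, per urea molarity.

    The table is restricted to the identified proteins and renormalized,
    then averaged over replicates per molarity.  Returns
    ``(per_molarity_means, per_replicate_values)``.
    """
    meta = fiber.sample_meta
    mask = (meta["solvent"] == "urea") & (meta["preparation"] == preparation)
    series = fiber.select_samples(mask).subset_proteins(proteins)
    mols = sorted(series.sample_meta["molarity"].dropna().unique())
    for need in (2.0, 4.0, 8.0):
        if need not in mols:
            raise ValidationError(f"missing urea molarity {need} ({preparation})")
    pct = percent_total_spectra(series)
    by_mol = {}
    for mol in mols:
        cols = series.sample_meta.index[series.sample_meta["molarity"] == mol]
        by_mol[mol] = pct[[c for c in pct.columns if c in set(cols)]].mean(axis=1)
    means = pd.DataFrame(by_mol)
    return means, pct


def urea_enrichment_test(fiber: SpectraTable, proteins: list[str],
                         alpha: float = 0.05, adjust: bool = True,
                         peak_margin: float = 0.0) -> pd.DataFrame:
    """Classify each protein by its 2 M vs 8 M urea behaviour.

    Two-sided Welch t-test of per-replicate relative abundances (2 M vs
    8 M), BH-adjusted across the tested proteins; significant and higher
    at 2 M -> enriched-2M; significant and higher at 8 M -> enriched-8M;
    otherwise peak-4M if the 4 M mean exceeds both others by
    ``peak_margin``; else unclassified.
    """
    means, pct = relative_urea_profiles(fiber, proteins)
    meta = fiber.sample_meta
    cols2 = [c for c in pct.columns if meta.loc[c, "molarity"] == 2.0]
    cols8 = [c for c in pct.columns if meta.loc[c, "molarity"] == 8.0]
    if len(cols2) < 2 or len(cols8) < 2:
        raise ValidationError("need >= 2 replicates at 2 M and 8 M")
    a = pct[cols2].to_numpy(dtype=float)
    b = pct[cols8].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = np.isnan(p)
    p = np.where(degenerate, 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1] if adjust else p
    rows = []
    for i, pid in enumerate(pct.index):
        m2, m4, m8 = means.loc[pid, 2.0], means.loc[pid, 4.0], means.loc[pid, 8.0]
        if padj[i] < alpha and m2 > m8:
            cls = "enriched-2M"
        elif padj[i] < alpha and m8 > m2:
            cls = "enriched-8M"
        elif m4 > max(m2, m8) + peak_margin:
            cls = "peak-4M"
        else:
            cls = "unclassified"
        rows.append(dict(protein_id=pid, urea_class=cls, t=t[i], p=p[i],
                         padj=padj[i], mean_2M=m2, mean_4M=m4, mean_8M=m8))
    return pd.DataFrame(rows).set_index("protein_id")


def _linkage_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _linkage_to_newick(node.get_left(), labels)
    right = _linkage_to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def intact_vs_dissolved_compare(fiber: SpectraTable, proteins: list[str],
                                alpha: float = 0.05) -> dict:
    """Pairwise Pearson r over urea-extract samples plus a 2 M contrast.

    All intact and dissolved urea samples enter; the correlation is over
    per-sample relative-abundance vectors (restricted protein set);
    hierarchical clustering uses average linkage on 1 - r.  A per-protein
    Welch t-test contrasts 2 M intact vs 2 M dissolved relative abundance.
    """
    meta = fiber.sample_meta
    mask = (meta["solvent"] == "urea") & meta["preparation"].isin(["intact", "dissolved"])
    series = fiber.select_samples(mask).subset_proteins(proteins)
    pct = percent_total_spectra(series)
    keep = [c for c in pct.columns if pct[c].std() > 0]
    dropped = [c for c in pct.columns if c not in keep]
    if dropped:
        warnings.warn(f"zero-variance samples excluded: {dropped}", stacklevel=2)
    pct = pct[keep]
    corr = pct.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    tree = hierarchy.to_tree(Z)
    newick = _linkage_to_newick(tree, list(corr.columns)) + ";"

    m = series.sample_meta
    cols_i = [c for c in pct.columns if m.loc[c, "molarity"] == 2.0
              and m.loc[c, "preparation"] == "intact"]
    cols_d = [c for c in pct.columns if m.loc[c, "molarity"] == 2.0
              and m.loc[c, "preparation"] == "dissolved"]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(pct[cols_i].to_numpy(), pct[cols_d].to_numpy(),
                               axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1]
    contrast = pd.DataFrame({
        "t": t, "p": p, "padj": padj,
        "mean_2M_intact": pct[cols_i].mean(axis=1),
        "mean_2M_dissolved": pct[cols_d].mean(axis=1),
        "higher_in_intact": pct[cols_i].mean(axis=1) > pct[cols_d].mean(axis=1),
    }, index=pct.index)
    return dict(correlation=corr, linkage=Z, newick=newick, contrast=contrast)


def histo_match_layers(histo: pd.DataFrame, min_vesicles: int = 3) -> dict:
    """Map lumen layers to zones by nearest vesicle-cluster centroid.

    (H, E) values are standardized jointly; zone centroids come from the
    vesicle objects; each lumen object is assigned to the nearest centroid
    and each layer to the majority zone of its objects (ties unmapped).
    """
    validate_histo_table(histo)
    vesicles = histo[histo["compartment"] == "vesicle"]
    lumen = histo[histo["compartment"] == "lumen-layer"]
    for zone, group in vesicles.groupby("zone"):
        if len(group) < min_vesicles:
            raise ValidationError(f"zone {zone}: fewer than {min_vesicles} vesicle objects")
    if not len(lumen):
        raise ValidationError("no lumen-layer objects")
    he = histo[["hematoxylin", "eosin"]].astype(float)
    mu, sd = he.mean(axis=0), he.std(axis=0).replace(0, 1.0)
    z = (he - mu) / sd
    centroids = z.loc[vesicles.index].groupby(vesicles["zone"].to_numpy()).mean()

    votes: dict[str, list] = {}
    for idx, row in lumen.iterrows():
        d = np.hypot(
            centroids["hematoxylin"] - z.loc[idx, "hematoxylin"],
            centroids["eosin"] - z.loc[idx, "eosin"],
        )
        best = d.min()
        winners = d.index[d == best]
        votes.setdefault(row["layer"], []).append(
            winners[0] if len(winners) == 1 else None
        )
    mapping, fractions = {}, {}
    for layer, vote_list in votes.items():
        valid = [v for v in vote_list if v is not None]
        counts = pd.Series(valid).value_counts() if valid else pd.Series(dtype=int)
        fractions[layer] = (counts / len(vote_list)).to_dict()
        if len(counts) and (len(counts) == 1 or counts.iloc[0] > counts.iloc[1]):
            mapping[layer] = counts.index[0]
        else:
            warnings.warn(f"layer {layer}: majority tie, unmapped", stacklevel=2)
            mapping[layer] = None
    return dict(mapping=mapping, vote_fractions=fractions, centroids=centroids)


def zone_of_origin(zone_markers: dict, proteins: list[str],
                   alpha: float = 0.05) -> pd.Series:
    """Zone of maximal marker significance per protein gene, else 'mixed'."""
    out = {}
    for pid in proteins:
        best_zone, best_p = "mixed", np.inf
        for zone, table in zone_markers.items():
            if pid in table.index:
                p = table.loc[pid, "padj"]
                if p < alpha and p < best_p:
                    best_zone, best_p = zone, p
        out[pid] = best_zone
    return pd.Series(out, name="zone_of_origin")


@dataclass
class LayerModel:
    """Final per-protein zone/urea-class/layer assignment."""

    table: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            pid: {
                "zone_of_origin": row["zone_of_origin"],
                "urea_class": row["urea_class"],
                "layer": row["layer"],
                "consistency": bool(row["consistency"]),
            }
            for pid, row in self.table.iterrows()
        }


def build_layer_model(zones: pd.Series, urea_classes: pd.DataFrame,
                      proteins: list[str]) -> LayerModel:
    """Join zone-of-origin with urea enrichment into the layer model.

    layer = A->core, B->middle, C->outer; consistency requires the urea
    class to match (8M<->core, 4M-peak<->middle, 2M<->outer).  A protein
    with 'mixed' zone but a classified urea class takes its layer from the
    urea class, flagged inconsistent; missing zone input -> unresolved.
    """
    rows = []
    for pid in proteins:
        zone = zones.get(pid, None)
        urea = urea_classes.loc[pid, "urea_class"] if pid in urea_classes.index else "unclassified"
        if zone is None:
            layer, consistent = "unresolved", False
        elif zone in LAYER_OF_ZONE:
            layer = LAYER_OF_ZONE[zone]
            consistent = UREA_CLASS_OF_LAYER[layer] == urea
        elif urea in LAYER_OF_UREA_CLASS:  # mixed zone, classified urea
            layer, consistent = LAYER_OF_UREA_CLASS[urea], False
        else:
            layer, consistent = "unresolved", False
        row = dict(protein_id=pid, zone_of_origin=zone if zone else "mixed",
                   urea_class=urea, layer=layer, consistency=consistent)
        if pid in urea_classes.index:
            for col in ("t", "padj", "mean_2M", "mean_4M", "mean_8M"):
                row[col] = urea_classes.loc[pid, col]
        rows.append(row)
    return LayerModel(table=pd.DataFrame(rows).set_index("protein_id"))


def run_layer_stage(spectra: SpectraTable, identified: list[str],
                    zone_markers: dict, histo: pd.DataFrame) -> dict:
    """Urea classification, dissolved control, histology matching, model."""
    meta = spectra.sample_meta
    fiber = spectra.select_samples(meta["source"] == "fiber")
    urea_classes = urea_enrichment_test(fiber, identified)
    control = intact_vs_dissolved_compare(fiber, identified)
    histo_map = histo_match_layers(histo)
    zones = zone_of_origin(zone_markers, identified)
    model = build_layer_model(zones, urea_classes, identified)
    profiles, _ = relative_urea_profiles(fiber, identified)
    return dict(urea_classes=urea_classes, control=control,
                histology_mapping=histo_map, zones=zones,
                layer_model=model, profiles=profiles)
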