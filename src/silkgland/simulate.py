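"""Simulators for every assay consumed by the pipeline.

Counts are negative binomial (gamma-Poisson) with one dispersion per assay;
spatial spot means are mixture-weighted sums of cell-type programs; fiber
proteomics follows a layer-dependent logistic extractability in urea
molarity; histology intensities are Gaussian around zone means.  One RNG
stream per assay is derived from ``(seed, assay tag)`` so assays can be
regenerated independently.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SpectraTable, ValidationError
from .design import (
    CELL_TYPES,
    CLASS_ZONE,
    GlandDesign,
    GlandTruth,
    POSITIONAL_CLASSES,
)

# Fixed stream index per assay tag.
_ASSAY_STREAMS = {
    "genes": 0,
    "bulk": 1,
    "cells": 2,
    "spatial": 3,
    "proteomics": 4,
    "histology": 5,
    "sequences": 6,
}


def assay_rng(seed: int, assay: str) -> np.random.Generator:
    """Independent generator for one assay, derived from the master seed."""
    if seed is None:
        raise ValidationError("a seed is required (no silent nondeterminism)")
    return np.random.default_rng([int(seed), _ASSAY_STREAMS[assay]])


def nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial draw, var = mu + dispersion * mu^2 (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    lam = rng.gamma(shape=size, scale=np.maximum(mean, 1e-300) / size)
    lam[mean == 0] = 0.0
    return rng.poisson(lam)


def gene_lengths(design: GlandDesign, seed: int) -> pd.Series:
    """Per-gene transcript length in bp (uniform over the configured range)."""
    rng = assay_rng(seed, "genes")
    lo, hi = design.config["genes"]["length_range"]
    lens = rng.integers(lo, hi, size=design.n_genes)
    return pd.Series(lens, index=design.gene_ids(), name="length")


def simulate_transcriptomes(design: GlandDesign, seed: int):
    """Generate bulk, single-cell and spatial counts plus the truth.

    Returns ``(bulk, cells, spatial, spots, truth)`` where the first three
    are :class:`ExpressionMatrix` (counts layer), ``spots`` is the SpotTable
    DataFrame and ``truth`` the :class:`GlandTruth`.
    """
    if seed is None:
        raise ValidationError("a seed is required (no silent nondeterminism)")
    ids = design.gene_ids()
    lengths = gene_lengths(design, seed)

    # ---- bulk ------------------------------------------------------------
    rng = assay_rng(seed, "bulk")
    bcfg = design.config["bulk"]
    tissue_means = design.bulk_tissue_means()
    cols, meta_rows = {}, []
    for tissue in tissue_means.columns:
        mu = tissue_means[tissue].to_numpy() * bcfg["scale"]
        for rep in range(1, bcfg["replicates"] + 1):
            sid = f"{tissue}_r{rep}"
            cols[sid] = nb_counts(rng, mu, bcfg["dispersion"])
            meta_rows.append((sid, tissue, rep))
    bulk_meta = pd.DataFrame(meta_rows, columns=["sample", "tissue", "replicate"]).set_index("sample")
    bulk = ExpressionMatrix(
        values=pd.DataFrame(cols, index=ids),
        layer="counts", unit_meta=bulk_meta, gene_lengths=lengths,
    )

    # ---- single cells ----------------------------------------------------
    rng = assay_rng(seed, "cells")
    ccfg = design.config["cells"]
    n_cells = int(ccfg["n_cells"])
    prog = design.type_programs().to_numpy()  # genes x types
    type_idx = rng.integers(0, len(CELL_TYPES), size=n_cells)
    sample_idx = rng.integers(0, int(ccfg["n_samples"]), size=n_cells)
    depth = np.exp(rng.normal(0.0, ccfg["depth_sd_log"], size=n_cells))
    mu = prog[:, type_idx] * (ccfg["scale"] * depth)[None, :]
    cell_counts = nb_counts(rng, mu, ccfg["dispersion"])
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    cell_meta = pd.DataFrame(
        {"sample": [f"s{j + 1}" for j in sample_idx]}, index=cell_ids
    )
    cells = ExpressionMatrix(
        values=pd.DataFrame(cell_counts, index=ids, columns=cell_ids),
        layer="counts", unit_meta=cell_meta, gene_lengths=lengths,
    )

    # ---- spatial ---------------------------------------------------------
    rng = assay_rng(seed, "spatial")
    scfg = design.config["spatial"]
    mix = design.zone_mixture
    he = design.config["histology"]["he_means"]
    he_sd = scfg["he_sd"]
    grad = design.config["histology"]
    perims = design.tail_perimeters
    pmin, pmax = perims.min(), perims.max()

    region_rows, spot_rows, spot_mu = [], [], []
    for sec in range(1, int(scfg["n_sections"]) + 1):
        region_defs = [(f"s{sec}_A{i:02d}", "A", p, i) for i, p in enumerate(perims)]
        region_defs.append((f"s{sec}_B00", "B", float(scfg["b_perimeter"]), len(perims)))
        region_defs.append((f"s{sec}_C00", "C", float(scfg["c_perimeter"]), len(perims) + 1))
        for rid, zone, per, slot in region_defs:
            cx, cy = 200.0 * slot + 100.0, 400.0 * sec
            region_rows.append((rid, sec, zone, cx, cy, per))
            if zone == "A":
                if per < 500:
                    cls = "A-proximal"
                elif per > 1000:
                    cls = "A-distal"
                else:
                    cls = "A-middle"
            else:
                cls = zone
            w = mix[cls]
            h_mean, e_mean = he[zone]
            if zone == "A" and grad["gradient"]:
                h_mean = h_mean - grad["gradient_strength"] * (per - pmin) / (pmax - pmin)
            for k in range(int(scfg["spots_per_region"])):
                sid = f"{rid}_sp{k:02d}"
                x = cx + rng.uniform(-40, 40)
                y = cy + rng.uniform(-40, 40)
                hema = h_mean + rng.normal(0, he_sd)
                eos = e_mean + rng.normal(0, he_sd)
                spot_rows.append((sid, sec, x, y, zone, rid, per, hema, eos, cls, w))
                spot_mu.append(w)

    spot_ids = [r[0] for r in spot_rows]
    depth = np.exp(rng.normal(0.0, scfg["depth_sd_log"], size=len(spot_rows)))
    mu = (design.type_programs().to_numpy() @ np.array(spot_mu).T) * (scfg["scale"] * depth)[None, :]
    spatial_counts = nb_counts(rng, mu, scfg["dispersion"])
    spatial = ExpressionMatrix(
        values=pd.DataFrame(spatial_counts, index=ids, columns=spot_ids),
        layer="counts",
        unit_meta=pd.DataFrame(index=pd.Index(spot_ids, name="spot_id")),
        gene_lengths=lengths,
    )
    spots = pd.DataFrame(
        [r[:10] for r in spot_rows],
        columns=["spot_id", "section", "x", "y", "zone", "region_id",
                 "perimeter", "hematoxylin", "eosin", "positional_class"],
    )
    regions = pd.DataFrame(
        region_rows, columns=["region_id", "section", "zone", "x", "y", "perimeter"]
    )
    spots.attrs["regions"] = regions

    gt = design.gene_truth()
    truth = GlandTruth(
        gene_part=gt["part"].to_dict(),
        gene_zone=gt["zone"].to_dict(),
        gene_marker_of=gt["marker_of"].to_dict(),
        cell_types={cid: CELL_TYPES[t] for cid, t in zip(cell_ids, type_idx)},
        spot_class={r[0]: r[9] for r in spot_rows},
        spot_mixture={r[0]: list(map(float, r[10])) for r in spot_rows},
        protein_layer=design.protein_table["layer"].to_dict(),
        params=design.config,
    )
    return bulk, cells, spatial, spots, truth


def logistic(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(np.asarray(x, dtype=float))


def extraction_probability(design: GlandDesign, molarity: float) -> pd.Series:
    """Expected extractability of each protein at the given urea molarity."""
    tab = design.protein_table
    p = pd.Series(
        logistic((molarity - tab["midpoint"]) / tab["slope"]), index=tab.index
    )
    return p.fillna(1.0)  # contaminants have no layer: fully extractable


def simulate_proteomics(design: GlandDesign, seed: int) -> SpectraTable:
    """Spectral-count tables for gland, fiber solvents and urea series.

    Samples generated (replicates ``r``):

    * ``gland_r*`` — secreted silk proteins plus contaminants lacking a
      signal peptide.
    * ``fiber_<solvent>_r*`` — fully solubilized fiber in urea / HFIP / LiBr.
    * ``urea<2|4|8>_intact_r*`` — sequential solubilization of intact fiber;
      extractability is logistic in molarity with layer-dependent midpoint.
    * ``urea<2|4|8>_dissolved_r*`` — formic-acid-dissolved control; the
      layer term is replaced by a protein-specific solubility factor.
    """
    if seed is None:
        raise ValidationError("a seed is required (no silent nondeterminism)")
    pcfg = design.config["proteomics"]
    total = int(pcfg["total_spectra"])
    if total <= 0:
        raise ValidationError("total spectra per sample must be positive")
    reps = int(pcfg["replicates"])
    rng = assay_rng(seed, "proteomics")
    tab = design.protein_table
    pids = tab.index.to_list()
    n = len(pids)
    fiber_share = tab["fiber_share"].to_numpy(dtype=float)
    gland_share = tab["gland_share"].to_numpy(dtype=float)
    solubility = np.exp(rng.normal(0.0, pcfg["solubility_sd_log"], size=n))
    response = np.exp(rng.normal(0.0, 0.2, size=n))  # per-protein MS response

    solvent_presence = {}
    for solv in ("urea", "HFIP", "LiBr"):
        present = np.array([
            solv in str(s).split(";") if s else False for s in tab["solvents"]
        ])
        solvent_presence[solv] = present.astype(float)

    def draw(sample_id, base_share, meta):
        share = np.asarray(base_share, dtype=float).copy()
        share *= np.exp(rng.normal(0.0, pcfg["abundance_jitter_sd"], size=n))
        if share.sum() <= 0:
            raise ValidationError(f"{sample_id}: empty composition")
        counts = rng.multinomial(total, share / share.sum())
        intens = counts * response * pcfg["intensity_scale"]
        return sample_id, counts, intens, meta

    samples = []
    for r in range(1, reps + 1):
        samples.append(draw(
            f"gland_r{r}", gland_share,
            dict(source="gland", solvent="none", molarity=np.nan,
                 preparation="none", replicate=r),
        ))
    for solv in ("urea", "HFIP", "LiBr"):
        base = fiber_share * solvent_presence[solv]
        for r in range(1, reps + 1):
            samples.append(draw(
                f"fiber_{solv}_r{r}", base,
                dict(source="fiber", solvent=solv, molarity=np.nan,
                     preparation="none", replicate=r),
            ))
    is_fiber = fiber_share > 0
    for mol in (2.0, 4.0, 8.0):
        p_ext = extraction_probability(design, mol).to_numpy()
        for r in range(1, reps + 1):
            samples.append(draw(
                f"urea{int(mol)}_intact_r{r}", fiber_share * p_ext * is_fiber,
                dict(source="fiber", solvent="urea", molarity=mol,
                     preparation="intact", replicate=r),
            ))
        for r in range(1, reps + 1):
            samples.append(draw(
                f"urea{int(mol)}_dissolved_r{r}", fiber_share * solubility * is_fiber,
                dict(source="fiber", solvent="urea", molarity=mol,
                     preparation="dissolved", replicate=r),
            ))

    counts = pd.DataFrame({sid: c for sid, c, _, _ in samples}, index=pids)
    intens = pd.DataFrame({sid: i for sid, _, i, _ in samples}, index=pids)
    meta = pd.DataFrame({sid: m for sid, _, _, m in samples}).T
    meta.index.name = "sample_id"
    return SpectraTable(
        counts=counts, sample_meta=meta,
        lengths=tab["length"].astype(float), intensities=intens,
    )


def simulate_histology(design: GlandDesign, seed: int) -> pd.DataFrame:
    """Per-object H&E intensity table for vesicles and lumen layers.

    Vesicle objects draw (H, E) around their zone's mean; lumen-layer
    objects draw around the mean of their originating zone (layer I is the
    innermost, from zone A).  With the gradient flag set, zone-A vesicle
    hematoxylin decreases with the perimeter of the cross section the
    object belongs to.
    """
    if seed is None:
        raise ValidationError("a seed is required (no silent nondeterminism)")
    hcfg = design.config["histology"]
    rng = assay_rng(seed, "histology")
    sd = float(hcfg["sd"])
    he = hcfg["he_means"]
    lo, hi = hcfg["perimeter_range"]
    rows = []
    for zone, n_obj in hcfg["n_vesicles"].items():
        if n_obj < 10:
            raise ValidationError(f"need >= 10 vesicle objects per zone ({zone})")
        h0, e0 = he[zone]
        for i in range(int(n_obj)):
            per = np.nan
            h_mean = h0
            if zone == "A":
                per = rng.uniform(lo, hi)
                if hcfg["gradient"]:
                    h_mean = h0 - hcfg["gradient_strength"] * (per - lo) / (hi - lo)
            rows.append(dict(
                object_id=f"ves_{zone}_{i:03d}", compartment="vesicle",
                zone=zone, layer=None, perimeter=per,
                hematoxylin=h_mean + rng.normal(0, sd),
                eosin=e0 + rng.normal(0, sd),
            ))
    layer_zone = {"I": "A", "II": "B", "III": "C"}
    for layer, zone in layer_zone.items():
        h0, e0 = he[zone]
        for i in range(int(hcfg["n_lumen_per_layer"])):
            rows.append(dict(
                object_id=f"lum_{layer}_{i:03d}", compartment="lumen-layer",
                zone=None, layer=layer, perimeter=np.nan,
                hematoxylin=h0 + rng.normal(0, sd),
                eosin=e0 + rng.normal(0, sd),
            ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Small purpose-built toys


def simulate_deconv_toy(n_types: int = 3, n_genes: int = 150, n_spots: int = 200,
                        dispersion: float = 0.1, depth: float = 2000.0,
                        seed: int = 0):
    """Mixture spots over block signatures for deconvolution benchmarking.

    Returns ``(signatures, spot_counts, true_proportions)``; signatures are
    genes x types with marker blocks per type over a shared background.
    """
    rng = np.random.default_rng([int(seed), 77])
    genes = [f"tg{i:04d}" for i in range(n_genes)]
    types = [f"T{j}" for j in range(n_types)]
    sig = np.full((n_genes, n_types), 1.0)
    block = n_genes // (n_types + 1)
    for j in range(n_types):
        sig[j * block:(j + 1) * block, j] = 8.0
    sig /= sig.sum(axis=0, keepdims=True)
    props = rng.dirichlet(np.ones(n_types), size=n_spots)
    mu = depth * (sig @ props.T)
    counts = nb_counts(rng, mu, dispersion)
    signatures = pd.DataFrame(sig, index=genes, columns=types)
    spots = pd.DataFrame(counts, index=genes,
                         columns=[f"spot{i:04d}" for i in range(n_spots)])
    truth = pd.DataFrame(props, index=spots.columns, columns=types)
    return signatures, spots, truth


# ---------------------------------------------------------------------------
# Synthetic protein sequences (for FASTA export and motif profiling)

_MOTIF_POOLS = {
    "MaSp1": ["AAAAAA", "GGAGQG", "GGQGAG", "GGYGQG"],
    "MaSp2": ["AAAAAA", "GPGQQ", "GPGGY", "GGYGP"],
    "MaSp3": ["AAAAA", "GGQGQ", "SSAAA", "GGAGA"],
    "MaSp4": ["AAAAA", "GPGQQ", "GGAGA", "VSVVS"],
}
_GENERIC_AA = list("ADEFGHIKLMNPQRSTVWY")


def synthetic_protein_sequences(design: GlandDesign, seed: int) -> dict:
    """Repeat-motif-rich synthetic sequences, one per fiber protein.

    Sequence length equals the protein's designed length.  MaSp-class
    sequences are built from poly-alanine / glycine-rich repeat pools so
    that motif profiling has realistic structure; other proteins get
    composition-random sequences.  These are synthetic stand-ins, not
    reconstructions of any real spidroin.
    """
    rng = assay_rng(seed, "sequences")
    out = {}
    for pid, row in design.protein_table.iterrows():
        length = int(row["length"])
        pool = None
        for cls, motifs in _MOTIF_POOLS.items():
            if pid.startswith(cls):
                pool = motifs
        chunks = []
        size = 0
        while size < length:
            if pool is not None:
                m = pool[rng.integers(0, len(pool))]
            else:
                m = "".join(rng.choice(_GENERIC_AA, size=6))
            chunks.append(m)
            size += len(m)
        seq = "".join(chunks)[:length]
        out[pid] = seq
    return out
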