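"""Ground-truth design of the synthetic major ampullate gland and fiber.

The generator emulates the study system: a silk gland whose tail and sac
epithelium is partitioned into secretory zones A, B and C populated by eight
cell types, a tapering tail whose cross-section perimeter encodes
proximo-distal position, and a three-layer fiber whose layers derive from the
zones (core from A, middle from B, outer from C).  Everything downstream of
the simulators can therefore be scored against known labels.
"""
from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import ValidationError

#: The eight cell types in their canonical order.
CELL_TYPES = (
    "ZoneA_MaSp1",
    "ZoneA_MaSp2",
    "ZoneA_SpiCE",
    "ZoneB_MaSp3",
    "ZoneC_SpiCE",
    "ZoneABC",
    "Duct_1",
    "Duct_2",
)

POSITIONAL_CLASSES = ("A-proximal", "A-middle", "A-distal", "B", "C")

#: Zone of each positional class.
CLASS_ZONE = {
    "A-proximal": "A",
    "A-middle": "A",
    "A-distal": "A",
    "B": "B",
    "C": "C",
}

#: Layer <-> zone mapping used for the ground truth (core from zone A,
#: middle from zone B, outer from zone C).
LAYER_OF_ZONE = {"A": "core", "B": "middle", "C": "outer"}
ZONE_OF_LAYER = {v: k for k, v in LAYER_OF_ZONE.items()}

#: Bulk part from which each cell type's markers originate.
PART_OF_TYPE = {
    "ZoneA_MaSp1": "tail",
    "ZoneA_MaSp2": "tail",
    "ZoneA_SpiCE": "tail",
    "ZoneB_MaSp3": "sac",
    "ZoneC_SpiCE": "sac",
    "ZoneABC": "sac",
    "Duct_1": "duct",
    "Duct_2": "duct",
}

ZONE_OF_TYPE = {
    "ZoneA_MaSp1": "A",
    "ZoneA_MaSp2": "A",
    "ZoneA_SpiCE": "A",
    "ZoneB_MaSp3": "B",
    "ZoneC_SpiCE": "C",
    "ZoneABC": "none",
    "Duct_1": "none",
    "Duct_2": "none",
}

# Cell-type mixture per positional class (columns follow CELL_TYPES).  The
# zone-A classes encode the proximo-distal gradient: ZoneA_MaSp2 dominates
# proximally and fades distally while ZoneA_MaSp1 rises, mirroring the
# reported distribution of the tail cell types.
DEFAULT_ZONE_MIXTURE = {
    "A-proximal": [0.15, 0.60, 0.10, 0.00, 0.00, 0.10, 0.025, 0.025],
    "A-middle":   [0.35, 0.30, 0.20, 0.00, 0.00, 0.10, 0.025, 0.025],
    "A-distal":   [0.50, 0.10, 0.25, 0.00, 0.00, 0.10, 0.025, 0.025],
    "B":          [0.05, 0.02, 0.03, 0.70, 0.05, 0.10, 0.025, 0.025],
    "C":          [0.05, 0.02, 0.03, 0.05, 0.70, 0.10, 0.025, 0.025],
}

# Perimeters (pixels) of the tail cross sections, strictly increasing from
# proximal to distal and spanning both split thresholds (500 and 1000 px).
DEFAULT_TAIL_PERIMETERS = [300, 380, 460, 560, 660, 760, 860, 960, 1100, 1300, 1500]

# The 18 fiber proteins: id, producing cell type, true layer, logistic
# extraction midpoint (M urea) and fiber abundance share (percent scale).
# Shares are chosen so that, under the default logistic midpoints, the
# middle layer peaks at 4 M while its 2 M and 8 M relative abundances are
# near-equal in expectation (see docs/methods.md for the derivation).
SILK_PROTEIN_SPECS = [
    # id,            producer,       layer,    midpoint, share, length(aa)
    ("MaSp1a",      "ZoneA_MaSp1",  "core",    6.0, 14.0, 920),
    ("MaSp1b",      "ZoneA_MaSp1",  "core",    6.0, 14.0, 900),
    ("MaSp1c",      "ZoneA_MaSp1",  "core",    6.0, 14.0, 880),
    ("MaSp2b",      "ZoneA_MaSp2",  "core",    6.0,  4.0, 800),
    ("MaSp2c",      "ZoneA_MaSp2",  "core",    6.0,  4.0, 790),
    ("MaSp2e",      "ZoneA_MaSp2",  "core",    6.0,  4.0, 780),
    ("MaSp2f",      "ZoneA_MaSp2",  "core",    6.0,  4.0, 770),
    ("MaSp4",       "ZoneA_MaSp2",  "core",    6.0,  1.5, 640),
    ("SpiCE-LMa3",  "ZoneA_SpiCE",  "core",    6.0,  1.2, 420),
    ("SpiCE-LMa5",  "ZoneA_SpiCE",  "core",    6.0,  1.2, 400),
    ("SpiCE-LMa6",  "ZoneA_SpiCE",  "core",    6.0,  1.1, 380),
    ("MaSp3a",      "ZoneB_MaSp3",  "middle",  3.5, 12.5, 840),
    ("MaSp3b",      "ZoneB_MaSp3",  "middle",  3.5, 12.5, 820),
    ("AmSp-like1",  "ZoneC_SpiCE",  "outer",   1.5,  2.5, 560),
    ("AmSp-like2",  "ZoneC_SpiCE",  "outer",   1.5,  2.5, 540),
    ("SpiCE-LMa1",  "ZoneC_SpiCE",  "outer",   1.5,  3.0, 480),
    ("SpiCE-LMa2",  "ZoneC_SpiCE",  "outer",   1.5,  1.8, 460),
    ("SpiCE-LMa4",  "ZoneC_SpiCE",  "outer",   1.5,  1.2, 440),
]

SILK_PROTEIN_IDS = [s[0] for s in SILK_PROTEIN_SPECS]

# H&E staining means per zone: (hematoxylin, eosin) on a 0-1 optical-density
# scale; zones separate in this plane as in the stained sections.
DEFAULT_HE_MEANS = {
    "A": [0.80, 0.35],
    "B": [0.50, 0.60],
    "C": [0.25, 0.80],
}

DEFAULTS: dict = {
    "n_genes": 2000,
    "genes": {
        "n_markers_per_type": 30,
        "n_head_markers": 60,
        "n_other_markers": 60,
        "n_silent": 100,
        "baseline_mean": 1.0,
        "silent_mean": 0.001,
        "length_range": [500, 5000],
    },
    "effects": {
        "marker_log2": 3.0,
        "shared_gland_log2": 2.5,
        "body_leak_log2": 1.0,
        "head_log2": 3.0,
        "other_log2": 3.0,
    },
    "bulk": {
        "replicates": 5,
        "scale": 50.0,       # mean counts for a baseline gene
        "dispersion": 0.1,
    },
    "cells": {
        "n_cells": 3000,
        "n_samples": 5,
        "scale": 0.4,        # mean counts per baseline gene per cell
        "depth_sd_log": 0.3,
        "dispersion": 0.1,
    },
    "spatial": {
        "n_sections": 6,
        "spots_per_region": 11,
        "scale": 0.5,
        "depth_sd_log": 0.2,
        "dispersion": 0.1,
        "tail_perimeters": DEFAULT_TAIL_PERIMETERS,
        "b_perimeter": 900.0,
        "c_perimeter": 900.0,
        "he_sd": 0.05,
    },
    "zone_mixture": DEFAULT_ZONE_MIXTURE,
    "proteomics": {
        "total_spectra": 10000,
        "replicates": 3,
        "slope": 0.7,
        "abundance_jitter_sd": 0.05,
        "solubility_sd_log": 0.3,
        "n_contaminants": 30,
        "contaminant_gland_share": 0.3,   # percent of gland composition, each
        "benchmark": False,                # 4x50 single-criterion contaminants
        "intensity_scale": 1000.0,
    },
    "histology": {
        "n_vesicles": {"A": 80, "B": 30, "C": 30},
        "n_lumen_per_layer": 30,
        "sd": 0.05,
        "he_means": DEFAULT_HE_MEANS,
        "gradient": True,
        "gradient_strength": 0.15,
        "perimeter_range": [250, 1600],
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


@dataclass
class GlandDesign:
    """Fully resolved generative parameters for one synthetic gland/fiber."""

    config: dict
    protein_table: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.protein_table is None:
            self.protein_table = _build_protein_table(self.config["proteomics"])
        self.validate()

    # -- convenience views -------------------------------------------------
    @property
    def cell_types(self) -> tuple:
        return CELL_TYPES

    @property
    def n_genes(self) -> int:
        return int(self.config["n_genes"])

    @property
    def zone_mixture(self) -> dict:
        return {k: np.asarray(v, dtype=float) for k, v in self.config["zone_mixture"].items()}

    @property
    def tail_perimeters(self) -> np.ndarray:
        return np.asarray(self.config["spatial"]["tail_perimeters"], dtype=float)

    def validate(self) -> None:
        cfg = self.config
        if cfg["n_genes"] < 200:
            raise ValidationError("n_genes must be >= 200")
        for assay in ("bulk",):
            if cfg[assay]["replicates"] < 2:
                raise ValidationError(f"{assay}: need >= 2 replicates per tissue")
        for cls in POSITIONAL_CLASSES:
            if cls not in cfg["zone_mixture"]:
                raise ValidationError(f"zone_mixture missing class {cls!r}")
            vec = np.asarray(cfg["zone_mixture"][cls], dtype=float)
            if len(vec) != len(CELL_TYPES):
                raise ValidationError(
                    f"zone_mixture[{cls!r}] has {len(vec)} entries, expected {len(CELL_TYPES)}"
                )
            if (vec < 0).any():
                raise ValidationError(f"zone_mixture[{cls!r}] has negative proportions")
            if abs(vec.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"zone_mixture[{cls!r}] sums to {vec.sum():.6f}, expected 1"
                )
        per = self.tail_perimeters
        if not (np.diff(per) > 0).all():
            raise ValidationError("tail_perimeters must be strictly increasing")
        if not (per.min() < 500 and per.max() > 1000):
            raise ValidationError("tail_perimeters must span below 500 and above 1000 px")
        n_named = (
            len(CELL_TYPES) * cfg["genes"]["n_markers_per_type"]
            + cfg["genes"]["n_head_markers"]
            + cfg["genes"]["n_other_markers"]
            + cfg["genes"]["n_silent"]
        )
        if n_named > cfg["n_genes"]:
            raise ValidationError(
                f"gene architecture needs {n_named} genes but n_genes={cfg['n_genes']}"
            )
        prod = self.protein_table
        fiber = prod[prod["role"] == "silk"]
        if (fiber["producer"] == "").any():
            raise ValidationError("every fiber protein needs >= 1 producing cell type")
        for _, row in fiber.iterrows():
            if LAYER_OF_ZONE[ZONE_OF_TYPE[row["producer"]]] != row["layer"]:
                raise ValidationError(
                    f"{row.name}: layer {row['layer']} inconsistent with producer zone"
                )

    # -- gene architecture -------------------------------------------------
    def gene_ids(self) -> list[str]:
        """Gene identifiers.  Marker blocks lead, with the silk genes named."""
        cfg = self.config["genes"]
        k = cfg["n_markers_per_type"]
        ids = [f"g{i:05d}" for i in range(self.n_genes)]
        for t_idx, ctype in enumerate(CELL_TYPES):
            block = range(t_idx * k, (t_idx + 1) * k)
            silk = [
                pid for pid, prod, *_ in
                [(r[0], r[1]) for r in SILK_PROTEIN_SPECS] if prod == ctype
            ]
            for j, pid in zip(block, silk):
                ids[j] = pid
        return ids

    def marker_index(self) -> dict:
        """Index ranges of the designed gene blocks."""
        cfg = self.config["genes"]
        k = cfg["n_markers_per_type"]
        n_types = len(CELL_TYPES)
        out = {"type_markers": {}, "head": None, "other": None, "silent": None}
        for t_idx, ctype in enumerate(CELL_TYPES):
            out["type_markers"][ctype] = np.arange(t_idx * k, (t_idx + 1) * k)
        pos = n_types * k
        out["head"] = np.arange(pos, pos + cfg["n_head_markers"])
        pos += cfg["n_head_markers"]
        out["other"] = np.arange(pos, pos + cfg["n_other_markers"])
        pos += cfg["n_other_markers"]
        out["silent"] = np.arange(pos, pos + cfg["n_silent"])
        return out

    def baseline(self) -> np.ndarray:
        cfg = self.config["genes"]
        base = np.full(self.n_genes, float(cfg["baseline_mean"]))
        base[self.marker_index()["silent"]] = float(cfg["silent_mean"])
        return base

    def type_programs(self) -> pd.DataFrame:
        """Expected relative expression per cell type (genes x types).

        Markers of a gland cell type are elevated 2^marker_log2 in that type
        and carry a shared gland-wide elevation 2^shared_gland_log2 in every
        gland cell type (silk genes are gland-enriched overall *and*
        part-differential, as in the real gland).
        """
        eff = self.config["effects"]
        idx = self.marker_index()
        base = self.baseline()
        gland_marker = np.zeros(self.n_genes, dtype=bool)
        for ctype in CELL_TYPES:
            gland_marker[idx["type_markers"][ctype]] = True
        prog = np.tile(base[:, None], (1, len(CELL_TYPES))).astype(float)
        prog[gland_marker, :] *= 2.0 ** eff["shared_gland_log2"]
        for t_idx, ctype in enumerate(CELL_TYPES):
            rows = idx["type_markers"][ctype]
            prog[rows, t_idx] *= 2.0 ** eff["marker_log2"]
        return pd.DataFrame(prog, index=self.gene_ids(), columns=list(CELL_TYPES))

    def bulk_tissue_means(self) -> pd.DataFrame:
        """Expected relative expression per bulk tissue (genes x tissues)."""
        eff = self.config["effects"]
        idx = self.marker_index()
        base = self.baseline()
        prog = self.type_programs().to_numpy()
        mix = self.zone_mixture
        tail = np.mean(
            [prog @ mix[c] for c in ("A-proximal", "A-middle", "A-distal")], axis=0
        )
        sac = prog @ (0.4 * mix["A-distal"] + 0.3 * mix["B"] + 0.3 * mix["C"])
        duct_mix = np.zeros(len(CELL_TYPES))
        duct_mix[CELL_TYPES.index("Duct_1")] = 0.5
        duct_mix[CELL_TYPES.index("Duct_2")] = 0.5
        duct = prog @ duct_mix
        head = base.copy()
        head[idx["head"]] *= 2.0 ** eff["head_log2"]
        gland_marker = np.zeros(self.n_genes, dtype=bool)
        for ctype in CELL_TYPES:
            gland_marker[idx["type_markers"][ctype]] = True
        body = base.copy()
        body[gland_marker] *= 2.0 ** eff["body_leak_log2"]
        other = base.copy()
        other[idx["other"]] *= 2.0 ** eff["other_log2"]
        cols = {"tail": tail, "sac": sac, "duct": duct,
                "head": head, "body": body, "other": other}
        return pd.DataFrame(cols, index=self.gene_ids())

    def gene_truth(self) -> pd.DataFrame:
        """Per-gene ground truth: part label and zone markerhood."""
        idx = self.marker_index()
        ids = self.gene_ids()
        part = np.array(["none"] * self.n_genes, dtype=object)
        zone = np.array(["none"] * self.n_genes, dtype=object)
        for ctype in CELL_TYPES:
            rows = idx["type_markers"][ctype]
            part[rows] = PART_OF_TYPE[ctype]
            zone[rows] = ZONE_OF_TYPE[ctype]
        marker_of = np.array(["none"] * self.n_genes, dtype=object)
        for ctype in CELL_TYPES:
            marker_of[idx["type_markers"][ctype]] = ctype
        return pd.DataFrame(
            {"part": part, "zone": zone, "marker_of": marker_of}, index=ids
        )


def _build_protein_table(pcfg: dict) -> pd.DataFrame:
    """Protein-level generative parameters (silk proteins + contaminants)."""
    rows = []
    for pid, producer, layer, midpoint, share, length in SILK_PROTEIN_SPECS:
        rows.append(dict(
            protein_id=pid, role="silk", producer=producer, layer=layer,
            midpoint=midpoint, slope=pcfg["slope"], fiber_share=share,
            gland_share=share, length=length, signal_peptide=True,
            solvents="urea;HFIP;LiBr",
        ))
    if pcfg.get("benchmark", False):
        groups = [
            ("absent_gland", dict(gland_share=0.0, fiber_share=0.30,
                                  signal_peptide=True, solvents="urea;HFIP;LiBr")),
            ("one_solvent", dict(gland_share=0.10, fiber_share=0.90,
                                 signal_peptide=True, solvents=None)),
            ("no_signal", dict(gland_share=0.10, fiber_share=0.30,
                               signal_peptide=False, solvents="urea;HFIP;LiBr")),
            ("low_abundance", dict(gland_share=0.10, fiber_share=0.02,
                                   signal_peptide=True, solvents="urea;HFIP;LiBr")),
        ]
        solvent_cycle = ["urea", "HFIP", "LiBr"]
        i = 0
        for gname, params in groups:
            for j in range(50):
                solv = params["solvents"] or solvent_cycle[j % 3]
                rows.append(dict(
                    protein_id=f"CONT_{i:03d}", role=f"contaminant:{gname}",
                    producer="", layer="none", midpoint=np.nan, slope=np.nan,
                    fiber_share=params["fiber_share"],
                    gland_share=params["gland_share"],
                    length=200 + 5 * i,
                    signal_peptide=params["signal_peptide"], solvents=solv,
                ))
                i += 1
    else:
        for i in range(int(pcfg["n_contaminants"])):
            rows.append(dict(
                protein_id=f"CONT_{i:03d}", role="contaminant:gland_only",
                producer="", layer="none", midpoint=np.nan, slope=np.nan,
                fiber_share=0.0, gland_share=pcfg["contaminant_gland_share"],
                length=200 + 10 * i, signal_peptide=False, solvents="",
            ))
    table = pd.DataFrame(rows).set_index("protein_id")
    return table


def make_design(config: dict | None = None) -> GlandDesign:
    """Resolve a configuration tree into a validated :class:`GlandDesign`.

    Deterministic: the same config always yields an identical design.
    Raises :class:`ValidationError` for invalid mixtures (naming the class),
    too few genes or replicates, or inconsistent protein truth.
    """
    merged = _deep_merge(DEFAULTS, config or {})
    return GlandDesign(config=merged)


@dataclass
class GlandTruth:
    """Ground-truth labels echoed by the simulators (the acceptance oracle)."""

    gene_part: dict
    gene_zone: dict
    gene_marker_of: dict
    cell_types: dict          # cell id -> true type
    spot_class: dict          # spot id -> positional class
    spot_mixture: dict        # spot id -> list of 8 proportions
    protein_layer: dict       # protein id -> core/middle/outer/none
    params: dict              # full config echo

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GlandTruth":
        return cls(**json.loads(text))

    def gene_part_series(self) -> pd.Series:
        return pd.Series(self.gene_part)
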