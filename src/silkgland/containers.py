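"""In-memory containers shared across the pipeline.

All tabular data ride on pandas objects; the thin dataclass wrappers exist to
pin orientation (genes x units, proteins x samples), carry assay metadata, and
validate the invariants the downstream stages rely on.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_LAYERS = ("counts", "tpm", "vst", "normalized")

#: Tissues recognised in bulk unit metadata.
BULK_TISSUES = ("tail", "sac", "duct", "head", "body", "other")

#: The three anatomical parts of the major ampullate gland.
GLAND_PARTS = ("tail", "sac", "duct")


class ValidationError(ValueError):
    """Raised when a container violates one of its documented invariants."""


@dataclass
class ExpressionMatrix:
    """Genes x units expression values with per-unit metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are unit ids (bulk samples,
        cells or spatial spots).
    layer
        One of ``counts``, ``tpm``, ``vst``, ``normalized``.
    unit_meta
        DataFrame indexed by unit id.  For bulk data it carries ``tissue``
        and ``replicate``; for cells ``sample``; for spots nothing extra.
    gene_lengths
        Optional per-gene length in bp (required to compute TPM).
    """

    values: pd.DataFrame
    layer: str = "counts"
    unit_meta: pd.DataFrame | None = None
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.layer not in VALID_LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise ValidationError(f"duplicate gene identifiers: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][:5].tolist()
            raise ValidationError(f"duplicate unit identifiers: {dup}")
        if self.layer == "counts":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise ValidationError("counts layer contains negative values")
        if self.layer == "tpm":
            sums = self.values.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1e6, rtol=1e-6):
                raise ValidationError("TPM columns must each sum to 1e6")
        if self.unit_meta is not None:
            missing = self.values.columns.difference(self.unit_meta.index)
            if len(missing):
                raise ValidationError(
                    f"{len(missing)} units missing from unit_meta, e.g. {missing[:3].tolist()}"
                )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def units(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(genes)])

    def subset_units(self, units) -> "ExpressionMatrix":
        meta = self.unit_meta.loc[list(units)] if self.unit_meta is not None else None
        return replace(self, values=self.values[list(units)], unit_meta=meta)

    def with_values(self, values: pd.DataFrame, layer: str) -> "ExpressionMatrix":
        return replace(self, values=values, layer=layer)


# Columns expected in a SpotTable.
SPOT_COLUMNS = [
    "spot_id", "section", "x", "y", "zone", "region_id", "perimeter",
    "hematoxylin", "eosin", "positional_class",
]

ZONE_A_CLASSES = ("A-proximal", "A-middle", "A-distal")
POSITIONAL_CLASSES = ZONE_A_CLASSES + ("B", "C")


def validate_spot_table(spots: pd.DataFrame) -> pd.DataFrame:
    """Check SpotTable invariants; returns the table for chaining."""
    missing = [c for c in ("spot_id", "section", "x", "y", "zone") if c not in spots]
    if missing:
        raise ValidationError(f"SpotTable missing columns: {missing}")
    if "perimeter" in spots:
        per = spots["perimeter"].dropna()
        if (per <= 0).any():
            raise ValidationError("SpotTable perimeter values must be > 0")
    if "positional_class" in spots:
        bad = spots[
            spots["positional_class"].isin(ZONE_A_CLASSES) & (spots["zone"] != "A")
        ]
        if len(bad):
            raise ValidationError(
                f"{len(bad)} spots carry a zone-A positional class but zone != A"
            )
    return spots


@dataclass
class SpectraTable:
    """Proteins x MS-samples spectral counts with sample metadata.

    ``counts`` is indexed by protein id with sample ids as columns.
    ``sample_meta`` is indexed by sample id with columns ``source``
    (gland/fiber), ``solvent`` (urea/HFIP/LiBr/none), ``molarity``
    (2, 4, 8 or NaN) and ``preparation`` (intact/dissolved/none), plus
    ``replicate``.  ``lengths`` gives protein length in amino acids.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    lengths: pd.Series | None = None
    intensities: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("spectral counts must be >= 0")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("spectral counts must be integers")
        missing = self.counts.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValidationError(
                f"samples missing from sample_meta: {missing[:5].tolist()}"
            )
        if self.lengths is not None:
            lens = self.lengths.reindex(self.counts.index)
            if lens.isna().any():
                miss = lens.index[lens.isna()][:5].tolist()
                raise ValidationError(f"proteins without length: {miss}")
            if (lens <= 0).any():
                raise ValidationError("protein lengths must be > 0")

    @property
    def proteins(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def select_samples(self, mask: pd.Series) -> "SpectraTable":
        keep = self.sample_meta.index[mask]
        keep = [s for s in self.counts.columns if s in set(keep)]
        return SpectraTable(
            counts=self.counts[keep],
            sample_meta=self.sample_meta.loc[keep],
            lengths=self.lengths,
            intensities=self.intensities[keep] if self.intensities is not None else None,
        )

    def subset_proteins(self, proteins) -> "SpectraTable":
        proteins = list(proteins)
        return SpectraTable(
            counts=self.counts.loc[proteins],
            sample_meta=self.sample_meta,
            lengths=self.lengths.loc[proteins] if self.lengths is not None else None,
            intensities=self.intensities.loc[proteins] if self.intensities is not None else None,
        )


HISTO_COLUMNS = ["object_id", "compartment", "zone", "layer", "hematoxylin", "eosin"]


def validate_histo_table(histo: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("object_id", "compartment", "hematoxylin", "eosin") if c not in histo]
    if missing:
        raise ValidationError(f"HistoTable missing columns: {missing}")
    vesicles = histo[histo["compartment"] == "vesicle"]
    if "zone" not in histo or vesicles["zone"].isna().any():
        raise ValidationError("vesicle objects must carry zone labels")
    lumen = histo[histo["compartment"] == "lumen-layer"]
    if len(lumen) and ("layer" not in histo or lumen["layer"].isna().any()):
        raise ValidationError("lumen-layer objects must carry layer indices")
    vals = histo[["hematoxylin", "eosin"]].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValidationError("H&E intensities must be finite")
    return histo


@dataclass
class ProteinRecord:
    """One protein sequence with the flags used downstream."""

    id: str
    sequence: str
    signal_peptide: bool = False
    nt_domain: bool = False
    ct_domain: str = "absent"  # present | noncanonical | absent

    ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - self.ALPHABET
        if bad:
            raise ValidationError(f"{self.id}: non-standard residues {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)
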