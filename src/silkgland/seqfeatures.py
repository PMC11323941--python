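"""Deterministic protein-sequence features for silk proteins.

Repeat-motif counts (poly-alanine runs, GGX, GPGXX) and amino-acid category
composition.  Counting is non-overlapping left-to-right with the longer
motif (GPGXX) taking precedence over GGX at shared positions.
"""
from __future__ import annotations

import warnings

import pandas as pd

from .containers import ProteinRecord, ValidationError

#: Amino-acid categories used for composition profiles.
AA_CATEGORIES = {
    "small_nonpolar": set("AGPST"),
    "hydrophobic": set("ILMV"),
    "polar": set("DEHKNQR"),
    "aromatic_cysteine": set("CFWY"),
}


def count_repeat_motifs(record: ProteinRecord | str, polya_min: int = 4) -> dict:
    """Count poly-A runs (length >= ``polya_min``), GGX and GPGXX motifs.

    poly-A counts maximal runs of 'A'; GGX and GPGXX are counted as
    non-overlapping matches scanning left to right with X = any residue;
    positions inside a GPGXX match are excluded from GGX counting.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else str(record).upper()
    if not seq:
        raise ValidationError("empty sequence")

    # maximal poly-A runs
    polya = 0
    run = 0
    for ch in seq + "$":
        if ch == "A":
            run += 1
        else:
            if run >= polya_min:
                polya += 1
            run = 0

    # non-overlapping GPGXX, left to right
    taken = [False] * len(seq)
    gpgxx = 0
    i = 0
    while i + 5 <= len(seq):
        if seq[i:i + 3] == "GPG":
            gpgxx += 1
            for j in range(i, i + 5):
                taken[j] = True
            i += 5
        else:
            i += 1

    # non-overlapping GGX on the remaining positions
    ggx = 0
    i = 0
    while i + 3 <= len(seq):
        if seq[i] == "G" and seq[i + 1] == "G" and not any(taken[i:i + 3]):
            ggx += 1
            i += 3
        else:
            i += 1

    return {"polyA": polya, "GGX": ggx, "GPGXX": gpgxx}


def aa_category_composition(record: ProteinRecord | str) -> dict:
    """Fraction of residues in each of the four amino-acid categories.

    'X' residues are excluded from the denominator (with a warning); the
    fractions over a standard-alphabet sequence sum to 1.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else str(record).upper()
    if not seq:
        raise ValidationError("empty sequence")
    n_x = seq.count("X")
    if n_x:
        warnings.warn(f"{n_x} 'X' residues excluded from composition", stacklevel=2)
    denom = len(seq) - n_x
    if denom == 0:
        raise ValidationError("sequence contains only 'X' residues")
    out = {}
    for name, residues in AA_CATEGORIES.items():
        out[name] = sum(seq.count(ch) for ch in residues) / denom
    return out


def feature_table(records: list[ProteinRecord], polya_min: int = 4) -> pd.DataFrame:
    """Per-protein motif counts and category fractions."""
    rows = {}
    for rec in records:
        row = {"length": rec.length, "signal_peptide": rec.signal_peptide}
        row.update(count_repeat_motifs(rec, polya_min=polya_min))
        row.update(aa_category_composition(rec))
        rows[rec.id] = row
    return pd.DataFrame(rows).T
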