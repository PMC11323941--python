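"""Spectral-count quantification and the fiber-protein identification filter.

Three quantifications (percent of total spectra, NSAF, iBAQ) plus the
four-criteria filter that defines the fiber-constituent silk proteins:
present in the gland, found in at least two solvents, signal peptide
predicted, and mean percent of total spectra above a threshold.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import SpectraTable, ValidationError

MEAN_PCT_THRESHOLD = 0.15  # percent of total spectra, strict >


def percent_total_spectra(table: SpectraTable) -> pd.DataFrame:
    """100 * count / sample total; absent proteins contribute 0."""
    totals = table.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"zero-total sample(s): {zero.index.tolist()}")
    return table.counts.div(totals, axis=1) * 100.0


def nsaf(table: SpectraTable) -> pd.DataFrame:
    """Normalized spectral abundance factor: (SpC/L) / sum(SpC/L)."""
    if table.lengths is None:
        raise ValidationError("protein lengths are required for NSAF")
    saf = table.counts.div(table.lengths, axis=0)
    totals = saf.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"zero-total sample(s): {zero.index.tolist()}")
    return saf.div(totals, axis=1)


def count_tryptic_peptides(sequence: str, pep_min: int = 6, pep_max: int = 30) -> int:
    """Theoretical peptides: cleave after K or R unless followed by P.

    Only peptides with ``pep_min <= length <= pep_max`` qualify.
    """
    seq = sequence.upper()
    peptides = []
    start = 0
    for i, ch in enumerate(seq):
        if ch in "KR" and (i + 1 >= len(seq) or seq[i + 1] != "P"):
            peptides.append(seq[start:i + 1])
            start = i + 1
    if start < len(seq):
        peptides.append(seq[start:])
    return sum(1 for p in peptides if pep_min <= len(p) <= pep_max)


def ibaq(table: SpectraTable, sequences: dict[str, str],
         pep_min: int = 6, pep_max: int = 30):
    """Intensity / number of theoretical tryptic peptides, per sample.

    Returns ``(ibaq_matrix, flagged)`` where ``flagged`` lists proteins with
    zero qualifying peptides (excluded from the matrix).
    """
    if table.intensities is None:
        raise ValidationError("intensities are required for iBAQ")
    n_pep = {}
    flagged = []
    for pid in table.proteins:
        if pid not in sequences:
            raise ValidationError(f"no sequence for {pid}")
        n = count_tryptic_peptides(sequences[pid], pep_min, pep_max)
        if n == 0:
            flagged.append(pid)
        else:
            n_pep[pid] = n
    keep = [p for p in table.proteins if p in n_pep]
    values = table.intensities.loc[keep].div(pd.Series(n_pep), axis=0)
    return values, flagged


def identify_silk_proteins(gland: SpectraTable, fiber: SpectraTable,
                           flags: pd.Series,
                           threshold: float = MEAN_PCT_THRESHOLD) -> pd.DataFrame:
    """Four-criteria identification of fiber-constituent proteins.

    (i) nonzero spectra in >= 1 gland replicate; (ii) nonzero spectra in
    >= 1 replicate of >= 2 distinct solvents; (iii) signal peptide flag;
    (iv) mean percent of total spectra over all fiber samples (zeros
    included) strictly greater than ``threshold``.  Returns the evidence
    table for every protein with per-criterion booleans and the verdict.
    """
    meta = fiber.sample_meta
    if "solvent" not in meta:
        raise ValidationError("fiber sample metadata must include solvent")
    solvents = meta["solvent"].dropna().unique()
    if len(solvents) < 2:
        raise ValidationError("fiber table must span >= 2 solvents")
    proteins = fiber.proteins.union(gland.proteins)

    in_gland = (gland.counts > 0).any(axis=1).reindex(proteins, fill_value=False)

    per_solvent = {}
    for solv in solvents:
        cols = meta.index[meta["solvent"] == solv]
        cols = [c for c in fiber.counts.columns if c in set(cols)]
        per_solvent[solv] = (fiber.counts[cols] > 0).any(axis=1)
    n_solvents = pd.DataFrame(per_solvent).sum(axis=1).reindex(proteins, fill_value=0)

    sig = flags.reindex(proteins, fill_value=False).astype(bool)

    pct = percent_total_spectra(fiber)
    mean_pct = pct.mean(axis=1).reindex(proteins, fill_value=0.0)

    evidence = pd.DataFrame({
        "in_gland": in_gland,
        "n_solvents": n_solvents,
        "in_two_solvents": n_solvents >= 2,
        "signal_peptide": sig,
        "mean_pct_total": mean_pct,
        "above_threshold": mean_pct > threshold,
    }, index=proteins)
    evidence["identified"] = (
        evidence["in_gland"] & evidence["in_two_solvents"]
        & evidence["signal_peptide"] & evidence["above_threshold"]
    )
    return evidence


def identified_list(evidence: pd.DataFrame) -> list[str]:
    return evidence.index[evidence["identified"]].to_list()


def run_proteomics_stage(spectra: SpectraTable, flags: pd.Series,
                         threshold: float = MEAN_PCT_THRESHOLD) -> dict:
    """Split the combined table, quantify, and run the silk filter."""
    meta = spectra.sample_meta
    gland = spectra.select_samples(meta["source"] == "gland")
    solvent_series = spectra.select_samples(
        (meta["source"] == "fiber") & (meta["preparation"] == "none")
    )
    evidence = identify_silk_proteins(gland, solvent_series, flags, threshold)
    return dict(
        evidence=evidence,
        identified=identified_list(evidence),
        pct_fiber=percent_total_spectra(solvent_series),
        nsaf_fiber=nsaf(solvent_series) if spectra.lengths is not None else None,
    )
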