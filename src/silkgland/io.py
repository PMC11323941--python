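"""On-disk formats, bundle loading and end-to-end orchestration.

Counts are MatrixMarket (sparse assays) or TSV (bulk); spot, spectra and
histology tables are CSV (comma, UTF-8, header row, '.' decimal); protein
sequences FASTA; truth and run logs JSON; configuration YAML.  A manifest
YAML ties a dataset together, and :func:`run_pipeline` executes the stages
in order with one structured log line each.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as spio
from scipy import sparse

from .containers import ExpressionMatrix, SpectraTable, ValidationError
from .design import GlandDesign, GlandTruth, make_design
from . import bulk as bulk_mod
from . import layers as layers_mod
from . import proteomics as prot_mod
from . import sc as sc_mod
from . import spatial as spatial_mod
from .simulate import (
    simulate_histology,
    simulate_proteomics,
    simulate_transcriptomes,
    synthetic_protein_sequences,
)

MANIFEST_ROLES = [
    "bulk_counts", "bulk_meta", "gene_lengths",
    "cell_counts", "cell_genes", "cell_units", "cell_meta",
    "spatial_counts", "spatial_genes", "spatial_units",
    "spot_table", "region_table",
    "spectra_counts", "spectra_meta", "protein_lengths", "protein_flags",
    "protein_fasta", "histo_table",
]


# ---------------------------------------------------------------------------
# Writers


def write_matrix_mtx(matrix: ExpressionMatrix, prefix: Path) -> dict:
    prefix.parent.mkdir(parents=True, exist_ok=True)
    coo = sparse.coo_matrix(matrix.values.to_numpy())
    spio.mmwrite(str(prefix) + ".mtx", coo)
    pd.Series(matrix.genes).to_csv(str(prefix) + ".genes.tsv", sep="\t",
                                   index=False, header=False)
    pd.Series(matrix.units).to_csv(str(prefix) + ".units.tsv", sep="\t",
                                   index=False, header=False)
    return {"mtx": str(prefix) + ".mtx", "genes": str(prefix) + ".genes.tsv",
            "units": str(prefix) + ".units.tsv"}


def read_matrix_mtx(mtx: str, genes: str, units: str,
                    unit_meta: pd.DataFrame | None = None,
                    gene_lengths: pd.Series | None = None) -> ExpressionMatrix:
    arr = spio.mmread(mtx).toarray()
    gene_ids = pd.read_csv(genes, sep="\t", header=None)[0].tolist()
    unit_ids = pd.read_csv(units, sep="\t", header=None)[0].tolist()
    values = pd.DataFrame(arr, index=gene_ids, columns=unit_ids)
    return ExpressionMatrix(values=values, layer="counts",
                            unit_meta=unit_meta, gene_lengths=gene_lengths)


def write_fasta(sequences: dict[str, str], path: Path) -> None:
    records = [SeqRecord(Seq(s), id=pid, description="") for pid, s in sequences.items()]
    path.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_synthetic_bundle(design: GlandDesign, seed: int, outdir: Path) -> Path:
    """Simulate every assay and write a loadable manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bulk, cells, spatial, spots, truth = simulate_transcriptomes(design, seed)
    spectra = simulate_proteomics(design, seed)
    histo = simulate_histology(design, seed)
    seqs = synthetic_protein_sequences(design, seed)
    regions = spots.attrs["regions"]

    paths: dict[str, str] = {}
    bulk_path = outdir / "bulk_counts.tsv"
    bulk.values.to_csv(bulk_path, sep="\t")
    paths["bulk_counts"] = bulk_path.name
    bulk.unit_meta.to_csv(outdir / "bulk_meta.csv")
    paths["bulk_meta"] = "bulk_meta.csv"
    bulk.gene_lengths.rename("length").to_csv(outdir / "gene_lengths.tsv", sep="\t")
    paths["gene_lengths"] = "gene_lengths.tsv"

    refs = write_matrix_mtx(cells, outdir / "cells")
    paths.update({"cell_counts": Path(refs["mtx"]).name,
                  "cell_genes": Path(refs["genes"]).name,
                  "cell_units": Path(refs["units"]).name})
    cells.unit_meta.to_csv(outdir / "cell_meta.csv")
    paths["cell_meta"] = "cell_meta.csv"

    refs = write_matrix_mtx(spatial, outdir / "spatial")
    paths.update({"spatial_counts": Path(refs["mtx"]).name,
                  "spatial_genes": Path(refs["genes"]).name,
                  "spatial_units": Path(refs["units"]).name})
    spots.to_csv(outdir / "spots.csv", index=False)
    paths["spot_table"] = "spots.csv"
    regions.to_csv(outdir / "regions.csv", index=False)
    paths["region_table"] = "regions.csv"

    spectra.counts.to_csv(outdir / "spectra_counts.csv")
    paths["spectra_counts"] = "spectra_counts.csv"
    spectra.sample_meta.to_csv(outdir / "spectra_meta.csv")
    paths["spectra_meta"] = "spectra_meta.csv"
    spectra.lengths.rename("length").to_csv(outdir / "protein_lengths.csv")
    paths["protein_lengths"] = "protein_lengths.csv"
    if spectra.intensities is not None:
        spectra.intensities.to_csv(outdir / "spectra_intensities.csv")
        paths["spectra_intensities"] = "spectra_intensities.csv"
    design.protein_table["signal_peptide"].rename("signal_peptide").to_csv(
        outdir / "protein_flags.csv"
    )
    paths["protein_flags"] = "protein_flags.csv"
    write_fasta(seqs, outdir / "proteins.fasta")
    paths["protein_fasta"] = "proteins.fasta"
    histo.to_csv(outdir / "histology.csv", index=False)
    paths["histo_table"] = "histology.csv"
    (outdir / "truth.json").write_text(truth.to_json())
    paths["truth"] = "truth.json"
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(design.config, fh)
    paths["config"] = "config.yaml"

    manifest = {"roles": paths, "seed": int(seed)}
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return outdir / "manifest.yaml"


# ---------------------------------------------------------------------------
# Bundle


@dataclass
class DatasetBundle:
    """Loaded handles for every pipeline input plus provenance."""

    bulk: ExpressionMatrix
    cells: ExpressionMatrix
    spatial: ExpressionMatrix
    spots: pd.DataFrame
    regions: pd.DataFrame
    spectra: SpectraTable
    protein_flags: pd.Series
    sequences: dict
    histo: pd.DataFrame
    truth: GlandTruth | None = None
    provenance: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def load_bundle(manifest_path: str | Path, strict: bool = True) -> DatasetBundle:
    """Load and validate every input listed in a manifest.

    Missing files raise naming the path; transcriptomic gene identifiers
    and protein identifiers must agree across inputs (strict mode lists
    the offending identifiers).
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    roles = manifest["roles"]
    root = manifest_path.parent

    def need(role: str) -> Path:
        if role not in roles:
            raise ValidationError(f"manifest missing required role {role!r}")
        p = root / roles[role]
        if not p.exists():
            raise ValidationError(f"missing file for role {role!r}: {p}")
        return p

    lengths = pd.read_csv(need("gene_lengths"), sep="\t", index_col=0)["length"]
    bulk_meta = pd.read_csv(need("bulk_meta"), index_col=0)
    bulk = ExpressionMatrix(
        values=pd.read_csv(need("bulk_counts"), sep="\t", index_col=0),
        layer="counts", unit_meta=bulk_meta, gene_lengths=lengths,
    )
    cell_meta = pd.read_csv(need("cell_meta"), index_col=0)
    cells = read_matrix_mtx(str(need("cell_counts")), str(need("cell_genes")),
                            str(need("cell_units")), unit_meta=cell_meta,
                            gene_lengths=lengths)
    spatial = read_matrix_mtx(str(need("spatial_counts")), str(need("spatial_genes")),
                              str(need("spatial_units")), gene_lengths=lengths)
    spots = pd.read_csv(need("spot_table"))
    regions = pd.read_csv(need("region_table"))
    counts = pd.read_csv(need("spectra_counts"), index_col=0)
    meta = pd.read_csv(need("spectra_meta"), index_col=0)
    plengths = pd.read_csv(need("protein_lengths"), index_col=0)["length"]
    intens = None
    if "spectra_intensities" in roles:
        intens = pd.read_csv(root / roles["spectra_intensities"], index_col=0)
    spectra = SpectraTable(counts=counts, sample_meta=meta, lengths=plengths,
                           intensities=intens)
    flags = pd.read_csv(need("protein_flags"), index_col=0)["signal_peptide"].astype(bool)
    sequences = read_fasta(need("protein_fasta"))
    histo = pd.read_csv(need("histo_table"))
    truth = None
    if "truth" in roles and (root / roles["truth"]).exists():
        truth = GlandTruth.from_json((root / roles["truth"]).read_text())

    # identifier consistency
    for name, mat in (("cells", cells), ("spatial", spatial)):
        diff = mat.genes.difference(bulk.genes)
        if len(diff) and strict:
            raise ValidationError(
                f"{name}: {len(diff)} genes absent from bulk, e.g. {diff[:5].tolist()}"
            )
    for name, idx in (("flags", flags.index), ("fasta", pd.Index(sequences))):
        diff = pd.Index(idx).difference(spectra.proteins)
        if len(diff) and strict:
            raise ValidationError(
                f"{name}: {len(diff)} proteins absent from spectra, e.g. {diff[:5].tolist()}"
            )

    prov = {role: _sha256(root / rel) for role, rel in roles.items()
            if (root / rel).exists()}
    return DatasetBundle(bulk=bulk, cells=cells, spatial=spatial, spots=spots,
                         regions=regions, spectra=spectra, protein_flags=flags,
                         sequences=sequences, histo=histo, truth=truth,
                         provenance=prov)


# ---------------------------------------------------------------------------
# Orchestration


def run_pipeline(bundle: DatasetBundle, outdir: str | Path,
                 config: dict | None = None, seed: int = 0) -> dict:
    """Run gene set -> single cell -> spatial -> proteomics -> layers.

    Writes per-stage tables under ``outdir``, a LayerModel JSON and a run
    log (parameters, input hashes, elapsed seconds per stage).  Stages can
    be disabled via ``config['stages']`` (downstream stages are then
    skipped and flagged).  Idempotent for fixed inputs/config/seed.
    """
    config = config or {}
    stages = config.get("stages", ["geneset", "sc", "spatial", "proteomics", "layers"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    results: dict = {}

    def run_stage(name, fn):
        t0 = time.time()
        try:
            out = fn()
        except Exception as exc:  # pragma: no cover - error path
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        log.append({"stage": name, "elapsed_s": round(time.time() - t0, 3),
                    "seed": seed})
        return out

    if "geneset" in stages:
        gs = run_stage("geneset", lambda: bulk_mod.run_geneset_stage(bundle.bulk))
        results["geneset"] = gs
        gs.table.to_csv(outdir / "gene_set.tsv", sep="\t")
        for part, de in gs.de_tables.items():
            de.to_csv(outdir / f"de_{part}.tsv", sep="\t")
        pd.DataFrame({"Q2": [gs.plsda.q2]}).to_csv(outdir / "plsda_summary.tsv",
                                                   sep="\t", index=False)

    if "sc" in stages and "geneset" in results:
        sc_res = run_stage("sc", lambda: sc_mod.run_single_cell_stage(
            bundle.cells, results["geneset"].table,
            k=config.get("k", "auto"), seed=seed,
        ))
        results["sc"] = sc_res
        sc_res["cell_table"].to_csv(outdir / "cell_table.csv")
        sc_res["cluster_parts"].to_csv(outdir / "cluster_parts.csv")

    if "spatial" in stages and "sc" in results:
        sp_res = run_stage("spatial", lambda: spatial_mod.run_spatial_stage(
            bundle.spatial, bundle.spots, bundle.regions, results["sc"],
        ))
        results["spatial"] = sp_res
        sp_res["spots"].to_csv(outdir / "spot_table.csv", index=False)
        sp_res["signatures"].to_csv(outdir / "signatures.tsv", sep="\t")
        sp_res["proportions"].to_csv(outdir / "spot_proportions.csv")
        sp_res["class_proportions"].to_csv(outdir / "class_proportions.tsv", sep="\t")

    if "proteomics" in stages:
        pr = run_stage("proteomics", lambda: prot_mod.run_proteomics_stage(
            bundle.spectra, bundle.protein_flags,
        ))
        results["proteomics"] = pr
        pr["evidence"].to_csv(outdir / "silk_evidence.tsv", sep="\t")

    if "layers" in stages and "proteomics" in results and "spatial" in results:
        ly = run_stage("layers", lambda: layers_mod.run_layer_stage(
            bundle.spectra, results["proteomics"]["identified"],
            results["spatial"]["zone_markers"], bundle.histo,
        ))
        results["layers"] = ly
        ly["layer_model"].table.to_csv(outdir / "layer_model.tsv", sep="\t")
        with open(outdir / "layer_model.json", "w") as fh:
            json.dump(ly["layer_model"].to_json_dict(), fh, indent=1, sort_keys=True)
        ly["control"]["correlation"].to_csv(outdir / "sample_correlation.csv")
        (outdir / "samples.nwk").write_text(ly["control"]["newick"])

    complete = set(stages) <= set(results)
    run_log = {
        "stages_run": [entry["stage"] for entry in log],
        "stages_requested": list(stages),
        "partial": not complete,
        "seed": seed,
        "config": {k: v for k, v in config.items() if k != "stages"},
        "input_hashes": bundle.provenance,
        "log": log,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1, sort_keys=True)
    results["run_log"] = run_log
    return results
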