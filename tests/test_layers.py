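"""Urea-gradient enrichment, dissolved control, histology matching, model."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import silkgland as sg
from silkgland import layers as ly
from silkgland.containers import SpectraTable
from silkgland.design import SILK_PROTEIN_IDS
from silkgland.reference import pearson_matrix_naive, welch_t_naive


def _urea_table(values: dict, preparations=("intact",)):
    """values[protein][molarity] -> list of replicate counts."""
    counts, meta = {}, {}
    for prep in preparations:
        for mol in (2.0, 4.0, 8.0):
            n_rep = len(next(iter(values.values()))[mol])
            for r in range(n_rep):
                sid = f"u{int(mol)}_{prep}_r{r}"
                counts[sid] = {p: values[p][mol][r] for p in values}
                meta[sid] = dict(source="fiber", solvent="urea", molarity=mol,
                                 preparation=prep, replicate=r + 1)
    return SpectraTable(counts=pd.DataFrame(counts), sample_meta=pd.DataFrame(meta).T)


def test_single_protein_profile_is_100_percent():
    t = _urea_table({"P1": {2.0: [5, 8], 4.0: [9, 9], 8.0: [20, 30]}})
    means, pct = ly.relative_urea_profiles(t, ["P1"])
    assert np.allclose(means.to_numpy(), 100.0)


def test_two_equal_proteins_split_50_50():
    vals = {2.0: [10, 10], 4.0: [20, 20], 8.0: [30, 30]}
    t = _urea_table({"P1": vals, "P2": vals})
    means, _ = ly.relative_urea_profiles(t, ["P1", "P2"])
    assert np.allclose(means.to_numpy(), 50.0)


def test_core_protein_profile_increases_with_molarity(default_design):
    spectra = sg.simulate_proteomics(default_design, 13)
    fiber = spectra.select_samples(spectra.sample_meta["source"] == "fiber")
    means, _ = ly.relative_urea_profiles(fiber, SILK_PROTEIN_IDS)
    core = default_design.protein_table.query("layer == 'core'").index
    for pid in core:
        prof = means.loc[pid]
        assert prof[2.0] < prof[4.0] < prof[8.0]


def test_enrichment_2m_example_matches_reference_t():
    t = _urea_table({
        "P1": {2.0: [30, 31, 29], 4.0: [20, 20, 20], 8.0: [10, 11, 9]},
        "P2": {2.0: [70, 69, 71], 4.0: [80, 80, 80], 8.0: [90, 89, 91]},
    })
    out = ly.urea_enrichment_test(t, ["P1", "P2"], adjust=False)
    assert out.loc["P1", "urea_class"] == "enriched-2M"
    assert out.loc["P2", "urea_class"] == "enriched-8M"
    a = [30, 31, 29]
    b = [10, 11, 9]
    t_ref, df_ref = welch_t_naive(a, b)
    p_ref = 2 * stats.t.sf(abs(t_ref), df_ref)
    assert out.loc["P1", "p"] == pytest.approx(p_ref, abs=1e-9)


def test_identical_groups_unclassified_or_peak4m():
    flat = {2.0: [10, 10, 10], 4.0: [10, 10, 10], 8.0: [10, 10, 10]}
    peak = {2.0: [10, 10, 10], 4.0: [40, 40, 40], 8.0: [10, 10, 10]}
    t = _urea_table({"FLAT": flat, "PEAK": peak})
    out = ly.urea_enrichment_test(t, ["FLAT", "PEAK"])
    assert out.loc["FLAT", "urea_class"] == "unclassified"
    assert out.loc["PEAK", "urea_class"] == "peak-4M"


def test_middle_layer_protein_peaks_at_4m_across_seeds(default_design):
    hits = 0
    middle = default_design.protein_table.query("layer == 'middle'").index
    for seed in range(10):
        spectra = sg.simulate_proteomics(default_design, seed)
        fiber = spectra.select_samples(spectra.sample_meta["source"] == "fiber")
        out = ly.urea_enrichment_test(fiber, SILK_PROTEIN_IDS)
        if (out.loc[middle, "urea_class"] == "peak-4M").all():
            hits += 1
    assert hits >= 8


# ----------------------------------------------------- intact vs dissolved

def test_correlation_matrix_contract(default_design):
    spectra = sg.simulate_proteomics(default_design, 17)
    fiber = spectra.select_samples(spectra.sample_meta["source"] == "fiber")
    res = ly.intact_vs_dissolved_compare(fiber, SILK_PROTEIN_IDS)
    corr = res["correlation"]
    assert np.allclose(corr, corr.T)
    assert np.allclose(np.diag(corr), 1.0)
    # cross-check a few entries against the scalar-loop Pearson oracle
    cols = {c: corr.index.tolist() for c in corr.columns[:3]}
    _, pct = ly.relative_urea_profiles(fiber, SILK_PROTEIN_IDS)
    naive = pearson_matrix_naive(
        {c: pct[c].tolist() for c in corr.columns[:3]}
    )
    for a in corr.columns[:3]:
        for b in corr.columns[:3]:
            if a in pct and b in pct:
                assert corr.loc[a, b] == pytest.approx(naive[a][b], abs=1e-9)


def test_duplicate_samples_merge_first():
    vals = {"P1": {2.0: [30, 30], 4.0: [22, 21], 8.0: [5, 9]},
            "P2": {2.0: [70, 70], 4.0: [78, 79], 8.0: [95, 91]}}
    t = _urea_table(vals, preparations=("intact", "dissolved"))
    res = ly.intact_vs_dissolved_compare(t, ["P1", "P2"])
    corr = res["correlation"]
    # the duplicated 2M intact replicates are perfectly correlated
    assert corr.loc["u2_intact_r0", "u2_intact_r1"] == pytest.approx(1.0)
    assert "(" in res["newick"] and res["newick"].endswith(";")


def test_layering_signal_only_in_intact_preparation(default_design):
    """Within-preparation r at 2 M exceeds between-preparation r at 2 M."""
    spectra = sg.simulate_proteomics(default_design, 19)
    fiber = spectra.select_samples(spectra.sample_meta["source"] == "fiber")
    res = ly.intact_vs_dissolved_compare(fiber, SILK_PROTEIN_IDS)
    corr = res["correlation"]
    meta = fiber.sample_meta
    i2 = [c for c in corr.columns if meta.loc[c, "molarity"] == 2.0
          and meta.loc[c, "preparation"] == "intact"]
    d2 = [c for c in corr.columns if meta.loc[c, "molarity"] == 2.0
          and meta.loc[c, "preparation"] == "dissolved"]
    within = np.mean([corr.loc[a, b] for a in i2 for b in i2 if a != b]
                     + [corr.loc[a, b] for a in d2 for b in d2 if a != b])
    between = np.mean([corr.loc[a, b] for a in i2 for b in d2])
    assert within > between


# --------------------------------------------------------------- histology

def test_lumen_object_at_centroid_assigned_to_zone(default_design):
    cfg = {"histology": {"sd": 0.0}}
    design = sg.make_design(cfg)
    histo = sg.simulate_histology(design, 23)
    res = ly.histo_match_layers(histo)
    assert res["mapping"] == {"I": "A", "II": "B", "III": "C"}
    for layer, frac in res["vote_fractions"].items():
        assert max(frac.values()) == pytest.approx(1.0)


def test_histology_mapping_recovered_with_noise(default_design):
    histo = sg.simulate_histology(default_design, 29)
    res = ly.histo_match_layers(histo)
    assert res["mapping"] == {"I": "A", "II": "B", "III": "C"}


def test_single_equidistant_lumen_object_unmapped():
    rows = []
    for zone, (h, e) in {"A": (0.0, 0.0), "B": (1.0, 1.0)}.items():
        for i in range(3):
            rows.append(dict(object_id=f"v{zone}{i}", compartment="vesicle",
                             zone=zone, layer=None, hematoxylin=h, eosin=e))
    rows.append(dict(object_id="lum", compartment="lumen-layer", zone=None,
                     layer="I", hematoxylin=0.5, eosin=0.5))
    histo = pd.DataFrame(rows)
    with pytest.warns(UserWarning, match="tie"):
        res = ly.histo_match_layers(histo)
    assert res["mapping"]["I"] is None


# -------------------------------------------------------------- layer model

@pytest.mark.parametrize("zone,urea,layer,consistent", [
    ("A", "enriched-8M", "core", True),
    ("B", "peak-4M", "middle", True),
    ("C", "enriched-2M", "outer", True),
    ("A", "enriched-2M", "core", False),
    ("mixed", "peak-4M", "middle", False),
    ("mixed", "unclassified", "unresolved", False),
])
def test_layer_model_join_rules(zone, urea, layer, consistent):
    zones = pd.Series({"P1": zone})
    urea_classes = pd.DataFrame({
        "urea_class": [urea], "t": [0.0], "padj": [1.0],
        "mean_2M": [1.0], "mean_4M": [1.0], "mean_8M": [1.0],
    }, index=["P1"])
    model = ly.build_layer_model(zones, urea_classes, ["P1"])
    row = model.table.loc["P1"]
    assert row["layer"] == layer
    assert bool(row["consistency"]) == consistent


def test_protein_missing_from_zone_input_unresolved():
    model = ly.build_layer_model(pd.Series(dtype=object), pd.DataFrame(
        columns=["urea_class", "t", "padj", "mean_2M", "mean_4M", "mean_8M"]
    ), ["P1"])
    assert model.table.loc["P1", "layer"] == "unresolved"


def test_full_layer_stage_recovers_truth(pipeline_results, default_bundle):
    """>=90% of proteins get their planted layer with consistency=true."""
    lm = pipeline_results["layers"]["layer_model"].table
    truth = pd.Series(default_bundle.truth.protein_layer).loc[lm.index]
    ok = (lm["layer"] == truth) & lm["consistency"]
    assert ok.mean() >= 0.9
    assert len(lm) == 18


def test_dissolved_control_does_not_change_layers(pipeline_results, default_bundle):
    """The control only feeds the consistency report, never the layers."""
    spectra = default_bundle.spectra
    meta = spectra.sample_meta
    no_dissolved = spectra.select_samples(meta["preparation"] != "dissolved")
    identified = pipeline_results["proteomics"]["identified"]
    zones = pipeline_results["layers"]["zones"]
    fiber = no_dissolved.select_samples(
        no_dissolved.sample_meta["source"] == "fiber")
    urea = ly.urea_enrichment_test(fiber, identified)
    model = ly.build_layer_model(zones, urea, identified)
    full = pipeline_results["layers"]["layer_model"].table
    assert model.table["layer"].equals(full["layer"])
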