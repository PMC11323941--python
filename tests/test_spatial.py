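"""Spatial zones, perimeter trends, deconvolution, class summaries."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import silkgland as sg
from silkgland import spatial as sp
from silkgland.containers import ExpressionMatrix, ValidationError
from silkgland.reference import pearson_naive, simplex_grid_fit


def _spots(rows):
    return pd.DataFrame(rows, columns=["spot_id", "section", "x", "y", "zone",
                                       "region_id", "perimeter"])


# ----------------------------------------------------------- class splits

@pytest.mark.parametrize("perimeter,expected", [
    (400, "A-proximal"),
    (1500, "A-distal"),
    (500, "A-middle"),
    (1000, "A-middle"),
    (750, "A-middle"),
])
def test_zoneA_perimeter_split(perimeter, expected):
    spots = _spots([("s1", 1, 0, 0, "A", "r1", perimeter)])
    out = sp.split_zoneA_regions(spots)
    assert out.loc[0, "positional_class"] == expected


def test_zoneA_missing_perimeter_lists_regions():
    spots = _spots([("s1", 1, 0, 0, "A", "rX", np.nan)])
    with pytest.raises(ValidationError, match="rX"):
        sp.split_zoneA_regions(spots)


# ------------------------------------------------------- region assignment

def _regions(rows):
    return pd.DataFrame(rows, columns=["region_id", "section", "zone",
                                       "x", "y", "perimeter"])


def test_spot_at_centroid_assigned_there():
    spots = _spots([("s1", 1, 10, 10, "A", None, np.nan)])
    regions = _regions([("r1", 1, "A", 10, 10, 300), ("r2", 1, "A", 99, 99, 400)])
    out = sp.assign_spots_to_regions(spots, regions)
    assert out.loc[0, "region_id"] == "r1"
    assert out.loc[0, "perimeter"] == 300


def test_equidistant_tie_resolves_to_lowest_region_id():
    spots = _spots([("s1", 1, 50, 0, "A", None, np.nan)])
    regions = _regions([("r7", 1, "A", 0, 0, 300), ("r3", 1, "A", 100, 0, 400)])
    out = sp.assign_spots_to_regions(spots, regions)
    assert out.loc[0, "region_id"] == "r3"


def test_zone_constraint_respected():
    spots = _spots([("s1", 1, 0, 0, "B", None, np.nan)])
    regions = _regions([("rA", 1, "A", 0, 0, 300), ("rB", 1, "B", 500, 500, 900)])
    out = sp.assign_spots_to_regions(spots, regions)
    assert out.loc[0, "region_id"] == "rB"


# ----------------------------------------------------------------- trends

def _trend_fixture(default_sim):
    spots = default_sim["spots"]
    counts = default_sim["spatial"]
    truth = default_sim["truth"]
    marker_of = pd.Series(truth.gene_marker_of)
    sets = {
        "ZoneA_MaSp1": marker_of.index[marker_of == "ZoneA_MaSp1"].tolist(),
        "ZoneA_MaSp2": marker_of.index[marker_of == "ZoneA_MaSp2"].tolist(),
    }
    return spots, counts, sets


def test_perimeter_trend_signs_match_planted_gradient(default_sim):
    spots, counts, sets = _trend_fixture(default_sim)
    table = sp.expression_perimeter_trend(spots, counts, sets)
    assert table.loc["ZoneA_MaSp2", "slope"] < 0
    assert table.loc["ZoneA_MaSp2", "p"] < 0.05
    assert table.loc["ZoneA_MaSp1", "slope"] > 0
    assert table.loc["ZoneA_MaSp1", "p"] < 0.05


def test_trend_constant_expression_flagged(default_sim):
    spots = default_sim["spots"]
    counts = default_sim["spatial"]
    flat = counts.with_values(
        pd.DataFrame(1.0, index=counts.genes, columns=counts.units), "counts"
    )
    table = sp.expression_perimeter_trend(spots, flat, {"flat": list(counts.genes[:5])})
    assert table.loc["flat", "slope"] == 0.0
    assert table.loc["flat", "undefined"]


def test_trend_slope_matches_closed_form_ols(default_sim):
    spots, counts, sets = _trend_fixture(default_sim)
    table = sp.expression_perimeter_trend(spots, counts, sets)
    zone_a = spots[spots["zone"] == "A"]
    norm = sp.depth_normalize(counts)
    per_spot = norm.loc[sets["ZoneA_MaSp2"]].mean(axis=0)
    means = per_spot.loc[zone_a["spot_id"]].groupby(zone_a["region_id"].to_numpy()).mean()
    x = zone_a.groupby("region_id")["perimeter"].first().loc[means.index].to_numpy()
    y = means.to_numpy()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    assert table.loc["ZoneA_MaSp2", "slope"] == pytest.approx(slope, rel=1e-9)


# ------------------------------------------------------------ correlation

def test_perfect_negative_correlation():
    table = pd.DataFrame({
        "zone": ["A"] * 5,
        "hematoxylin": [5, 4, 3, 2, 1],
        "perimeter": [100, 200, 300, 400, 500],
    })
    r, p, n = sp.hematoxylin_perimeter_correlation(table)
    assert r == pytest.approx(-1.0)
    assert n == 5


def test_constant_hematoxylin_flagged_undefined():
    table = pd.DataFrame({
        "zone": ["A"] * 4, "hematoxylin": [1, 1, 1, 1],
        "perimeter": [1, 2, 3, 4],
    })
    with pytest.warns(UserWarning):
        r, p, n = sp.hematoxylin_perimeter_correlation(table)
    assert np.isnan(r) and np.isnan(p)


def test_simulated_gradient_negative_at_n80(default_design):
    histo = sg.simulate_histology(default_design, 21)
    ves = histo[histo["compartment"] == "vesicle"].rename(columns={})
    r, p, n = sp.hematoxylin_perimeter_correlation(ves)
    assert n == 80
    assert r < 0 and p < 0.05
    x = ves.loc[ves["zone"] == "A", "perimeter"].tolist()
    y = ves.loc[ves["zone"] == "A", "hematoxylin"].tolist()
    assert r == pytest.approx(pearson_naive(y, x), abs=1e-12)


# -------------------------------------------------------------- signatures

def _sig_inputs():
    genes = ["ga", "gb", "gc", "gd"]
    cells = ExpressionMatrix(
        values=pd.DataFrame(
            [[40, 2], [16, 4], [30, 30], [0, 0]], index=genes, columns=["c1", "c2"]
        ).astype(float),
        layer="counts",
    )
    labels = pd.Series(["T1", "T2"], index=["c1", "c2"])
    spatial = ExpressionMatrix(
        values=pd.DataFrame(
            np.tile([[4], [4], [4], [0]], (1, 60)), index=genes,
            columns=[f"sp{i}" for i in range(60)]
        ).astype(float),
        layer="counts",
    )
    return cells, labels, spatial


def test_signature_filters_boundaries():
    cells, labels, spatial = _sig_inputs()
    fc = pd.DataFrame({"T1": [3.0, 2.0, 0.0, 5.0], "T2": [0.0, 0.0, 0.0, 5.0]},
                      index=cells.genes)
    sig = sp.build_signatures(cells, labels, spatial, marker_log2fc=fc,
                              min_counts=200, min_spots=50)
    assert "ga" in sig.index       # log2FC 3 > 2, 240 counts in 60 spots
    assert "gb" not in sig.index   # log2FC exactly 2.0 -> dropped (strict >)
    assert "gd" not in sig.index   # absent from spatial data
    # exactly 200 counts in exactly 50 spots qualifies
    spatial2 = ExpressionMatrix(
        values=pd.DataFrame(
            np.tile([[4], [4], [4], [0]], (1, 50)), index=cells.genes,
            columns=[f"sp{i}" for i in range(50)]
        ).astype(float),
        layer="counts",
    )
    sig2 = sp.build_signatures(cells, labels, spatial2, marker_log2fc=fc,
                               min_counts=200, min_spots=50)
    assert "ga" in sig2.index


def test_empty_signature_set_reports_counts():
    cells, labels, spatial = _sig_inputs()
    fc = pd.DataFrame({"T1": [0.0] * 4, "T2": [0.0] * 4}, index=cells.genes)
    with pytest.raises(ValidationError, match="log2FC"):
        sp.build_signatures(cells, labels, spatial, marker_log2fc=fc)


# ------------------------------------------------------------ deconvolution

def _toy_signatures():
    sig = np.array([[10.0, 1.0], [1.0, 10.0], [5.0, 5.0]])
    return pd.DataFrame(sig, index=["g1", "g2", "g3"], columns=["A", "B"])


def test_noiseless_mixture_recovered_exactly():
    sig = _toy_signatures()
    y = 0.5 * sig["A"] + 0.5 * sig["B"]
    spots = ExpressionMatrix(values=pd.DataFrame({"sp1": y * 3}), layer="counts")
    props, diag = sp.deconvolve_spots(spots, sig)
    assert props.loc["sp1"].to_numpy() == pytest.approx([0.5, 0.5], abs=1e-6)
    assert not diag.loc["sp1", "degenerate"]


def test_pure_spot_recovered():
    sig = _toy_signatures()
    spots = ExpressionMatrix(values=pd.DataFrame({"sp1": sig["B"] * 7}), layer="counts")
    props, _ = sp.deconvolve_spots(spots, sig)
    assert props.loc["sp1", "B"] == pytest.approx(1.0, abs=1e-9)


def test_collinear_signatures_rejected():
    sig = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [2.0, 4.0, 6.0]},
                       index=["g1", "g2", "g3"])
    spots = ExpressionMatrix(values=pd.DataFrame({"sp1": [1.0, 2.0, 3.0]},
                                                 index=sig.index), layer="counts")
    with pytest.raises(ValidationError, match="collinear"):
        sp.deconvolve_spots(spots, sig)


def test_noisy_three_type_mixtures_close_to_truth_and_grid_oracle():
    signatures, spots_df, truth = sg.simulate_deconv_toy(
        n_types=3, n_genes=120, n_spots=60, seed=5
    )
    spots = ExpressionMatrix(values=spots_df, layer="counts")
    props, _ = sp.deconvolve_spots(spots, signatures)
    rmse = np.sqrt(((props.to_numpy() - truth.to_numpy()) ** 2).mean())
    assert rmse <= 0.10
    norm = sp.depth_normalize(spots)
    S = signatures.to_numpy()
    for spot in spots_df.columns[:10]:
        grid, _ = simplex_grid_fit(S, norm[spot].to_numpy(), step=0.01)
        assert np.abs(props.loc[spot].to_numpy() - grid).max() <= 0.02


def test_proportions_on_simplex(pipeline_results):
    props = pipeline_results["spatial"]["proportions"]
    arr = props.to_numpy()
    assert (arr >= -1e-12).all()
    assert np.allclose(arr.sum(axis=1), 1.0, atol=1e-9)


# -------------------------------------------------------- class summaries

def test_class_proportions_uniform_in_uniform_out():
    props = pd.DataFrame(np.full((4, 3), 1 / 3),
                         index=["s1", "s2", "s3", "s4"], columns=["A", "B", "C"])
    spots = pd.DataFrame({
        "spot_id": ["s1", "s2", "s3", "s4"],
        "positional_class": ["B", "B", "C", "C"],
    })
    out = sp.class_proportions(props, spots)
    assert np.allclose(out.to_numpy(), 1 / 3)


def test_class_proportion_rows_sum_to_one(pipeline_results):
    per_class = pipeline_results["spatial"]["class_proportions"]
    assert np.allclose(per_class.sum(axis=1), 1.0, atol=1e-9)


def test_end_to_end_argmax_matches_planted_type(pipeline_results, default_bundle):
    """Per positional class the dominant estimated type is the planted one."""
    per_class = pipeline_results["spatial"]["class_proportions"]
    ct = pipeline_results["sc"]["cell_table"]
    truth_types = pd.Series(default_bundle.truth.cell_types).loc[ct.index]
    cluster_of_type = pd.crosstab(ct["cluster"], truth_types).idxmax(axis=0)
    expected_dominant = {
        "A-proximal": "ZoneA_MaSp2", "A-middle": "ZoneA_MaSp1",
        "A-distal": "ZoneA_MaSp1", "B": "ZoneB_MaSp3", "C": "ZoneC_SpiCE",
    }
    for cls, ctype in expected_dominant.items():
        assert per_class.loc[cls].idxmax() == cluster_of_type[ctype]
    # the MaSp2-type fraction decreases proximal -> distal
    masp2 = cluster_of_type["ZoneA_MaSp2"]
    vals = per_class.loc[["A-proximal", "A-middle", "A-distal"], masp2]
    assert vals.is_monotonic_decreasing
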