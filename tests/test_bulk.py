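"""Bulk gene-set filter: TPM, VST, PCA steps, PLS-DA, DE."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import silkgland as sg
from silkgland import bulk as bk
from silkgland.containers import ExpressionMatrix, ValidationError
from silkgland import reference as ref
from tests.conftest import make_bulk_matrix


# ---------------------------------------------------------------------- TPM

def test_tpm_hand_example():
    m = make_bulk_matrix(np.array([[10.0], [10.0]]), ["tail"],
                         lengths=np.array([100.0, 200.0]))
    tpm = bk.compute_tpm(m).values.iloc[:, 0]
    assert tpm.iloc[0] == pytest.approx(666666.67, abs=0.01)
    assert tpm.iloc[1] == pytest.approx(333333.33, abs=0.01)


def test_tpm_single_gene_and_symmetry():
    single = make_bulk_matrix(np.array([[7.0]]), ["tail"])
    assert bk.compute_tpm(single).values.iloc[0, 0] == pytest.approx(1e6)
    equal = make_bulk_matrix(np.full((4, 2), 5.0), ["tail", "sac"])
    assert np.allclose(bk.compute_tpm(equal).values.to_numpy(), 250000.0)


def test_tpm_matches_naive_oracle(rng):
    counts = rng.integers(1, 1000, size=(30, 1)).astype(float)
    lengths = rng.integers(200, 5000, size=30).astype(float)
    m = make_bulk_matrix(counts, ["tail"], lengths=lengths)
    ours = bk.compute_tpm(m).values.iloc[:, 0]
    naive = ref.tpm_naive(
        {f"g{i}": counts[i, 0] for i in range(30)},
        {f"g{i}": lengths[i] for i in range(30)},
    )
    for i in range(30):
        assert ours.iloc[i] == pytest.approx(naive[f"g{i}"], abs=1e-9 * 1e6)


def test_tpm_zero_depth_unit_named():
    m = make_bulk_matrix(np.array([[0.0, 5.0], [0.0, 5.0]]), ["tail", "sac"])
    with pytest.raises(ValidationError, match="tail_r0"):
        bk.compute_tpm(m)


# ---------------------------------------------------------------------- VST

def test_vst_identical_columns_unit_size_factors():
    m = make_bulk_matrix(np.tile([[10.0], [20.0], [30.0]], (1, 3)),
                         ["tail", "tail", "tail"])
    sf = bk.size_factors(m.values)
    assert np.allclose(sf, 1.0)
    v = bk.vst(m).values
    assert np.allclose(v.iloc[:, 0], v.iloc[:, 1])


def test_vst_doubled_column_size_factor_ratio():
    base = np.array([[10.0], [20.0], [40.0], [100.0]])
    m = make_bulk_matrix(np.hstack([base, 2 * base]), ["tail", "tail"])
    sf = bk.size_factors(m.values)
    assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0, abs=1e-9)


def test_vst_monotone_within_unit(rng):
    counts = rng.integers(0, 500, size=(40, 3)).astype(float)
    counts[0] = [1, 1, 1]  # keep a strictly positive gene for size factors
    m = make_bulk_matrix(counts, ["tail", "sac", "duct"])
    v = bk.vst(m).values
    for j in range(3):
        order = np.argsort(counts[:, j], kind="stable")
        assert (np.diff(v.iloc[order, j]) >= -1e-12).all()


def test_vst_all_zero_rejected():
    m = make_bulk_matrix(np.zeros((3, 2)), ["tail", "sac"])
    with pytest.raises(ValidationError):
        bk.vst(m)


# ------------------------------------------------------------- sign filters

def _two_group_matrix(rng, n_bg=40):
    """body-high gene 0, head-high gene 1, flat gene 2, background noise."""
    tissues = ["head"] * 3 + ["body"] * 3
    vals = rng.normal(10, 0.2, size=(n_bg + 3, 6))
    vals[0, 3:] += 5.0     # gland-side (body) specific
    vals[1, :3] += 5.0     # head specific
    vals[2, :] = 10.0      # identical in all samples
    m = make_bulk_matrix(np.maximum(vals, 0), tissues)
    return ExpressionMatrix(values=m.values, layer="vst", unit_meta=m.unit_meta)


def test_sign_filter_keeps_gland_side_gene(rng):
    m = _two_group_matrix(rng)
    kept = bk.pca_sign_filter(m, group_pos="body", group_neg="head")
    assert "g0" in kept
    assert "g1" not in kept


def test_sign_filter_matches_covariance_eigenvector(rng):
    """PC1 loading signs agree with a brute-force covariance eigenvector."""
    m = _two_group_matrix(rng)
    kept = bk.pca_sign_filter(m, group_pos="body", group_neg="head")
    X = m.values.to_numpy().T
    C = np.cov(X, rowvar=False)
    w, v = np.linalg.eigh(C)
    pc1 = v[:, -1]
    scores = (X - X.mean(axis=0)) @ pc1
    if scores[3:].mean() < 0:  # orient toward body
        pc1 = -pc1
    brute = set(m.genes[pc1 > 1e-10])
    assert set(kept) == brute


def test_sign_filter_identical_gene_dropped_and_rescue(rng):
    m = _two_group_matrix(rng)
    kept = bk.pca_sign_filter(m, group_pos="body", group_neg="head")
    assert "g2" not in kept
    rescued = bk.pca_sign_filter(m, group_pos="body", group_neg="head",
                                 rescue=["g1", "g2"])
    assert {"g1", "g2"} <= set(rescued)


# ------------------------------------------------------- quadrant labelling

@pytest.mark.parametrize("pc1,pc2,expected", [
    (-0.2, 0.3, "tail"),
    (0.1, -0.2, "duct"),
    (0.25, 0.1, "sac"),
])
def test_pca_quadrant_rule(pc1, pc2, expected):
    assert bk.pca_quadrant_label(pc1, pc2) == expected


@pytest.mark.parametrize("lv1,lv2,expected", [
    (0.3, -0.1, "sac"),
    (-0.4, 0.2, "tail"),
    (0.3, 0.4, "duct"),
])
def test_plsda_quadrant_rule(lv1, lv2, expected):
    assert bk.plsda_quadrant_label(lv1, lv2) == expected


def test_gene_at_origin_excluded(default_sim):
    gs = bk.run_geneset_stage(default_sim["bulk"])
    tab = gs.table.dropna(subset=["distance"])
    assert (tab["in_gene_set"] == (tab["distance"] > bk.DISTANCE_CUTOFF)).all()
    assert not tab.loc[tab["distance"] <= bk.DISTANCE_CUTOFF, "in_gene_set"].any()


def test_filter_steps_are_monotone(default_sim):
    gs = bk.run_geneset_stage(default_sim["bulk"])
    t = gs.table
    assert (t["kept_step1"] <= t["kept_tpm"]).all()
    assert (t["kept_step2"] >= t["kept_step1"] & t["kept_step2"]).all()
    # step2 adds only rescue genes beyond step1 survivors
    extra = t[t["kept_step2"] & ~t["kept_step1"]]
    assert set(extra.index) <= {"MaSp4", "SpiCE-LMa4"}
    assert (t["in_gene_set"].to_numpy() <= t["kept_step2"].to_numpy()).all()


def test_tpm_prefilter_rule_and_silent_depletion(default_design, default_sim):
    """kept iff TPM > 4 in >= 1 sample; near-silent genes mostly drop out."""
    gs = bk.run_geneset_stage(default_sim["bulk"])
    tpm = bk.compute_tpm(default_sim["bulk"]).values
    expected = (tpm > 4.0).any(axis=1)
    assert gs.table["kept_tpm"].equals(expected)
    silent = np.array(default_design.gene_ids())[default_design.marker_index()["silent"]]
    background = gs.table["kept_tpm"].drop(silent)
    assert background.mean() > 0.99
    assert gs.table.loc[silent, "kept_tpm"].mean() < 0.8


# ----------------------------------------------------------------- PLS-DA

def test_plsda_q2_high_on_separated_classes(default_sim):
    gs = bk.run_geneset_stage(default_sim["bulk"])
    assert gs.plsda.q2 >= 0.8
    # scores of the two latent variables are uncorrelated on training data
    corr = np.corrcoef(gs.plsda.scores["LV1"], gs.plsda.scores["LV2"])[0, 1]
    assert abs(corr) < 1e-6
    assert gs.plsda.q2 <= 1.0


def test_plsda_permutation_null_q2_low(default_sim):
    gs = bk.run_geneset_stage(default_sim["bulk"])
    bulk = default_sim["bulk"]
    units = bulk.unit_meta.index[bulk.unit_meta["tissue"].isin(["tail", "sac", "duct"])]
    v = bk.vst(bk.tpm_prefilter(bulk)).subset_units(units).subset_genes(gs.gene_set)
    rng = np.random.default_rng(0)
    q2s = []
    for _ in range(20):
        perm = pd.Series(
            rng.permutation(v.unit_meta["tissue"].to_numpy()), index=v.units
        )
        meta = v.unit_meta.copy()
        meta["tissue"] = perm
        vm = ExpressionMatrix(values=v.values, layer="vst", unit_meta=meta)
        q2s.append(bk.plsda(vm).q2)
    assert np.median(q2s) <= 0.2


def test_plsda_engine_matches_nipals_oracle(rng):
    """sklearn-backed scores match a hand-coded NIPALS PLS2 up to sign."""
    X = rng.normal(size=(12, 8))
    Y = np.zeros((12, 3))
    Y[np.arange(12) % 3 == 0, 0] = 1
    Y[np.arange(12) % 3 == 1, 1] = 1
    Y[np.arange(12) % 3 == 2, 2] = 1
    from sklearn.cross_decomposition import PLSRegression
    model = PLSRegression(n_components=2, scale=False).fit(X, Y)
    T_ref, P_ref, W_ref, Q_ref = ref.nipals_pls2(X, Y, n_components=2)
    for k in range(2):
        a, b = model.x_scores_[:, k], T_ref[:, k]
        sign = np.sign(a @ b)
        # sklearn's inner NIPALS loop stops at tol 1e-6; allow that slack
        assert np.allclose(a, sign * b, atol=2e-3)


def test_plsda_single_class_rejected(default_sim):
    bulk = default_sim["bulk"]
    units = bulk.unit_meta.index[bulk.unit_meta["tissue"] == "tail"]
    v = bk.vst(bulk).subset_units(units)
    with pytest.raises(ValidationError):
        bk.plsda(v)


# ------------------------------------------------------------------- DE

def _de_counts(n_de, n_flat, fold, rng, reps=(3, 2, 2)):
    tissues = ["tail"] * reps[0] + ["sac"] * reps[1] + ["duct"] * reps[2]
    n = n_de + n_flat
    base = rng.poisson(200, size=(n, sum(reps))).astype(float)
    base[:n_de, :reps[0]] *= fold
    return make_bulk_matrix(base, tissues)


def test_de_flat_gene_not_retained(rng):
    m = _de_counts(5, 20, 16.0, rng)
    de = bk.differential_expression(m, "tail")
    flat = [f"g{i}" for i in range(5, 25)]
    assert not set(flat) & set(de.index)


def test_de_planted_eightfold_gene_retained(rng):
    m = _de_counts(3, 40, 8.0, rng)
    de = bk.differential_expression(m, "tail")
    assert {"g0", "g1", "g2"} <= set(de.index)
    assert (de["fold_change"] > 4).all()
    assert (de["padj"] < 0.001).all()


def test_de_capped_at_100(rng):
    m = _de_counts(150, 350, 32.0, rng, reps=(4, 3, 3))
    de = bk.differential_expression(m, "tail")
    assert len(de) == 100
    assert (np.diff(de["padj"]) >= -1e-15).all()


def test_de_pvalues_match_reference_welch(rng):
    m = _de_counts(2, 10, 8.0, rng, reps=(4, 3, 3))
    de = bk.differential_expression(m, "tail", alpha=1.0, min_fc=0.0, cap=1000)
    v = bk.vst(m).values
    for gene in ["g0", "g5"]:
        a = v.loc[gene].iloc[:4].tolist()
        b = v.loc[gene].iloc[4:].tolist()
        t_ref, df_ref = ref.welch_t_naive(a, b)
        p_ref = 2 * stats.t.sf(abs(t_ref), df_ref)
        assert de.loc[gene, "p"] == pytest.approx(p_ref, abs=1e-9)


def test_de_bh_matches_naive(rng):
    m = _de_counts(2, 30, 8.0, rng, reps=(4, 3, 3))
    de = bk.differential_expression(m, "tail", alpha=1.0, min_fc=0.0, cap=1000)
    naive = ref.bh_adjust_naive(de["p"].tolist())
    assert np.allclose(de["padj"].to_numpy(), naive, atol=1e-12)
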