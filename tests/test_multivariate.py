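import numpy as np
import pandas as pd
import pytest

import germdrift as gd
from germdrift.core import SampleDesign, ValidationError
from germdrift.multivariate import (
    build_diff_matrix,
    pca,
    pca_on_differences,
    subset_wca_pve,
    wca,
    wca_scores,
)
from germdrift.simulate import SimulationParams, simulate_counts


def pca_oracle(x, classes=None):
    """Eigendecompose the explicitly formed 1/n-weighted covariance matrix.

    With ``classes`` the matrix is globally centered then class-centered first,
    mirroring the within-class algorithm by an independent route.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    if classes is not None:
        classes = np.asarray(classes)
        for cls in np.unique(classes):
            mask = classes == cls
            xc[mask] -= xc[mask].mean(axis=0)
    cov = xc.T @ xc / n
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    return eigval[order], eigvec[:, order], xc


def assert_matches_oracle(eigenvalues, loadings, oracle_eig, oracle_vec, atol=1e-10):
    r = eigenvalues.size
    assert np.allclose(eigenvalues, oracle_eig[:r], atol=atol)
    for j in range(r):
        dot = abs(loadings[:, j] @ oracle_vec[:, j])
        assert dot == pytest.approx(1.0, abs=1e-8)


# ---------------------------------------------------------------------------
# pca


def test_pca_identical_rows_all_zero_eigenvalues():
    res = pca(np.ones((4, 3)) * 2.5)
    assert np.allclose(res.eigenvalues, 0.0)


def test_pca_two_point_hand_eigendecomposition():
    # rows (0,0) and (2,0): centered (-1,0),(1,0); 1/n covariance has
    # eigenvalue 1 along variable 1
    res = pca(np.array([[0.0, 0.0], [2.0, 0.0]]))
    assert res.eigenvalues == pytest.approx([1.0])
    assert abs(res.variable_loadings[0, 0]) == pytest.approx(1.0)
    assert res.variable_loadings[1, 0] == pytest.approx(0.0, abs=1e-12)
    assert res.percent_variance == pytest.approx([100.0])


def test_pca_matches_covariance_oracle():
    rng = np.random.default_rng(17)
    x = rng.normal(size=(8, 5))
    res = pca(x)
    eig, vec, xc = pca_oracle(x)
    assert_matches_oracle(res.eigenvalues, res.variable_loadings, eig, vec)
    assert np.allclose(res.row_coordinates, xc @ res.variable_loadings)


def test_pca_loading_columns_orthonormal():
    rng = np.random.default_rng(3)
    res = pca(rng.normal(size=(10, 6)))
    gram = res.variable_loadings.T @ res.variable_loadings
    assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-9)
    assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)
    assert (np.diff(res.eigenvalues) <= 1e-12).all()


def test_pca_requires_two_individuals():
    with pytest.raises(ValidationError, match="2 individuals"):
        pca(np.ones((1, 4)))


def test_pca_scaling_zero_variance_names_variable():
    x = pd.DataFrame([[1.0, 5.0], [2.0, 5.0]], columns=["ok", "flat"])
    with pytest.raises(ValidationError, match="flat"):
        pca(x, scale=True)


# ---------------------------------------------------------------------------
# difference matrix


def _toy_design():
    rows = []
    for lin in ("L1", "L2", "L3"):
        for state in ("P0", "F2", "F4_fertile", "F4_sterile"):
            rows.append((f"{lin}_{state}", lin, state))
    return SampleDesign(
        table=pd.DataFrame(rows, columns=["sample_id", "lineage", "state"]),
    )


def test_diff_matrix_zero_column_when_states_equal():
    design = _toy_design()
    rng = np.random.default_rng(0)
    lm = pd.DataFrame(rng.random((5, 12)), index=[f"g{i}" for i in range(5)],
                      columns=design.sample_ids)
    lm["L1_F2"] = lm["L1_P0"]
    dlm = build_diff_matrix(lm, design)
    assert np.allclose(dlm["L1:P0->F2"], 0.0)


def test_diff_matrix_has_nine_columns_in_documented_order():
    design = _toy_design()
    lm = pd.DataFrame(np.zeros((3, 12)), index=list("abc"), columns=design.sample_ids)
    dlm = build_diff_matrix(lm, design)
    assert list(dlm.columns) == [
        f"{lin}:{a}->{b}"
        for lin in ("L1", "L2", "L3")
        for a, b in (("P0", "F2"), ("F2", "F4_fertile"), ("F4_fertile", "F4_sterile"))
    ]


def test_diff_matrix_hand_subtraction():
    design = _toy_design()
    values = np.arange(24, dtype=float).reshape(2, 12)
    lm = pd.DataFrame(values, index=["g1", "g2"], columns=design.sample_ids)
    dlm = build_diff_matrix(lm, design)
    for lin_i, lin in enumerate(("L1", "L2", "L3")):
        for t_i, (a, b) in enumerate(
            (("P0", "F2"), ("F2", "F4_fertile"), ("F4_fertile", "F4_sterile"))
        ):
            expected = lm[f"{lin}_{b}"] - lm[f"{lin}_{a}"]
            assert np.allclose(dlm[f"{lin}:{a}->{b}"], expected)


def test_diff_matrix_missing_cell_identified():
    design = _toy_design()
    lm = pd.DataFrame(np.zeros((2, 11)), index=["g1", "g2"],
                      columns=design.sample_ids[:-1])  # drop L3_F4_sterile
    with pytest.raises(ValidationError, match=r"L3, F4_sterile"):
        build_diff_matrix(lm, design)


# ---------------------------------------------------------------------------
# pca on differences


def test_diff_pca_identical_columns_zero_eigenvalues():
    dlm = pd.DataFrame(np.tile([[1.0], [2.0], [3.0]], (1, 4)),
                       columns=[f"c{i}" for i in range(4)])
    res = pca_on_differences(dlm)
    assert np.allclose(res.eigenvalues, 0.0)


def test_diff_pca_matches_oracle():
    rng = np.random.default_rng(23)
    dlm = pd.DataFrame(rng.normal(size=(30, 9)), columns=[f"c{i}" for i in range(9)])
    res = pca_on_differences(dlm)
    eig, vec, _ = pca_oracle(dlm.to_numpy().T)
    assert_matches_oracle(res.eigenvalues, res.variable_loadings, eig, vec)


def test_diff_pca_recovers_two_step_clustering():
    # severity chosen so the early and terminal transitions carry the same
    # planted step while the middle transition is small (priming+amplification)
    params = SimulationParams(
        n_genes=1500, n_up_planted=300, n_down_planted=100, n_lineage_private=0,
        severity={"P0": 0.0, "F2": 1.0, "F4_fertile": 1.1, "F4_sterile": 2.4},
        effect_size_log2=2.0, dispersion=0.02, seed=31,
    )
    counts, design, _, _ = simulate_counts(params)
    lm = gd.log_transform(gd.normalize(counts, gd.estimate_size_factors(counts)))
    dlm = build_diff_matrix(lm, design)
    res = pca_on_differences(dlm)
    coord = pd.Series(res.row_coordinates[:, 0], index=res.row_ids)
    early = coord[[c for c in coord.index if "P0->F2" in c]]
    middle = coord[[c for c in coord.index if "F2->F4_fertile" in c]]
    late = coord[[c for c in coord.index if "F4_fertile->F4_sterile" in c]]
    # early and late transition profiles fall on the same side of PC1
    assert (np.sign(early) == np.sign(late.iloc[0])).all()
    assert (np.sign(middle) != np.sign(late.iloc[0])).all()
    # along PC1 same-transition profiles cluster tighter than different pairs
    groups = [early, middle, late]
    within = [
        abs(a - b)
        for grp in groups for i, a in enumerate(grp) for b in grp.iloc[i + 1:]
    ]
    between = [
        abs(a - b)
        for ga, gb in ((0, 1), (0, 2), (1, 2))
        for a in groups[ga] for b in groups[gb]
    ]
    assert max(within) < min(between)


# ---------------------------------------------------------------------------
# wca


def test_wca_singleton_classes_zero_everything():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(5, 8))
    with pytest.warns(UserWarning, match="singleton"):
        res = wca(x, classes=[f"c{i}" for i in range(5)])
    assert res.eigenvalues.size == 0 or np.allclose(res.eigenvalues, 0.0)
    assert res.within_total_ratio == pytest.approx(0.0, abs=1e-12)


def test_wca_single_class_equals_centered_pca():
    rng = np.random.default_rng(8)
    x = rng.normal(size=(7, 5))
    with pytest.warns(UserWarning, match="single class"):
        res = wca(x, classes=["all"] * 7)
    ref = pca(x)
    r = min(res.eigenvalues.size, ref.eigenvalues.size)
    assert np.allclose(res.eigenvalues[:r], ref.eigenvalues[:r], atol=1e-10)
    for j in range(r):
        assert abs(res.gene_loadings[:, j] @ ref.variable_loadings[:, j]) == pytest.approx(
            1.0, abs=1e-9
        )


def test_wca_matches_explicit_covariance_oracle():
    rng = np.random.default_rng(101)
    x = rng.normal(size=(12, 40))
    classes = np.repeat(["a", "b", "c"], 4)
    res = wca(x, classes)
    eig, vec, xc = pca_oracle(x, classes)
    assert_matches_oracle(res.eigenvalues, res.gene_loadings, eig, vec)
    # class means of the class-centered matrix are exactly zero
    for cls in "abc":
        assert np.allclose(xc[classes == cls].mean(axis=0), 0.0, atol=1e-10)
    assert res.pve.sum() == pytest.approx(100.0, abs=1e-9)
    assert res.eigenvalues.size == min(12 - 3, 40)


def test_wca_conservation_and_decomposition():
    rng = np.random.default_rng(55)
    x = rng.normal(size=(12, 20)) + np.repeat(rng.normal(size=(3, 20)), 4, axis=0)
    classes = np.repeat(["a", "b", "c"], 4)
    res = wca(x, classes)
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    total = (xc**2).sum() / n
    class_means = np.vstack([xc[classes == c].mean(axis=0) for c in "abc"])
    between = (np.repeat(class_means, 4, axis=0) ** 2).sum() / n
    within = res.eigenvalues.sum()
    assert within + between == pytest.approx(total, rel=1e-9)
    assert res.within_total_ratio == pytest.approx(within / total, rel=1e-12)


def test_wca_gene_permutation_equivariance():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(9, 15))
    classes = np.repeat(["a", "b", "c"], 3)
    perm = rng.permutation(15)
    res = wca(x, classes)
    res_perm = wca(x[:, perm], classes)
    assert np.allclose(res.eigenvalues, res_perm.eigenvalues, atol=1e-10)
    for j in range(res.eigenvalues.size):
        assert abs(res.gene_loadings[perm, j] @ res_perm.gene_loadings[:, j]) == pytest.approx(
            1.0, abs=1e-8
        )


def test_wca_class_label_length_mismatch():
    with pytest.raises(ValidationError, match="class label"):
        wca(np.ones((4, 3)), classes=["a", "b"])


def test_wca_scores_unit_norm_and_truth_separation(default_sim, default_analysis):
    scores = default_analysis.scores
    assert np.linalg.norm(scores) == pytest.approx(1.0, abs=1e-9)
    truth = default_sim.truth
    up = [g for g in truth.index[truth["label"] == "up_contributor"] if g in scores.index]
    background = [g for g in truth.index[truth["label"] == "background"] if g in scores.index]
    assert scores.loc[up].mean() > 0
    assert scores.loc[up].mean() > scores.loc[background].mean()


def test_wca_single_dominating_gene():
    rng = np.random.default_rng(4)
    x = np.zeros((6, 5))
    x[:, 2] = rng.normal(size=6) * 10
    classes = np.repeat(["a", "b"], 3)
    res = wca(x, classes)
    scores = wca_scores(res)
    assert abs(scores.iloc[2]) == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(np.delete(scores.to_numpy(), 2), 0.0, atol=1e-9)


def test_wca_path_recovery_strict_state_ordering(default_sim, default_analysis):
    res = default_analysis.result
    coord = pd.Series(res.sample_coordinates[:, 0], index=res.sample_ids)
    design = default_sim.design
    for lineage in design.lineages:
        values = [coord[f"{lineage}_{state}"] for state in design.states]
        assert (np.diff(values) > 0).all()


def test_wca_no_lineage_effect_limit_matches_pca():
    params = SimulationParams(n_genes=1200, n_lineage_private=0, seed=19)
    counts, design, _, _ = simulate_counts(params)
    lm = gd.log_transform(gd.normalize(counts, gd.estimate_size_factors(counts)))
    universe = gd.filter_expressed(lm)
    sub = lm.loc[universe].T
    classes = design.classes_for(list(sub.index))
    res = wca(sub, classes)
    ref = pca(sub)
    cosine = res.gene_loadings[:, 0] @ ref.variable_loadings[:, 0]
    assert abs(cosine) >= 0.99


def test_wca_severity_orientation(default_sim, default_analysis):
    res = default_analysis.result
    coord = res.sample_coordinates[:, 0]
    severity = default_analysis.severity
    from scipy.stats import spearmanr

    assert spearmanr(coord, severity).statistic > 0


# ---------------------------------------------------------------------------
# subset pve


def test_subset_pve_all_genes_consistent(default_analysis):
    res = default_analysis.result
    full = subset_wca_pve(
        default_analysis.matrix,
        default_analysis.classes,
        list(default_analysis.matrix.columns),
        severity_rank=default_analysis.severity,
    )
    assert full == pytest.approx(res.pve[0], rel=1e-9)


def test_subset_pve_single_gene_is_100(default_analysis):
    gene = default_analysis.matrix.columns[0]
    assert subset_wca_pve(
        default_analysis.matrix, default_analysis.classes, [gene]
    ) == pytest.approx(100.0)


def test_subset_pve_matches_manual_slice():
    rng = np.random.default_rng(77)
    x = pd.DataFrame(rng.normal(size=(9, 12)), columns=[f"g{i}" for i in range(12)])
    classes = np.repeat(["a", "b", "c"], 3)
    subset = ["g1", "g4", "g9", "g10"]
    got = subset_wca_pve(x, classes, subset)
    manual = wca(x[subset].to_numpy(), classes)
    assert got == pytest.approx(manual.pve[0], rel=1e-12)


def test_subset_pve_empty_subset_errors(default_analysis):
    with pytest.raises(ValidationError, match="non-empty"):
        subset_wca_pve(default_analysis.matrix, default_analysis.classes, [])
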