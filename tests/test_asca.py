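"""ASCA+ correctness: coding, variance partition, balanced-design
equivalence with classical ASCA, permutation and bootstrap behavior."""

import numpy as np
import pandas as pd
import pytest

from roimcr.asca import (
    asca_fit,
    bootstrap_loadings,
    build_design_codes,
    classical_asca_percents,
    pca_explore,
    permutation_test,
)
from roimcr.synthetic import generate_design


@pytest.fixture(scope="module")
def design():
    return generate_design()


def planted_matrix(design, pct_type=30.0, pct_time=50.0, pct_inter=0.0, n_vars=12, seed=0):
    """Matrix with exactly proportioned orthogonal effect contributions.

    Effect matrices are built from sum-coded cell patterns (orthogonal on
    a balanced design), the residual is projected out of the model space,
    and each part is rescaled to the requested share of the total sum of
    squares.
    """
    rng = np.random.default_rng(seed)
    codes = build_design_codes(design)
    ids = codes["sample_ids"]
    n = len(ids)
    D_type = codes["type"].to_numpy()
    D_time = codes["time"].to_numpy()
    D_int = codes["interaction"].to_numpy()
    M_type = D_type @ rng.normal(size=(D_type.shape[1], n_vars))
    M_time = D_time @ rng.normal(size=(D_time.shape[1], n_vars))
    M_int = D_int @ rng.normal(size=(D_int.shape[1], n_vars))
    R = rng.normal(size=(n, n_vars))
    D_full = np.hstack([np.ones((n, 1)), D_type, D_time, D_int])
    R = R - D_full @ np.linalg.lstsq(D_full, R, rcond=None)[0]  # pure residual

    def scale(M, pct):
        ss = np.sum(M**2)
        return M * np.sqrt(pct / 100.0 / ss) if ss > 0 and pct > 0 else M * 0.0

    pct_res = 100.0 - pct_type - pct_time - pct_inter
    X = (
        scale(M_type, pct_type)
        + scale(M_time, pct_time)
        + scale(M_int, pct_inter)
        + scale(R, pct_res)
    )
    return pd.DataFrame(X, index=ids, columns=[f"v{j}" for j in range(n_vars)])


class TestCodes:
    def test_balanced_column_structure(self, design):
        codes = build_design_codes(design)
        assert codes["intercept"].shape[1] == 1
        assert codes["type"].shape[1] == 1
        assert codes["time"].shape[1] == 6
        assert codes["interaction"].shape[1] == 6

    def test_balanced_codes_sum_to_zero(self, design):
        codes = build_design_codes(design)
        assert codes["type"].to_numpy().sum() == pytest.approx(0.0)
        assert codes["time"].to_numpy().sum(axis=0) == pytest.approx(np.zeros(6))

    def test_unbalanced_codes_keep_structure(self, design):
        unbal = design.drop(["C1_S1"])
        codes = build_design_codes(unbal)
        assert codes["time"].shape == (41, 6)
        assert codes["type"].to_numpy().sum() != 0.0

    def test_single_level_factor_rejected(self, design):
        only_control = design.drop([s.sample_id for s in design.study_samples if s.sample_type == "treatment"])
        with pytest.raises(ValueError, match="at least 2"):
            build_design_codes(only_control)


class TestFit:
    def test_constant_matrix_has_zero_effects(self, design):
        ids = [s.sample_id for s in design.study_samples]
        X = pd.DataFrame(np.ones((len(ids), 5)), index=ids)
        res = asca_fit(X, design)
        assert all(res.effects[e]["percent"] == 0.0 for e in res.effects)

    def test_planted_percents_recovered(self, design):
        X = planted_matrix(design, 30.0, 50.0, 0.0, seed=3)
        res = asca_fit(X, design)
        assert res.effects["type"]["percent"] == pytest.approx(30.0, abs=3.0)
        assert res.effects["time"]["percent"] == pytest.approx(50.0, abs=3.0)
        assert res.effects["interaction"]["percent"] == pytest.approx(0.0, abs=3.0)
        assert res.residual_percent == pytest.approx(20.0, abs=3.0)

    def test_partition_sums_to_total_on_balanced_design(self, design):
        X = planted_matrix(design, 25.0, 40.0, 10.0, seed=4)
        res = asca_fit(X, design)
        assert res.percents().sum() == pytest.approx(100.0, abs=1e-8)

    def test_glm_equals_classical_on_balanced_design(self, design):
        X = planted_matrix(design, 20.0, 35.0, 5.0, seed=5)
        glm = asca_fit(X, design).percents()
        classical = classical_asca_percents(X, design)
        pd.testing.assert_series_equal(glm, classical, atol=1e-8, rtol=0)

    def test_unbalanced_still_decomposes(self, design):
        unbal = design.drop(["C1_S1", "T2_S5"])
        X = planted_matrix(design, 30.0, 50.0, 0.0, seed=6)
        X = X.drop(index=["C1_S1", "T2_S5"])
        res = asca_fit(X, unbal)
        assert res.effects["time"]["percent"] > res.effects["interaction"]["percent"]

    def test_scores_and_loadings_shapes(self, design):
        X = planted_matrix(design, 30.0, 50.0, 0.0, seed=7)
        res = asca_fit(X, design)
        eff = res.effects["time"]
        assert eff["loadings"].shape[0] == X.shape[1]
        assert eff["scores"].shape[0] == X.shape[0]


class TestPermutation:
    def test_strong_effect_attains_minimum_p(self, design):
        X = planted_matrix(design, 60.0, 20.0, 0.0, seed=8)
        p = permutation_test(X, design, "type", n_perm=99, seed=0)
        assert p == pytest.approx(1.0 / 100.0)

    def test_seed_determinism(self, design):
        X = planted_matrix(design, 5.0, 10.0, 0.0, seed=9)
        p1 = permutation_test(X, design, "time", n_perm=49, seed=3)
        p2 = permutation_test(X, design, "time", n_perm=49, seed=3)
        assert p1 == p2

    def test_invalid_n_perm(self, design):
        X = planted_matrix(design)
        with pytest.raises(ValueError):
            permutation_test(X, design, "type", n_perm=0)

    def test_null_p_is_not_extreme(self, design):
        X = planted_matrix(design, 0.0, 0.0, 0.0, seed=10)
        p = permutation_test(X, design, "type", n_perm=99, seed=1)
        assert p > 0.05


class TestBootstrap:
    def test_carrier_variable_significant_noise_variable_not(self, design):
        rng = np.random.default_rng(0)
        codes = build_design_codes(design)
        ids = codes["sample_ids"]
        effect = codes["type"].to_numpy()[:, 0]
        X = pd.DataFrame(
            {"carrier": 5.0 * effect + 0.1 * rng.normal(size=len(ids)), "noise": rng.normal(size=len(ids))},
            index=ids,
        )
        out = bootstrap_loadings(X, design, "type", n_boot=100, seed=0)
        assert bool(out.loc["carrier", "significant"])

    def test_zero_boot_rejected(self, design):
        X = planted_matrix(design)
        with pytest.raises(ValueError):
            bootstrap_loadings(X, design, "type", n_boot=0)

    def test_single_sample_cell_falls_back_with_warning(self, design):
        unbal = design.drop(["C1_S1", "C2_S1"])
        X = planted_matrix(design, 30.0, 50.0, 0.0, seed=11).drop(index=["C1_S1", "C2_S1"])
        with pytest.warns(UserWarning, match="whole-stratum"):
            bootstrap_loadings(X, unbal, "type", n_boot=20, seed=0)


class TestPCA:
    def test_rank_one_matrix(self):
        v = np.outer(np.arange(1.0, 7.0), np.array([1.0, 2.0, 3.0]))
        out = pca_explore(pd.DataFrame(v))
        assert out["explained_variance_ratio"][0] == pytest.approx(1.0)

    def test_two_group_shift_separates_on_pc1(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 8)) * 0.1
        X[:10] += 3.0
        out = pca_explore(pd.DataFrame(X))
        pc1 = out["scores"]["PC1"].to_numpy()
        assert (pc1[:10].mean() - pc1[10:].mean()) ** 2 > 4 * (pc1[:10].var() + pc1[10:].var())

    def test_explained_variance_bounded_and_sorted(self):
        X = np.random.default_rng(2).normal(size=(15, 6))
        ratio = pca_explore(pd.DataFrame(X))["explained_variance_ratio"]
        assert ratio.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(ratio) <= 1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pca_explore(pd.DataFrame(np.ones((1, 3))))
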