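"""MCR/ALS correctness: rank estimation, purest-variable initialization,
exact and noisy factorization recovery, areas, and component cleaning."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment, nnls as scipy_nnls

from conftest import make_bilinear_system
from roimcr import mcr
from roimcr._nnls import nnls_multiple
from roimcr.assembly import AugmentedMatrix
from roimcr.synthetic import generate_design


class TestNNLS:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_nnls(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(rng.integers(5, 25), rng.integers(2, 7)))
        B = rng.normal(size=(A.shape[0], rng.integers(1, 15)))
        X = nnls_multiple(A, B)
        assert (X >= 0).all()
        for j in range(B.shape[1]):
            ref, _ = scipy_nnls(A, B[:, j])
            obj = np.linalg.norm(A @ X[:, j] - B[:, j])
            obj_ref = np.linalg.norm(A @ ref - B[:, j])
            assert obj <= obj_ref + 1e-9


class TestRank:
    def test_exact_rank3(self, bilinear):
        aug, _, _ = bilinear
        n, s = mcr.estimate_rank(aug.data)
        assert n == 3
        assert s[3] / s[0] < 1e-10

    def test_pure_noise_suggests_at_most_one(self):
        rng = np.random.default_rng(0)
        n, _ = mcr.estimate_rank(np.abs(rng.normal(size=(100, 50))))
        assert n <= 1

    def test_rank3_plus_noise(self):
        rng = np.random.default_rng(1)
        D = rng.normal(size=(100, 3)) @ rng.normal(size=(3, 50))
        D += 0.01 * np.linalg.norm(D) / np.sqrt(D.size) * rng.normal(size=D.shape)
        n, _ = mcr.estimate_rank(D)
        assert n == 3

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mcr.estimate_rank(np.zeros((5, 5)))


def simplisma_oracle(data, n_components, alpha_frac=0.05):
    """Exhaustive purity maximization with naive determinants."""
    m, n = data.shape
    mu, sd = data.mean(axis=1), data.std(axis=1)
    alpha = alpha_frac * mu.max()
    purity = sd / (mu + alpha)
    norm = np.sqrt(mu**2 + (sd + alpha) ** 2)
    norm[norm == 0] = 1.0
    Z = data / (norm[:, None] * np.sqrt(n))
    coo = Z @ Z.T
    selected = []
    for _ in range(n_components):
        best, best_val = -1, -np.inf
        for i in range(m):
            if i in selected:
                continue
            idx = [i] + selected
            val = purity[i] * max(np.linalg.det(coo[np.ix_(idx, idx)]), 0.0)
            if val > best_val:
                best, best_val = i, val
        selected.append(best)
    return selected


class TestInitialization:
    def test_two_separated_peaks_select_apex_rows(self):
        rts = np.arange(60.0)
        S = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.0], [0.0, 0.2]])
        C = np.stack(
            [np.exp(-0.5 * ((rts - 15) / 3) ** 2), np.exp(-0.5 * ((rts - 45) / 3) ** 2)], axis=1
        )
        S0 = mcr.initialize_spectra(C @ S.T, 2)
        apex_rows = {int(np.argmax(C[:, 0])), int(np.argmax(C[:, 1]))}
        chosen = {int(np.argmin(np.sum((C @ S.T - s) ** 2, axis=1))) for s in S0}
        assert chosen == apex_rows

    def test_single_component_selects_apex(self):
        rts = np.arange(40.0)
        prof = np.exp(-0.5 * ((rts - 20) / 4) ** 2)
        D = np.outer(prof, [1.0, 0.3, 0.1])
        S0 = mcr.initialize_spectra(D, 1)
        np.testing.assert_allclose(S0[0], D[20])

    def test_overlapping_trio_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        rts = np.arange(50.0)
        C = np.stack(
            [np.exp(-0.5 * ((rts - c) / 5) ** 2) for c in (18, 25, 32)], axis=1
        )
        S = np.abs(rng.normal(size=(8, 3))) + 0.1
        D = C @ S.T
        S0 = mcr.initialize_spectra(D, 3)
        expected = simplisma_oracle(D, 3)
        np.testing.assert_allclose(S0, D[expected])

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            mcr.initialize_spectra(np.ones((4, 3)), 5)


class TestFit:
    def test_noise_free_exact_factorization(self, bilinear):
        aug, _, _ = bilinear
        model = mcr.fit(aug, 3)
        assert model.lof < 0.1
        assert model.r2 > 99.9

    def test_lof_r2_identity_and_monotone_lof(self, bilinear):
        aug, _, _ = bilinear
        model = mcr.fit(aug, 3)
        assert (model.lof / 100) ** 2 + model.r2 / 100 == pytest.approx(1.0, abs=1e-10)
        h = np.asarray(model.lof_history)
        assert np.all(np.diff(h) <= 1e-8)

    def test_parameter_recovery_at_one_percent_noise(self):
        aug, C_true, S_true = make_bilinear_system(seed=11)
        rng = np.random.default_rng(11)
        noisy = np.maximum(aug.data * (1 + 0.01 * rng.normal(size=aug.data.shape)), 0.0)
        noisy_aug = AugmentedMatrix(noisy, aug.block_index, aug.col_mz, aug.rt_axes, aug.rt_window)
        model = mcr.fit(noisy_aug, 3)
        cos = (S_true / np.linalg.norm(S_true, axis=0)).T @ (model.S / np.linalg.norm(model.S, axis=0))
        rows, cols = linear_sum_assignment(-cos)
        assert (cos[rows, cols] >= 0.99).all()
        C_hat = model.C[:, cols]
        for k in range(3):
            c = np.dot(C_true[:, k], C_hat[:, k]) / (
                np.linalg.norm(C_true[:, k]) * np.linalg.norm(C_hat[:, k])
            )
            assert c >= 0.99

    def test_non_negativity_constraints_hold(self, bilinear):
        aug, _, _ = bilinear
        model = mcr.fit(aug, 3)
        assert (model.C >= 0).all() and (model.S >= 0).all()
        assert model.S.max(axis=0) == pytest.approx(np.ones(3))

    def test_invalid_component_count(self, bilinear):
        aug, _, _ = bilinear
        with pytest.raises(ValueError):
            mcr.fit(aug, 0)


class TestAreas:
    def _design_subset(self, aug):
        # name blocks after real design samples for area bookkeeping
        design = generate_design(n_reps_per_cell=1, include_blanks=False)
        ids = list(aug.block_index)
        mapping = dict(zip(ids, [s.sample_id for s in design.samples[: len(ids)]]))
        renamed = AugmentedMatrix(
            aug.data,
            {mapping[k]: v for k, v in aug.block_index.items()},
            aug.col_mz,
            {mapping[k]: v for k, v in aug.rt_axes.items()},
            aug.rt_window,
        )
        return renamed, design

    def test_gaussian_area_closed_form(self, bilinear):
        aug, C_true, _ = bilinear
        renamed, design = self._design_subset(aug)
        model = mcr.fit(renamed, 3)
        cam = mcr.compute_areas(model, design)
        # total area per block is conserved regardless of component order
        for i, sid in enumerate(renamed.block_index):
            sl = renamed.block_index[sid]
            true_total = np.trapezoid(C_true[sl], renamed.rt_axes[sid], axis=0).sum()
            assert cam.areas.loc[sid].sum() == pytest.approx(true_total, rel=1e-2)

    def test_zero_profile_zero_area(self):
        aug, _, _ = make_bilinear_system(n_blocks=2)
        data = aug.data.copy()
        data[aug.block_index["s1"]] = 0.0  # everything absent from one block
        aug2 = AugmentedMatrix(data, aug.block_index, aug.col_mz, aug.rt_axes, aug.rt_window)
        renamed, design = self._design_subset(aug2)
        model = mcr.fit(renamed, 3)
        cam = mcr.compute_areas(model, design)
        empty = list(renamed.block_index)[1]
        assert cam.areas.loc[empty].to_numpy() == pytest.approx(np.zeros(3), abs=1e-6)

    def test_doubling_block_doubles_areas(self):
        aug, _, _ = make_bilinear_system(n_blocks=3, seed=5)
        renamed, design = self._design_subset(aug)
        model = mcr.fit(renamed, 3)
        cam = mcr.compute_areas(model, design)
        scaled = renamed.data.copy()
        first = list(renamed.block_index)[0]
        scaled[renamed.block_index[first]] *= 2.0
        aug2 = AugmentedMatrix(scaled, renamed.block_index, renamed.col_mz, renamed.rt_axes, renamed.rt_window)
        model2 = mcr.fit(aug2, 3, S0=model.S.T)
        cam2 = mcr.compute_areas(model2, design)
        assert cam2.areas.loc[first].sum() == pytest.approx(2 * cam.areas.loc[first].sum(), rel=1e-3)


class TestCleaning:
    def _build_model(self, seed=0):
        """One region, four hand-built components: a real compound, a
        blank-only contaminant, a flat drift signal, an erratic artifact."""
        rng = np.random.default_rng(seed)
        design = generate_design()
        rts = np.arange(100) * 0.4
        peak = np.exp(-0.5 * ((rts - 20) / 2.5) ** 2)
        flat = np.full_like(rts, 0.6)
        n_comp = 4
        blocks, block_index, rt_axes = [], {}, {}
        areas_true = {}
        row0 = 0
        for s in design.samples:
            C = np.zeros((rts.size, n_comp))
            is_blank = s.role == "blank"
            good = 0.0 if is_blank else 1e4 * rng.lognormal(0, 0.1)
            C[:, 0] = good * peak
            contam = 1e4 * rng.lognormal(0, 0.1)  # equally strong in blanks
            C[:, 1] = contam * peak
            C[:, 2] = 5e3 * rng.lognormal(0, 0.1) * flat
            art = 0.0
            if not is_blank and rng.random() < 0.2:
                art = 2e4 * rng.lognormal(0, 1.0)
            C[:, 3] = art * peak
            blocks.append(C)
            block_index[s.sample_id] = slice(row0, row0 + rts.size)
            rt_axes[s.sample_id] = rts
            row0 += rts.size
        C_aug = np.vstack(blocks)
        S = np.eye(n_comp)
        model = mcr.MCRModel(
            C=C_aug, S=S, col_mz=np.array([200.0, 300.0, 400.0, 500.0]),
            block_index=block_index, rt_axes=rt_axes, n_components=n_comp,
            lof=1.0, r2=99.99, region_id=0,
        )
        return model, design

    def test_rules_fire_per_component_kind(self):
        model, design = self._build_model()
        cam = mcr.compute_areas(model, design)
        retained, log = mcr.clean_components(cam, [model], design)
        rules = log.set_index("component")["rule"]
        assert rules["r00_c0"] == "retained"
        assert rules["r00_c1"] == "blank"
        assert rules["r00_c2"] in ("shape", "blank")  # drift fails both rules
        assert rules["r00_c3"] in ("prevalence", "replicate-cv")  # sporadic artifact
        assert list(retained.areas.columns) == ["r00_c0"]

    def test_blank_rule_requires_blanks(self):
        model, design = self._build_model()
        no_blanks = design.drop(design.blank_ids)
        cam = mcr.compute_areas(model, no_blanks)
        with pytest.raises(ValueError, match="no blanks"):
            mcr.clean_components(cam, [model], no_blanks)
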