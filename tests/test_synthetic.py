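"""The study generator must reproduce the mesocosm layout and provide
exactly the statistical structure downstream stages assume."""

import numpy as np
import pytest

from conftest import simple_component
from roimcr.synthetic import (
    DetectionConfig,
    EffectConfig,
    GroundTruthComponent,
    NoiseModel,
    SampleInfo,
    emit_fp_feature_table,
    generate_components,
    generate_design,
    render_sample,
    simulate_study,
)


class TestDesign:
    def test_default_layout_is_45_samples(self):
        d = generate_design()
        types = d.to_frame()["type"].value_counts()
        assert d.n_samples == 45
        assert types["control"] == 21 and types["treatment"] == 21 and types["blank"] == 3

    @pytest.mark.parametrize(
        "kwargs, expected_total",
        [
            (dict(n_reps_per_cell=1, include_blanks=False), 14),
            (dict(include_qc=True), 53),  # 45 water samples + 8 QC runs
            (dict(n_reps_per_cell=2, include_blanks=True), 31),
        ],
    )
    def test_cell_count_arithmetic(self, kwargs, expected_total):
        assert generate_design(**kwargs).n_samples == expected_total

    def test_marginals_sum_to_total_and_roundtrip(self, tmp_path):
        d = generate_design(include_qc=True)
        frame = d.to_frame()
        assert frame["role"].value_counts().sum() == d.n_samples
        d.to_csv(tmp_path / "design.csv")
        back = type(d).from_csv(tmp_path / "design.csv")
        assert back.to_frame().equals(frame)

    def test_dropping_samples_unbalances(self):
        d = generate_design()
        assert d.is_balanced()
        assert not d.drop(["C1_S1"]).is_balanced()

    def test_rep_count_precondition(self):
        with pytest.raises(ValueError):
            generate_design(n_reps_per_cell=0)


class TestComponents:
    def test_empty_request(self):
        assert generate_components(0) == []

    def test_empty_ranges_rejected(self):
        with pytest.raises(ValueError):
            generate_components(5, mz_range=(300, 300))

    def test_seed_reproducibility(self):
        a = generate_components(20, seed=7)
        b = generate_components(20, seed=7)
        assert a == b

    def test_fixed_treatment_multiplier_is_exact_before_noise(self):
        cfg = EffectConfig(treatment_fraction=1.0, treatment_multiplier_range=(4.0, 4.0), n_internal_standards=0)
        comp = generate_components(1, effect_config=cfg, seed=1)[0]
        control = SampleInfo("c", "control", "S3", 1, "study")
        treated = SampleInfo("t", "treatment", "S3", 1, "study")
        assert comp.expected_area(treated) == pytest.approx(4.0 * comp.expected_area(control))

    def test_internal_standards_are_flat(self):
        comps = generate_components(10, seed=0)
        standards = [c for c in comps if c.is_internal_standard]
        assert standards
        for c in standards:
            assert c.treatment_multiplier == 1.0
            assert set(c.temporal_profile.values()) == {1.0}

    def test_invalid_satellite_intensity_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthComponent("x", 200.0, satellites=[(1.0, 1.5)])


class TestRender:
    def test_no_components_no_noise_gives_empty_scans(self, study_sample, quiet_noise):
        scans, _ = render_sample([], study_sample, quiet_noise, seed=0)
        assert all(len(m) == 0 for m in scans.mzs)

    def test_xic_area_matches_closed_form(self, study_sample, quiet_noise):
        comp = simple_component(satellites=[])
        scans, truth = render_sample([comp], study_sample, quiet_noise, seed=0)
        xic = scans.tic()
        area = np.trapezoid(xic, scans.rts)
        assert area == pytest.approx(truth["areas"]["cpX"], rel=1e-3)

    def test_default_peak_spans_more_than_30_scans(self, study_sample, quiet_noise):
        comp = simple_component(sigma=6.0, satellites=[])
        scans, _ = render_sample([comp], study_sample, quiet_noise, scan_interval=0.4, seed=0)
        above = sum(1 for i in range(scans.n_scans) if scans.intensities[i].size and scans.intensities[i].max() >= 500)
        # Gaussian above 500 counts for 2*sigma*sqrt(2 ln(apex/500)) seconds
        apex = comp.base_area / (comp.sigma * np.sqrt(2 * np.pi))
        expected = int(2 * comp.sigma * np.sqrt(2 * np.log(apex / 500)) / 0.4)
        assert above >= 30
        assert abs(above - expected) <= 2

    def test_component_outside_run_rejected(self, study_sample):
        comp = simple_component(rt_center=2500.0)
        with pytest.raises(ValueError, match="outside run"):
            render_sample([comp], study_sample, NoiseModel.quiet(), run_length=1800.0, seed=0)

    def test_blanks_carry_only_leakage(self, quiet_noise):
        comp = simple_component(blank_presence=0.1)
        blank = SampleInfo("B1", "blank", None, 1, "blank")
        _, truth = render_sample([comp], blank, quiet_noise, seed=0)
        assert truth["areas"]["cpX"] == pytest.approx(0.1 * comp.base_area)

    def test_noise_free_rendering_is_bilinear(self, quiet_noise):
        """Stacked noise-free XIC matrices factor exactly as C * S^T."""
        comps = [
            simple_component(component_id="a", mz=300.0, rt_center=500.0, satellites=[(1.00336, 0.4)]),
            simple_component(component_id="b", mz=400.0, rt_center=520.0, satellites=[]),
        ]
        samples = [SampleInfo(f"s{i}", "control", "S1", i, "study") for i in range(3)]
        for s in samples:
            scans, truth = render_sample(comps, s, quiet_noise, seed=5)
            rts = scans.rts
            # rebuild the (scans x mass) matrix from centroids
            masses = sorted({m for c in comps for m, _ in c.masses})
            D = np.zeros((scans.n_scans, len(masses)))
            for i in range(scans.n_scans):
                for mz, inten in zip(scans.mzs[i], scans.intensities[i]):
                    D[i, masses.index(mz)] += inten
            C = np.stack(
                [
                    truth["areas"][c.component_id]
                    * np.exp(-0.5 * ((rts - c.rt_center) / c.sigma) ** 2)
                    / (c.sigma * np.sqrt(2 * np.pi))
                    for c in comps
                ],
                axis=1,
            )
            S = np.zeros((len(masses), len(comps)))
            for k, c in enumerate(comps):
                for mz, rel in c.masses:
                    S[masses.index(mz), k] = rel
            resid = D - C @ S.T
            # rendering truncates profiles beyond +-6 sigma; inside that
            # window the factorization is exact
            assert np.abs(resid).max() <= 1e-6 * D.max()

    def test_simulate_study_is_seed_deterministic(self, quiet_noise):
        d = generate_design(n_reps_per_cell=1, include_blanks=False)
        comps = generate_components(3, rt_range=(400.0, 800.0), seed=2)
        s1, t1 = simulate_study(d, comps, quiet_noise, run_length=900.0, seed=11)
        s2, t2 = simulate_study(d, comps, quiet_noise, run_length=900.0, seed=11)
        assert t1.true_areas.equals(t2.true_areas)
        sid = d.sample_ids[0]
        assert all(np.array_equal(a, b) for a, b in zip(s1[sid].mzs, s2[sid].mzs))


class TestFeatureTableSurrogate:
    def _truth(self, comps, seed=0):
        d = generate_design(n_reps_per_cell=1, include_blanks=False)
        _, truth = simulate_study(d, comps, NoiseModel.quiet(), run_length=900.0, seed=seed)
        return truth

    def test_row_count_equals_component_mass_count(self):
        comps = [
            simple_component(component_id="a", mz=300.0, satellites=[(1.00336, 0.3), (2.00672, 0.1)]),
            simple_component(component_id="b", mz=400.0, satellites=[]),
        ]
        table = emit_fp_feature_table(self._truth(comps), DetectionConfig())
        assert table.n_features == (1 + 2) + (1 + 0)

    def test_min_scan_span_drops_narrow_component(self):
        wide = simple_component(component_id="wide", mz=300.0, sigma=6.0, satellites=[])
        narrow = simple_component(component_id="narrow", mz=400.0, sigma=1.0, base_area=1.5e5, satellites=[])
        det = DetectionConfig(min_intensity=500.0, min_scan_span=30, scan_interval=0.4)
        table = emit_fp_feature_table(self._truth([wide, narrow]), det)
        ids = {i.split("_m")[0] for i in table.data.index}
        assert ids == {"wide"}

    def test_false_positive_rows_are_binomial_and_reproducible(self):
        comps = [simple_component(component_id=f"c{i}", mz=300.0 + i, satellites=[]) for i in range(10)]
        truth = self._truth(comps)
        det = DetectionConfig(false_positive_rate=0.1)
        t1 = emit_fp_feature_table(truth, det, seed=5)
        t2 = emit_fp_feature_table(truth, det, seed=5)
        assert t1.data.equals(t2.data)
        n_fp = t1.n_features - 10
        assert n_fp == np.random.default_rng(5).binomial(10, 0.1)
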