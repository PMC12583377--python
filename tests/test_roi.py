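"""ROI search correctness: oracle equivalence, the consecutive-scan rule,
and conservation/monotonicity invariants."""

import numpy as np
import pytest

from conftest import simple_component
from roimcr.ms_io import ScanSet
from roimcr.roi import (
    ROIParams,
    build_union_axis,
    extract_rois,
    extract_rois_brute,
    rois_to_frame,
)
from roimcr.synthetic import NoiseModel, SampleInfo, render_sample


def peak_scanset(n_scans_above, mz=300.0, thr=1000.0, scan_interval=0.4, sample_id="x"):
    """One Gaussian trace spending exactly n_scans_above scans >= thr."""
    sigma_scans = 10.0
    apex = thr * np.exp(0.5 * (n_scans_above / 2.0 / sigma_scans) ** 2)
    idx = np.arange(120)
    inten = apex * np.exp(-0.5 * ((idx - 60) / sigma_scans) ** 2)
    mzs = [np.array([mz]) for _ in idx]
    return ScanSet(sample_id, idx * scan_interval, mzs, [np.array([v]) for v in inten])


def random_cloud(n_scans=60, n_max=12, mz_lo=100.0, mz_hi=101.0, seed=0, sample_id="x"):
    rng = np.random.default_rng(seed)
    mzs, intens = [], []
    for _ in range(n_scans):
        k = int(rng.integers(0, n_max))
        mzs.append(np.sort(rng.uniform(mz_lo, mz_hi, k)))
        intens.append(rng.uniform(400.0, 2000.0, k))
    return ScanSet(sample_id, np.arange(n_scans) * 0.4, mzs, intens)


def assert_same_rois(a, b):
    assert len(a) == len(b)
    for ra, rb in zip(a, b):
        assert ra.mz_mean == pytest.approx(rb.mz_mean, abs=1e-12)
        np.testing.assert_array_equal(ra.scan_idx, rb.scan_idx)
        np.testing.assert_allclose(ra.trace, rb.trace)


class TestExtract:
    def test_forty_scan_peak_yields_one_roi(self):
        rois = extract_rois(peak_scanset(40), ROIParams(0.005, 1000.0, 30))
        assert len(rois) == 1
        assert rois[0].mz_mean == pytest.approx(300.0)
        assert rois[0].max_run >= 30

    def test_twenty_scan_peak_dropped_by_consecutive_rule(self):
        """The insufficient-consecutive-appearances false-negative case."""
        rois = extract_rois(peak_scanset(20), ROIParams(0.005, 1000.0, 30))
        assert rois == []

    def test_empty_scanset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_rois(ScanSet("x", [], [], []), ROIParams())

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random_clouds(self, seed):
        """Streaming search equals the O(n^2) brute-force clusterer."""
        cloud = random_cloud(seed=seed)
        params = ROIParams(mass_tolerance=0.05, intensity_threshold=500.0, min_consecutive_scans=3)
        assert_same_rois(extract_rois(cloud, params), extract_rois_brute(cloud, params))

    def test_signal_conservation(self):
        cloud = random_cloud(seed=42)
        params = ROIParams(mass_tolerance=0.02, intensity_threshold=800.0, min_consecutive_scans=5)
        retained, dropped = extract_rois(cloud, params, return_dropped=True)
        total = cloud.total_intensity()
        assigned = sum(r.total_intensity for r in retained) + sum(r.total_intensity for r in dropped)
        sub_thr = sum(
            float(inten[inten < params.intensity_threshold].sum()) for inten in cloud.intensities
        )
        assert assigned + sub_thr == pytest.approx(total, rel=1e-12)

    @pytest.mark.parametrize("stricter", ["min_consecutive_scans", "intensity_threshold"])
    def test_monotonicity(self, stricter):
        """Raising the consecutive-scan or intensity requirement never
        increases the ROI count."""
        cloud = random_cloud(n_scans=80, seed=9)
        base = dict(mass_tolerance=0.03, intensity_threshold=500.0, min_consecutive_scans=2)
        counts = []
        for value in ([2, 5, 10, 20] if stricter == "min_consecutive_scans" else [500.0, 800.0, 1200.0, 1800.0]):
            kw = dict(base)
            kw[stricter] = value
            counts.append(len(extract_rois(cloud, ROIParams(**kw))))
        assert counts == sorted(counts, reverse=True)

    def test_full_recall_with_generous_parameters(self):
        """Every planted mass yields a ROI when thresholds are open."""
        comps = [
            simple_component(component_id=f"c{i}", mz=200.0 + 50 * i, rt_center=150.0 + 80 * i, satellites=[])
            for i in range(5)
        ]
        sample = SampleInfo("s", "control", "S1", 1, "study")
        scans, _ = render_sample(comps, sample, NoiseModel.quiet(), run_length=700.0, seed=0)
        rois = extract_rois(scans, ROIParams(0.005, 1e-6, 1))
        roi_mz = np.array([r.mz_mean for r in rois])
        for c in comps:
            assert np.any(np.abs(roi_mz - c.mz) <= 0.005)

    def test_mz_window_bounded_by_tolerance(self):
        cloud = random_cloud(seed=4)
        params = ROIParams(mass_tolerance=0.05, intensity_threshold=500.0, min_consecutive_scans=2)
        for roi in extract_rois(cloud, params):
            assert roi.mz_max - roi.mz_min <= 2 * params.mass_tolerance + 1e-12

    def test_summary_frame_schema(self):
        rois = extract_rois(peak_scanset(40), ROIParams(0.005, 1000.0, 30))
        frame = rois_to_frame(rois, np.arange(120) * 0.4)
        assert {"roi_id", "mz_mean", "first_scan", "max_run", "total_intensity", "rt_first"} <= set(frame.columns)


def brute_force_single_linkage(entries, tol):
    """Naive single-linkage grouping of (mz, weight) entries by chaining."""
    order = sorted(range(len(entries)), key=lambda i: entries[i][0])
    groups, cur = [], [order[0]]
    for prev, nxt in zip(order, order[1:]):
        if entries[nxt][0] - entries[prev][0] <= tol:
            cur.append(nxt)
        else:
            groups.append(cur)
            cur = [nxt]
    groups.append(cur)
    return groups


class TestUnionAxis:
    def _roi_set(self, mz_list, sample_id="a"):
        ss = ScanSet(
            sample_id,
            np.arange(5) * 0.4,
            [np.array(sorted(mz_list))] * 5,
            [np.full(len(mz_list), 1000.0)] * 5,
        )
        return extract_rois(ss, ROIParams(0.001, 500.0, 3))

    def test_identical_lists_merge_fully(self):
        sets = {"a": self._roi_set([200.0, 300.0], "a"), "b": self._roi_set([200.0, 300.0], "b")}
        axis, mapping = build_union_axis(sets, 0.005)
        assert axis.shape == (2,)
        np.testing.assert_array_equal(mapping["a"], mapping["b"])

    @pytest.mark.parametrize("mz2, expected_cols", [(200.0060, 2), (200.0040, 1)])
    def test_threshold_arithmetic(self, mz2, expected_cols):
        sets = {"a": self._roi_set([200.0], "a"), "b": self._roi_set([mz2], "b")}
        axis, _ = build_union_axis(sets, 0.005)
        assert axis.shape == (expected_cols,)

    def test_three_sample_oracle(self):
        rng = np.random.default_rng(5)
        sets = {}
        entries = []
        for sid in ("a", "b", "c"):
            mzs = np.sort(rng.uniform(100.0, 100.5, 8))
            mzs = mzs[np.diff(np.concatenate([[0.0], mzs])) > 0.002]  # avoid within-sample merges
            sets[sid] = self._roi_set(list(mzs), sid)
            for r in sets[sid]:
                entries.append((r.mz_mean, r.total_intensity))
        axis, mapping = build_union_axis(sets, 0.005)
        groups = brute_force_single_linkage(entries, 0.005)
        assert axis.shape[0] == len(groups)
        # every ROI maps to exactly one column
        for sid in sets:
            assert (mapping[sid] >= 0).all()

    def test_column_mz_is_weighted_mean(self):
        sets = {"a": self._roi_set([200.000], "a"), "b": self._roi_set([200.004], "b")}
        wa = sum(r.total_intensity for r in sets["a"])
        wb = sum(r.total_intensity for r in sets["b"])
        axis, _ = build_union_axis(sets, 0.005)
        assert axis[0] == pytest.approx((200.000 * wa + 200.004 * wb) / (wa + wb))
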