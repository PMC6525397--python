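"""ROI searching, filtering and compression on one run."""

import numpy as np
import pytest

import roimcr as rm
from roimcr.msio import ValidationError
from roimcr.synthetic import default_spec, simulate_run

from conftest import oracle_find_rois, random_micro_run


class TestFindRois:
    def test_hand_traced_two_ion_run(self, three_scan_run, default_params):
        """Two ions above threshold in every scan give exactly two ROIs with
        constant elution columns."""
        rs = rm.find_rois(three_scan_run, default_params)
        np.testing.assert_allclose(rs.mzroi, [100.00, 200.00])
        np.testing.assert_allclose(rs.msroi[:, 0], [1000.0] * 3)
        np.testing.assert_allclose(rs.msroi[:, 1], [800.0] * 3)
        assert all(cell.n_members == 3 for cell in rs.roicell)

    def test_all_below_threshold_yields_zero_rois(self, three_scan_run):
        params = rm.ROIParams(thresh=5000.0, mzerror=0.05, minroi=1)
        rs = rm.find_rois(three_scan_run, params)
        assert rs.n_rois == 0
        assert rs.msroi.shape == (3, 0)

    def test_zero_scans_rejected(self, default_params):
        run = rm.ScanList("x", np.zeros(0), [])
        with pytest.raises(ValidationError):
            rm.find_rois(run, default_params)

    def test_minroi_filters_short_lived_clusters(self):
        """An ion present in two of four scans dies under minroi=3."""
        times = np.arange(1.0, 5.0)
        persistent = (np.array([100.0]), np.array([900.0]))
        both = (np.array([100.0, 300.0]), np.array([900.0, 900.0]))
        run = rm.ScanList("x", times, [both, both, persistent, persistent])
        rs = rm.find_rois(run, rm.ROIParams(thresh=500, mzerror=0.05, minroi=3))
        np.testing.assert_allclose(rs.mzroi, [100.0])

    def test_same_scan_duplicates_summed_in_msroi(self):
        """Two points of one ROI in one scan contribute their sum to the
        msroi cell while both stay in the provenance record."""
        times = np.arange(1.0, 4.0)
        pair = (np.array([100.00, 100.01]), np.array([600.0, 700.0]))
        run = rm.ScanList("x", times, [pair] * 3)
        rs = rm.find_rois(run, rm.ROIParams(thresh=500, mzerror=0.05, minroi=3))
        assert rs.n_rois == 1
        np.testing.assert_allclose(rs.msroi[:, 0], [1300.0] * 3)
        assert rs.roicell[0].n_members == 6

    def test_median_center_mode(self):
        times = np.arange(1.0, 4.0)
        pts = (np.array([100.00, 100.04]), np.array([600.0, 700.0]))
        run = rm.ScanList("x", times, [pts] * 3)
        rs = rm.find_rois(run, rm.ROIParams(thresh=500, mzerror=0.05,
                                            minroi=3, center="median"))
        assert rs.n_rois == 1
        assert rs.mzroi[0] == pytest.approx(np.median([100.0, 100.04] * 3))

    def test_consecutive_occurrence_mode(self):
        """Present in scans 0,2,4 only: 3 total occurrences but a longest
        consecutive run of 1."""
        times = np.arange(1.0, 6.0)
        on = (np.array([100.0]), np.array([900.0]))
        off = (np.zeros(0), np.zeros(0))
        run = rm.ScanList("x", times, [on, off, on, off, on])
        total = rm.find_rois(run, rm.ROIParams(thresh=500, mzerror=0.05,
                                               minroi=3, occurrence_mode="total"))
        consec = rm.find_rois(run, rm.ROIParams(thresh=500, mzerror=0.05,
                                                minroi=3,
                                                occurrence_mode="consecutive"))
        assert total.n_rois == 1
        assert consec.n_rois == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(60))
    def test_matches_brute_force_on_micro_runs(self, seed):
        """The scan-by-scan search agrees with an exhaustive greedy oracle
        (full center recomputation, plain lists) on random micro-runs."""
        rng = np.random.default_rng(1000 + seed)
        run, params = random_micro_run(rng)
        centers, members = oracle_find_rois(run, params)
        rs = rm.find_rois(run, params)
        np.testing.assert_allclose(rs.mzroi, centers, atol=1e-12)
        for cell, roi in zip(rs.roicell, members):
            got = sorted(zip(cell.scan.tolist(), cell.mz.tolist(),
                             cell.intensity.tolist()))
            want = sorted(roi)
            assert got == pytest.approx(want)


@pytest.fixture(scope="module")
def noisy_run():
    spec = default_spec(seed=11, baseline_rate=40.0, baseline_scale=400.0,
                        background_ions=120)
    run, _ = simulate_run(spec, "mono")
    return run


class TestTableOneMonotonicity:
    def test_roi_count_monotone_in_all_three_parameters(self, noisy_run):
        """Raising the threshold or the occurrence minimum 10x shrinks the
        ROI count; shrinking the tolerance 10x grows it."""
        def count(**kw):
            base = dict(thresh=750.0, mzerror=0.05, minroi=10)
            base.update(kw)
            return rm.find_rois(noisy_run, rm.ROIParams(**base)).n_rois

        assert count(thresh=75.0) > count(thresh=750.0) > count(thresh=7500.0)
        assert count(minroi=1) > count(minroi=10) > count(minroi=100)
        assert count(mzerror=0.005) >= count(mzerror=0.05) >= count(mzerror=0.5)
        assert count(mzerror=0.005) > count(mzerror=0.5)


class TestCompressionSoundness:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_each_suprathreshold_point_in_at_most_one_roi(self, seed):
        """No raw point is assigned twice, and every member point exceeds the
        threshold; column sums equal member-intensity sums."""
        rng = np.random.default_rng(2000 + seed)
        run, params = random_micro_run(rng)
        rs = rm.find_rois(run, params)
        seen = set()
        for j, cell in enumerate(rs.roicell):
            assert np.all(cell.intensity > params.thresh)
            for s, m, v in zip(cell.scan, cell.mz, cell.intensity):
                key = (int(s), float(m), float(v))
                assert key not in seen
                seen.add(key)
            col = rs.msroi[:, j]
            assert cell.intensity.sum() == pytest.approx(
                col[~rs.filled_mask[:, j]].sum()
            )

    def test_mzroi_accuracy_on_synthetic_truth(self):
        """With jitter sd well under the tolerance, every recovered center
        lies within mzerror of a true ion m/z."""
        spec = default_spec(seed=3, mz_jitter_sd=0.01, baseline_rate=0.0)
        run, _ = simulate_run(spec, "acc")
        params = rm.ROIParams(thresh=500.0, mzerror=0.05, minroi=5)
        rs = rm.find_rois(run, params)
        true_mz = np.array([m for c in spec.components for m, _ in c.spectrum])
        assert rs.n_rois == len(true_mz)
        for c in rs.mzroi:
            assert np.min(np.abs(true_mz - c)) <= params.mzerror


class TestFillMissing:
    def test_full_matrix_returned_unchanged(self, default_params):
        m = np.ones((4, 3))
        np.testing.assert_array_equal(rm.fill_missing(m, default_params), m)

    def test_fill_statistics_match_stated_uniform(self):
        """1000 empties at thresh 750, fraction 1%: mean near 7.5, support
        (0, 15), real cells untouched."""
        params = rm.ROIParams(thresh=750.0, mzerror=0.05, minroi=1, seed=42)
        m = np.zeros((100, 10))
        m[0, :] = 99.0
        filled = rm.fill_missing(m, params)
        vals = filled[1:, :].ravel()
        assert abs(vals.mean() - 7.5) < 0.75
        assert vals.min() > 0 and vals.max() < 15.0
        np.testing.assert_array_equal(filled[0, :], m[0, :])

    def test_same_seed_reproduces_fill(self):
        params = rm.ROIParams(thresh=750.0, mzerror=0.05, minroi=1, seed=7)
        m = np.zeros((5, 5))
        np.testing.assert_array_equal(rm.fill_missing(m, params),
                                      rm.fill_missing(m, params))


class TestRoiTrace:
    def test_trace_of_hand_built_roi(self, three_scan_run, default_params):
        rs = rm.find_rois(three_scan_run, default_params)
        profile, members = rm.roi_trace(rs, 0)
        np.testing.assert_allclose(profile, [1000.0] * 3)
        assert members.shape == (3, 3)
        np.testing.assert_allclose(members[:, 0], three_scan_run.times)

    def test_trace_preserves_disjoint_time_clusters(self):
        """A peak plus late background noise on the same m/z stays one ROI
        whose members span both time clusters."""
        times = np.arange(1.0, 11.0)
        scans = []
        for i in range(10):
            if i < 3 or i >= 7:  # early peak, late background
                scans.append((np.array([391.284]), np.array([900.0])))
            else:
                scans.append((np.zeros(0), np.zeros(0)))
        run = rm.ScanList("two-cluster", times, scans)
        rs = rm.find_rois(run, rm.ROIParams(thresh=500, mzerror=0.05, minroi=5))
        assert rs.n_rois == 1
        _, members = rm.roi_trace(rs, 0)
        rts = members[:, 0]
        assert set(rts) == {1.0, 2.0, 3.0, 8.0, 9.0, 10.0}

    def test_index_out_of_range(self, three_scan_run, default_params):
        rs = rm.find_rois(three_scan_run, default_params)
        with pytest.raises(IndexError):
            rm.roi_trace(rs, rs.n_rois)


def test_threshold_from_max(three_scan_run):
    assert rm.threshold_from_max(three_scan_run, 0.01) == pytest.approx(10.0)
    with pytest.raises(ValidationError):
        rm.threshold_from_max(three_scan_run, 1.5)
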