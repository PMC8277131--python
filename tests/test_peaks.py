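"""EIC extraction, noise estimation, peak detection, and RT alignment."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ntms.peaks import (
    EIC,
    MzWindow,
    Run,
    Scan,
    align_runs,
    detect_peaks,
    estimate_noise,
    extract_eic,
    improvement_factor,
    integrate_peak,
    sn_for_species,
)
from ntms.synth import AnalyteSpec, NoiseSpec, interference_fixture, make_run


def _run_one_scan(mz, inten, rt=1.0):
    return Run([Scan(rt=rt, mz=np.array(mz), intensity=np.array(inten))])


def _gauss_eic(apex=5e4, sigma=4, n=200, center=None, noise_sigma=0.0, seed=0):
    """Gaussian peak on a flat baseline; baseline sits at 5x the noise sigma
    so the noisy trace stays non-negative without folding the noise."""
    rng = np.random.default_rng(seed)
    x = np.arange(n, dtype=float)
    c = center if center is not None else n / 2
    y = apex * np.exp(-0.5 * ((x - c) / sigma) ** 2)
    if noise_sigma:
        y = y + rng.normal(5 * noise_sigma, noise_sigma, n)
    return EIC(MzWindow(100.0, 101.0, "unit"), x * 0.01, y)


class TestExtractEic:
    def test_unit_window_sums_all_centroids(self):
        run = _run_one_scan([123.045, 123.98], [1e5, 4e4])
        eic = extract_eic(run, MzWindow(123.0, 124.0, "unit"))
        assert eic.intensity[0] == pytest.approx(1.4e5)

    def test_accurate_window_selects_target(self):
        run = _run_one_scan([123.045, 123.98], [1e5, 4e4])
        eic = extract_eic(run, MzWindow(123.0450, 123.0460))
        assert eic.intensity[0] == pytest.approx(1e5)

    def test_narrowing_never_increases(self):
        run = _run_one_scan([123.045, 123.4, 123.98], [1e5, 2e4, 4e4])
        wide = extract_eic(run, MzWindow(123.0, 124.0, "unit")).intensity[0]
        for lo, hi in [(123.0, 123.5), (123.04, 123.05), (123.9, 123.99)]:
            assert extract_eic(run, MzWindow(lo, hi)).intensity[0] <= wide

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            MzWindow(124.0, 123.0)
        with pytest.raises(ValueError):
            MzWindow(123.0, 124.5, "unit")


class TestEstimateNoise:
    def test_constant_is_zero(self):
        eic = EIC(MzWindow(100, 101, "unit"), np.arange(20.0), np.full(20, 7.0))
        assert estimate_noise(eic) == 0.0

    def test_alternating_baseline(self):
        n = 50.0
        y = np.tile([0.0, 2 * n], 10)
        eic = EIC(MzWindow(100, 101, "unit"), np.arange(20.0), y)
        assert estimate_noise(eic) == pytest.approx(1.4826 * n)

    def test_gaussian_noise_recovery(self):
        rng = np.random.default_rng(42)
        y = rng.normal(0, 100, 500)
        eic = EIC(MzWindow(100, 101, "unit"), np.arange(500.0), y)
        assert estimate_noise(eic) == pytest.approx(100, rel=0.15)

    def test_too_few_points(self):
        eic = EIC(MzWindow(100, 101, "unit"), np.arange(5.0), np.zeros(5))
        with pytest.raises(ValueError):
            estimate_noise(eic)


class TestDetectPeaks:
    def test_gaussian_on_noise(self):
        eic = _gauss_eic(apex=5e4, noise_sigma=1e3, seed=1)
        peaks = detect_peaks(eic)
        assert len(peaks) == 1
        assert peaks[0].sn == pytest.approx(50, rel=0.4)
        assert peaks[0].apex_intensity == pytest.approx(5e4, rel=0.1)

    def test_below_min_intensity(self):
        eic = _gauss_eic(apex=2e4, noise_sigma=1e3, seed=1)
        assert detect_peaks(eic) == []

    def test_two_scan_spike_rejected(self):
        y = np.zeros(100)
        y[50] = 1e6
        y[51] = 9e5
        eic = EIC(MzWindow(100, 101, "unit"), np.arange(100) * 0.01, y)
        assert detect_peaks(eic, min_scans=3) == []

    def test_scale_invariance(self):
        eic = _gauss_eic(apex=5e4, noise_sigma=1e3, seed=3)
        scaled = EIC(eic.window, eic.rt, eic.intensity * 10)
        p1 = detect_peaks(eic, min_sn=3, min_intensity=3e4)
        p2 = detect_peaks(scaled, min_sn=3, min_intensity=3e5)
        assert len(p1) == len(p2) == 1
        assert p2[0].area == pytest.approx(10 * p1[0].area, rel=1e-9)
        assert p2[0].sn == pytest.approx(p1[0].sn, rel=1e-9)

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(9)
        x = np.arange(400, dtype=float)
        y = np.abs(rng.normal(0, 800, 400))
        for c, apex in [(60, 5e4), (150, 1.2e5), (250, 4e4), (330, 8e4)]:
            y += apex * np.exp(-0.5 * ((x - c) / 4) ** 2)
        eic = EIC(MzWindow(100, 101, "unit"), x * 0.01, y)
        base = len(detect_peaks(eic, 3, 3e4, 3))
        assert len(detect_peaks(eic, 10, 3e4, 3)) <= base
        assert len(detect_peaks(eic, 3, 1e5, 3)) <= base
        assert len(detect_peaks(eic, 3, 3e4, 10)) <= base

    def test_recall_precision_on_known_truth(self):
        """Strong peaks (apex >= 3x min intensity) are recovered cleanly."""
        rng = np.random.default_rng(17)
        analytes = [
            AnalyteSpec(
                f"C{c}H{2 * c - 2}O2",
                rt=float(rt),
                apex_intensity=float(a),
                name=f"a{i}",
            )
            for i, (c, rt, a) in enumerate(
                zip(
                    rng.integers(6, 18, 12),
                    np.linspace(0.5, 7.5, 12),
                    rng.uniform(1e5, 8e5, 12),
                )
            )
        ]
        run, truth = make_run(
            analytes, NoiseSpec(baseline_sigma=300, seed=17), rt_range=(0, 8)
        )
        hits = 0
        for _, row in truth.iterrows():
            eic = extract_eic(run, MzWindow.accurate(row["mz"], 5))
            peaks = detect_peaks(eic)
            if any(abs(p.apex_rt - row["rt"]) < 0.1 for p in peaks):
                hits += 1
        assert hits / len(truth) >= 0.95


class TestIntegrate:
    def test_rectangle(self):
        eic = EIC(MzWindow(100, 101, "unit"), np.linspace(0, 1, 11), np.full(11, 5.0))
        assert integrate_peak(eic, (0.0, 1.0)) == pytest.approx(5.0)

    def test_triangle(self):
        y = np.concatenate([np.linspace(0, 10, 6), np.linspace(10, 0, 6)[1:]])
        eic = EIC(MzWindow(100, 101, "unit"), np.linspace(0, 1, 11), y)
        assert integrate_peak(eic, (0.0, 1.0)) == pytest.approx(5.0)

    def test_linearity(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(0, 10, 20)
        eic1 = EIC(MzWindow(100, 101, "unit"), np.linspace(0, 1, 20), y)
        eic2 = EIC(MzWindow(100, 101, "unit"), np.linspace(0, 1, 20), 2 * y)
        assert integrate_peak(eic2, (0.0, 1.0)) == pytest.approx(
            2 * integrate_peak(eic1, (0.0, 1.0))
        )

    def test_inverted_bounds(self):
        eic = EIC(MzWindow(100, 101, "unit"), np.linspace(0, 1, 11), np.ones(11))
        with pytest.raises(ValueError):
            integrate_peak(eic, (0.8, 0.2))


class TestSnForSpecies:
    def test_interference_reduces_unit_mode_only(self):
        run, _, mz = interference_fixture(seed=3)
        sn_unit = sn_for_species(run, mz, "unit")
        sn_acc = sn_for_species(run, mz, "accurate")
        assert sn_acc > sn_unit

    def test_clean_run_modes_agree(self):
        analyte = AnalyteSpec("C7H8O2", rt=2.0, apex_intensity=2e5)
        run, truth = make_run(
            [analyte],
            NoiseSpec(baseline_sigma=150, background_density=0.5, seed=8),
            rt_range=(0, 4),
        )
        mz = truth.iloc[0]["mz"]
        sn_unit = sn_for_species(run, mz, "unit")
        sn_acc = sn_for_species(run, mz, "accurate")
        assert sn_acc >= sn_unit

    def test_noise_free_is_infinite(self):
        analyte = AnalyteSpec("C7H8O2", rt=2.0, apex_intensity=2e5)
        run, truth = make_run([analyte], NoiseSpec(seed=0), rt_range=(0, 4))
        assert math.isinf(sn_for_species(run, truth.iloc[0]["mz"], "accurate"))

    def test_no_signal_raises(self):
        run = _run_one_scan([200.0], [1e5])
        with pytest.raises(ValueError):
            sn_for_species(run, 500.0, "accurate")

    def test_improvement_factor_rounding(self):
        assert improvement_factor(20.8, 1.89) == 11


class TestAlignment:
    def _run_with_anchors(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        analytes = [
            AnalyteSpec(
                f"C{c}H{2 * c}O3",
                rt=float(rt + shift),
                apex_intensity=5e5,
                name=f"anchor{i}",
            )
            for i, (c, rt) in enumerate(zip(range(8, 16), np.linspace(0.8, 5.2, 8)))
        ]
        run, _ = make_run(analytes, NoiseSpec(seed=seed), rt_range=(0, 6))
        return run

    def test_self_alignment_is_identity(self):
        run = self._run_with_anchors()
        warps = align_runs([run, run])
        assert warps[1].max_correction < 1e-6

    def test_global_shift_recovery(self):
        ref = self._run_with_anchors(0.0)
        shifted = self._run_with_anchors(0.1)
        warp = align_runs([ref, shifted])[1]
        rts = np.linspace(1.0, 5.0, 20)
        corrected = warp(rts)
        assert np.median(np.abs(corrected - (rts - 0.1))) < 0.02

    def test_warp_is_monotone(self):
        ref = self._run_with_anchors(0.0)
        shifted = self._run_with_anchors(0.3, seed=2)
        warp = align_runs([ref, shifted])[1]
        rts = np.linspace(0, 6, 200)
        out = warp(rts)
        assert np.all(np.diff(out) >= -1e-9)

    def test_shift_error_reduction(self):
        """Alignment removes >= 80% of a 0.4 min global shift."""
        ref = self._run_with_anchors(0.0)
        shifted = self._run_with_anchors(0.4)
        warp = align_runs([ref, shifted])[1]
        anchor_rts = np.linspace(1.2, 5.2, 8)
        before = np.median(np.abs(anchor_rts + 0.4 - anchor_rts))
        after = np.median(np.abs(warp(anchor_rts + 0.4) - anchor_rts))
        assert after <= 0.2 * before
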