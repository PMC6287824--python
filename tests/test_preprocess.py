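import numpy as np
import pandas as pd
import pytest

from mdinet.formulas import ppm_error
from mdinet.preprocess import (CalibrationError, align_peaks,
                               apply_calibration, estimate_calibration,
                               frequency_filter)
from mdinet.simulate import (SimulationConfig, generate_cohort,
                             generate_metabolome, mass_error_ppm,
                             render_peak_lists)


def _clean_sample(seed=2, **render_kw):
    cfg = SimulationConfig(seed=seed, n_metabolites=350, n_differential=0,
                           dropout=0.0, noise_peaks_per_sample=0,
                           isotopologue_prob=0.0, sigma_ppm=0.05,
                           **render_kw)
    gt = generate_metabolome(cfg)
    cohort = generate_cohort(gt, cfg)
    return cfg, gt, cohort


def test_exact_peaks_give_null_curve():
    cfg, gt, cohort = _clean_sample()
    peaks = pd.DataFrame({"mz": gt.ion_masses, "intensity": np.ones(gt.n)})
    curve = estimate_calibration(peaks, gt.ion_masses)
    grid = np.linspace(150, 950, 40)
    assert np.abs(curve.predict(grid)).max() < 1e-3


def test_constant_offset_recovered():
    cfg, gt, cohort = _clean_sample()
    gt.calib_coeffs = np.zeros_like(gt.calib_coeffs)
    gt.calib_coeffs[0] = [0.5, 0.0]
    peaks = render_peak_lists(gt, cohort, cfg)["S000"]
    curve = estimate_calibration(peaks, gt.ion_masses)
    grid = np.linspace(gt.ion_masses.min(), gt.ion_masses.max(), 50)
    assert np.allclose(curve.predict(grid), 0.5, atol=0.05)


def test_linear_drift_recovered_within_tenth_ppm():
    cfg, gt, cohort = _clean_sample()
    gt.calib_coeffs = np.zeros_like(gt.calib_coeffs)
    gt.calib_coeffs[0] = [0.0, 1.0]      # 0 -> 1 ppm across the range
    peaks = render_peak_lists(gt, cohort, cfg)["S000"]
    curve = estimate_calibration(peaks, gt.ion_masses)
    grid = np.linspace(gt.ion_masses.min(), gt.ion_masses.max(), 60)
    truth = mass_error_ppm(np.array([0.0, 1.0]), grid)
    assert np.abs(curve.predict(grid) - truth).max() < 0.1


def test_too_few_matches_raises_or_flags():
    peaks = pd.DataFrame({"mz": [200.0, 300.0], "intensity": [1.0, 1.0]})
    with pytest.raises(CalibrationError):
        estimate_calibration(peaks, [200.0, 300.0])
    curve = estimate_calibration(peaks, [200.0], on_failure="identity")
    assert curve.flagged_identity
    assert np.all(curve.predict([500.0]) == 0.0)


def test_apply_identity_preserves_peaks():
    peaks = pd.DataFrame({"mz": [200.0, 300.0], "intensity": [5.0, 7.0]})
    curve = estimate_calibration(peaks, [999.0], on_failure="identity")
    out = apply_calibration(peaks, curve)
    pd.testing.assert_frame_equal(out, peaks)


def test_calibration_fixpoint():
    """Applying the fitted curve then re-estimating yields ~zero residual
    curve, and corrected errors shrink."""
    cfg, gt, cohort = _clean_sample()
    gt.calib_coeffs = np.zeros_like(gt.calib_coeffs)
    gt.calib_coeffs[0] = [0.4, 0.6]
    peaks = render_peak_lists(gt, cohort, cfg)["S000"]
    curve = estimate_calibration(peaks, gt.ion_masses)
    corr = apply_calibration(peaks, curve)
    residual = estimate_calibration(corr, gt.ion_masses)
    grid = np.linspace(gt.ion_masses.min(), gt.ion_masses.max(), 50)
    assert np.abs(residual.predict(grid)).max() < 0.1
    before = np.median([abs(ppm_error(o, t)) for o, t in
                        zip(np.sort(peaks.mz), np.sort(gt.ion_masses))])
    after = np.median([abs(ppm_error(o, t)) for o, t in
                       zip(np.sort(corr.mz), np.sort(gt.ion_masses))])
    assert after < before


def test_alignment_within_and_beyond_tolerance():
    a = pd.DataFrame({"mz": [200.000000], "intensity": [10.0]})
    b = pd.DataFrame({"mz": [200.000100], "intensity": [20.0]})  # 0.5 ppm
    fm = align_peaks({"s1": a, "s2": b}, tol_ppm=1.0)
    assert len(fm.feature_ids) == 1
    assert fm.frequency.iloc[0] == 1.0
    c = pd.DataFrame({"mz": [200.0000], "intensity": [1.0]})
    d = pd.DataFrame({"mz": [200.0010], "intensity": [1.0]})     # 5 ppm
    fm2 = align_peaks({"s1": c, "s2": d}, tol_ppm=1.0)
    assert len(fm2.feature_ids) == 2


def test_alignment_duplicate_peak_rule():
    """Two peaks of one sample in a cluster: the most intense survives."""
    a = pd.DataFrame({"mz": [200.000000, 200.000050], "intensity": [5.0, 50.0]})
    fm = align_peaks({"s1": a}, tol_ppm=1.0)
    assert len(fm.feature_ids) == 1
    assert fm.intensities.iloc[0, 0] == 50.0


def test_alignment_matches_ground_truth(noisy_dataset):
    cfg, gt, cohort, _ = noisy_dataset
    quiet = SimulationConfig(seed=cfg.seed, n_metabolites=cfg.n_metabolites,
                             n_differential=cfg.n_differential,
                             sigma_ppm=0.2, mass_error_scale_ppm=0.0,
                             dropout=0.0, noise_peaks_per_sample=0,
                             isotopologue_prob=0.0)
    peaks = render_peak_lists(gt, cohort, quiet)
    fm = align_peaks(peaks, tol_ppm=1.0)
    assert len(fm.feature_ids) == gt.n
    # bijection: consensus m/z within 1 ppm of each true ion mass
    consensus = fm.mz.to_numpy()
    truth = np.sort(gt.ion_masses)
    assert np.all(np.abs(consensus - truth) / truth * 1e6 < 1.0)


def test_alignment_sample_order_invariance(noisy_dataset):
    cfg, gt, cohort, peaks = noisy_dataset
    fm1 = align_peaks(peaks, tol_ppm=1.0)
    reversed_peaks = dict(reversed(list(peaks.items())))
    fm2 = align_peaks(reversed_peaks, tol_ppm=1.0)
    assert np.allclose(fm1.mz.to_numpy(), fm2.mz.to_numpy(), atol=1e-9)
    pd.testing.assert_frame_equal(fm1.intensities,
                                  fm2.intensities[fm1.intensities.columns])


def test_alignment_conserves_total_intensity(noisy_dataset):
    """Calibration and alignment keep total intensity, up to the documented
    duplicate-peak rule (duplicates are rare at these densities)."""
    cfg, gt, cohort, peaks = noisy_dataset
    fm = align_peaks(peaks, tol_ppm=1.0)
    total_in = sum(p.intensity.sum() for p in peaks.values())
    total_out = fm.intensities.to_numpy().sum()
    assert total_out <= total_in + 1e-6
    assert total_out > 0.98 * total_in


def test_empty_input_gives_empty_matrix():
    fm = align_peaks({}, tol_ppm=1.0)
    assert len(fm.feature_ids) == 0


def test_frequency_filter_threshold_arithmetic():
    """With 126 samples: present in 12 (9.5%) is dropped, 13 (10.3%) kept."""
    n = 126
    lists = {}
    for i in range(n):
        mz = [400.0]                        # anchor present everywhere
        if i < 12:
            mz.append(200.0)
        if i < 13:
            mz.append(300.0)
        lists[f"s{i}"] = pd.DataFrame({"mz": sorted(mz),
                                       "intensity": [1.0] * len(mz)})
    fm = align_peaks(lists)
    fm = frequency_filter(fm, 0.10)
    assert set(np.round(fm.mz.to_numpy())) == {300.0, 400.0}


def test_frequency_filter_limits():
    a = pd.DataFrame({"mz": [200.0, 300.0], "intensity": [1.0, 1.0]})
    b = pd.DataFrame({"mz": [200.0], "intensity": [1.0]})
    fm = align_peaks({"s1": a, "s2": b})
    ubiquitous = frequency_filter(fm, 1.0)
    assert list(ubiquitous.mz) == [200.0]
    assert len(frequency_filter(fm, 0.1).feature_ids) == 2
    with pytest.raises(ValueError):
        frequency_filter(fm, 0.0)
    with pytest.raises(ValueError):
        frequency_filter(fm, 1.5)
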