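"""Spectral preprocessing: recalibration, cross-sample alignment, filtering.

Direct-infusion ultra-high-resolution spectra carry a smooth, per-sample
systematic mass error at sub-ppm scale.  Recalibration estimates that
error curve from the 2-D density map of (m/z, ppm error) over candidate
matches between observed peaks and reference masses: the modal error per
m/z bin forms a ridge, and a robust quadratic fit to the ridge (weighted
by bin density) is the calibration curve.  Corrected peak lists are then
aligned across samples within a 1 ppm tolerance window into a feature
matrix, and features detected in fewer than 10% of samples are removed
(their intensities elsewhere stay zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formulas import ppm_error

__all__ = ["CalibrationCurve", "CalibrationError", "FeatureMatrix",
           "estimate_calibration", "apply_calibration", "align_peaks",
           "frequency_filter"]


class CalibrationError(RuntimeError):
    """Too few peak/reference matches to estimate a calibration curve."""


@dataclass
class CalibrationCurve:
    """Polynomial model of the systematic ppm error as a function of m/z."""

    coeffs: np.ndarray                 # np.polyval convention, highest power first
    n_matches: int = 0
    residual_ppm_sd: float = float("nan")
    max_abs_ppm: float = 5.0
    flagged_identity: bool = False

    def predict(self, mz) -> np.ndarray:
        e = np.polyval(self.coeffs, np.asarray(mz, dtype=float))
        return np.clip(e, -self.max_abs_ppm, self.max_abs_ppm)

    @staticmethod
    def identity(flagged: bool = False) -> "CalibrationCurve":
        return CalibrationCurve(np.zeros(1), 0, float("nan"), flagged_identity=flagged)


@dataclass
class FeatureMatrix:
    """Aligned features x samples intensity table with sample metadata.

    ``intensities`` is indexed by feature id with one column per sample;
    missing observations are exact zeros.  ``mz`` holds the consensus
    (intensity-weighted mean) m/z per feature, strictly increasing.
    """

    mz: pd.Series                      # index = feature ids
    intensities: pd.DataFrame          # features x samples
    metadata: pd.DataFrame | None = None
    flags: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def frequency(self) -> pd.Series:
        return (self.intensities > 0).mean(axis=1)

    def subset(self, keep: np.ndarray) -> "FeatureMatrix":
        """Boolean row subset preserving metadata and per-feature flags."""
        keep = np.asarray(keep)
        return FeatureMatrix(self.mz[keep], self.intensities.loc[keep],
                             self.metadata,
                             {k: v[keep] for k, v in self.flags.items()})

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"mz": self.mz, "frequency": self.frequency})
        return pd.concat([out, self.intensities], axis=1)


def match_references(mz: np.ndarray, references: np.ndarray,
                     window_ppm: float) -> tuple[np.ndarray, np.ndarray]:
    """All (peak m/z, signed ppm error vs nearest-in-window reference) pairs."""
    refs = np.sort(np.asarray(references, dtype=float))
    mz = np.asarray(mz, dtype=float)
    lo = np.searchsorted(refs, mz * (1 - window_ppm * 1e-6))
    hi = np.searchsorted(refs, mz * (1 + window_ppm * 1e-6), side="right")
    obs, err = [], []
    for m, a, b in zip(mz, lo, hi):
        for r in refs[a:b]:
            obs.append(m)
            err.append(ppm_error(m, r))
    return np.array(obs), np.array(err)


def estimate_calibration(peaks: pd.DataFrame, reference_masses: Sequence[float],
                         match_window_ppm: float = 3.0,
                         min_matches: int = 20,
                         n_mass_bins: int = 50,
                         ppm_bin_width: float = 0.05,
                         degree: int = 2,
                         max_abs_ppm: float = 5.0,
                         on_failure: str = "raise") -> CalibrationCurve:
    """Fit the most probable calibration curve from the error density map.

    Candidate matches within ``match_window_ppm`` populate a 2-D histogram
    over (m/z, ppm error); per m/z bin the modal ppm cell (refined by the
    mean error of matches inside that cell) gives one ridge point, weighted
    by its density.  A density-weighted polynomial of ``degree`` is fitted
    to the ridge, with one re-weighting pass down-weighting 3-sigma
    outliers.  On too few matches an identity curve is returned flagged
    (or CalibrationError raised, per ``on_failure``).
    """
    mz, err = match_references(peaks["mz"].to_numpy(), np.asarray(reference_masses),
                               match_window_ppm)
    if len(mz) < min_matches:
        if on_failure == "raise":
            raise CalibrationError(
                f"only {len(mz)} candidate matches (< {min_matches})")
        return CalibrationCurve.identity(flagged=True)

    mass_edges = np.linspace(mz.min(), mz.max() + 1e-9, n_mass_bins + 1)
    half_span = max(match_window_ppm, np.abs(err).max()) + ppm_bin_width
    n_ppm = int(np.ceil(2 * half_span / ppm_bin_width))
    ppm_edges = np.linspace(-half_span, half_span, n_ppm + 1)

    hist, _, _ = np.histogram2d(mz, err, bins=[mass_edges, ppm_edges])
    ridge_x, ridge_y, ridge_w = [], [], []
    mbin = np.clip(np.digitize(mz, mass_edges) - 1, 0, n_mass_bins - 1)
    pbin = np.clip(np.digitize(err, ppm_edges) - 1, 0, n_ppm - 1)
    for i in range(n_mass_bins):
        col = hist[i]
        total = col.sum()
        if total == 0:
            continue
        j = int(col.argmax())
        # refine the modal cell with its immediate neighbours so the ridge
        # is not quantised to the ppm bin width
        in_cell = (mbin == i) & (np.abs(pbin - j) <= 1)
        ridge_x.append(mz[in_cell].mean())
        ridge_y.append(err[in_cell].mean())
        ridge_w.append(col[max(j - 1, 0):j + 2].sum())
    ridge_x = np.array(ridge_x)
    ridge_y = np.array(ridge_y)
    ridge_w = np.array(ridge_w, dtype=float)

    deg = min(degree, len(ridge_x) - 1)
    coeffs = np.polyfit(ridge_x, ridge_y, deg, w=np.sqrt(ridge_w))
    resid = ridge_y - np.polyval(coeffs, ridge_x)
    sd = float(np.sqrt(np.average(resid ** 2, weights=ridge_w))) or 1e-12
    keep_w = ridge_w * (np.abs(resid) <= 3 * sd)
    if keep_w.sum() > 0 and np.count_nonzero(keep_w) > deg:
        coeffs = np.polyfit(ridge_x, ridge_y, deg, w=np.sqrt(keep_w))
        resid = ridge_y - np.polyval(coeffs, ridge_x)
        sd = float(np.sqrt(np.average(resid ** 2, weights=np.maximum(keep_w, 1e-12))))
    return CalibrationCurve(coeffs, n_matches=len(mz), residual_ppm_sd=sd,
                            max_abs_ppm=max_abs_ppm)


def apply_calibration(peaks: pd.DataFrame, curve: CalibrationCurve) -> pd.DataFrame:
    """Undo the systematic error: m_corr = m / (1 + e(m) * 1e-6)."""
    out = peaks.copy()
    out["mz"] = peaks["mz"].to_numpy() / (1.0 + curve.predict(peaks["mz"]) * 1e-6)
    return out


def align_peaks(peak_lists: Mapping[str, pd.DataFrame],
                tol_ppm: float = 1.0,
                metadata: pd.DataFrame | None = None) -> FeatureMatrix:
    """Cluster pooled peaks into cross-sample features within ``tol_ppm``.

    Single-linkage sweep over the pooled sorted m/z axis: a new feature
    starts whenever the gap to the previous peak exceeds ``tol_ppm`` of the
    current m/z.  The consensus m/z is the intensity-weighted mean; when one
    sample contributes several peaks to a cluster only its most intense peak
    is kept.
    """
    sample_ids = list(peak_lists)
    frames = []
    for i, sid in enumerate(sample_ids):
        df = peak_lists[sid]
        if len(df):
            frames.append(np.column_stack([
                df["mz"].to_numpy(dtype=float),
                df["intensity"].to_numpy(dtype=float),
                np.full(len(df), i, dtype=float)]))
    if not frames:
        return FeatureMatrix(pd.Series(dtype=float),
                             pd.DataFrame(columns=sample_ids), metadata)
    pooled = np.vstack(frames)
    order = np.lexsort((pooled[:, 2], pooled[:, 0]))
    pooled = pooled[order]
    mzs = pooled[:, 0]
    gaps = np.diff(mzs)
    new_cluster = np.concatenate([[True], gaps > tol_ppm * 1e-6 * mzs[1:]])
    cluster = np.cumsum(new_cluster) - 1
    n_clusters = cluster[-1] + 1
    n_samples = len(sample_ids)

    inten = np.zeros((n_clusters, n_samples))
    # most-intense-wins per (cluster, sample)
    np.maximum.at(inten, (cluster, pooled[:, 2].astype(int)), pooled[:, 1])
    kept = inten[cluster, pooled[:, 2].astype(int)] == pooled[:, 1]
    w = np.where(kept, pooled[:, 1], 0.0)
    num = np.bincount(cluster, weights=w * mzs, minlength=n_clusters)
    den = np.bincount(cluster, weights=w, minlength=n_clusters)
    # all-zero-intensity clusters fall back to the unweighted mean
    num0 = np.bincount(cluster, weights=mzs, minlength=n_clusters)
    cnt = np.bincount(cluster, minlength=n_clusters)
    consensus = np.where(den > 0, num / np.maximum(den, 1e-300), num0 / cnt)

    ids = pd.Index([f"F{i:05d}" for i in range(n_clusters)], name="feature_id")
    return FeatureMatrix(pd.Series(consensus, index=ids, name="mz"),
                         pd.DataFrame(inten, index=ids, columns=sample_ids),
                         metadata)


def frequency_filter(matrix: FeatureMatrix, min_frac: float = 0.10) -> FeatureMatrix:
    """Drop features detected in fewer than ``min_frac`` of the samples."""
    if not 0.0 < min_frac <= 1.0:
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    keep = (matrix.frequency >= min_frac).to_numpy()
    return matrix.subset(keep)
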