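"""Synthetic case/control direct-infusion metabolomics cohorts.

Generates a ground-truth metabolome from CHNOPS formula space, a cohort of
case and control samples with realistic demographics, and per-sample
centroided peak lists carrying the distortions a Fourier-transform
instrument produces: a smooth per-sample mass-error curve at sub-ppm
scale, random mass jitter, 13C isotopologue satellites, chemical-noise
peaks and per-sample feature dropout.

The defaults mirror a cerebrospinal-fluid case/control design: 31 cases
against 95 controls, case ages 65.5 +/- 12.2 y versus control 44.9 +/-
17.3 y, sex splits 9f/22m and 59f/36m, spectra covering m/z 123-1000.
The groups are deliberately unmatched for age and sex so that the
covariate-adjustment stage has genuine confounding to remove.

Metabolites are generated by chaining: each new formula is an existing one
plus a random building block, so every ground-truth metabolite is
connected to the rest by at least one catalogue mass difference and the
resulting mass-difference network is a single component by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formulas import (
    ATOMIC_MASSES,
    C13_SPACING,
    BuildingBlock,
    ElementalFormula,
    default_building_blocks,
    deprotonated_ion_mass,
    format_formula,
    monoisotopic_mass,
    parse_formula,
)

__all__ = ["SimulationConfig", "GroundTruth", "Cohort",
           "generate_metabolome", "generate_cohort", "render_peak_lists",
           "simulate_dataset", "write_peak_lists"]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the simulator, with study-design defaults."""

    seed: int = 0
    # cohort
    n_cases: int = 31
    n_controls: int = 95
    age_mean_case: float = 65.5
    age_sd_case: float = 12.2
    age_mean_control: float = 44.9
    age_sd_control: float = 17.3
    sex_counts_case: tuple[int, int] = (9, 22)      # (f, m)
    sex_counts_control: tuple[int, int] = (59, 36)  # (f, m)
    min_age: float = 18.0
    # metabolome
    n_metabolites: int = 500
    mass_min: float = 123.0
    mass_max: float = 1000.0
    n_differential: int = 25
    effect_size: float = 2.0          # log2 group shift, units of intensity_log_sd
    prob_up: float = 2 / 3            # fraction of differential features increased in cases
    intensity_log_mean: float = 17.0  # log2 of base intensity (~1.3e5 counts)
    intensity_log_sd: float = 1.0     # per-sample biological + technical spread (log2)
    base_log_sd: float = 1.5          # spread of per-metabolite base intensity (log2)
    # age/sex nuisance effects (log2 per decade / log2 f-vs-m) on a feature fraction
    age_effect: float = 0.0
    sex_effect: float = 0.0
    nuisance_fraction: float = 0.0
    # peak rendering
    dropout: float = 0.10
    mass_error_scale_ppm: float = 0.2   # SD of per-sample calibration-curve coefficients
    sigma_ppm: float = 0.05             # random mass jitter per peak
    noise_peaks_per_sample: int = 100
    isotopologue_prob: float = 0.5
    # enrichment planting for MDEA
    enriched_blocks: tuple[str, ...] = ("CO2",)
    enrichment_multiplier: float = 3.0

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0 or self.n_metabolites <= 0:
            raise ValueError("counts must be positive")
        if not self.mass_min < self.mass_max:
            raise ValueError("mass range must satisfy low < high")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_differential > self.n_metabolites:
            raise ValueError("n_differential cannot exceed n_metabolites")
        if sum(self.sex_counts_case) != self.n_cases:
            raise ValueError("sex counts for cases must sum to n_cases")
        if sum(self.sex_counts_control) != self.n_controls:
            raise ValueError("sex counts for controls must sum to n_controls")


@dataclass
class GroundTruth:
    """The simulated metabolome and its planted structure."""

    formulas: list[ElementalFormula]
    neutral_masses: np.ndarray          # Da, aligned with formulas
    ion_masses: np.ndarray              # [M-H]- m/z
    base_log_intensity: np.ndarray      # log2
    differential: np.ndarray            # indices into formulas
    effects: np.ndarray                 # log2 shift per differential feature (signed)
    parent_index: np.ndarray            # chain parent per metabolite (-1 for the root)
    parent_block: list[str | None]      # block label linking to parent
    calib_coeffs: np.ndarray | None = None  # (n_samples, 2): ppm offset + linear drift
    nuisance_age: np.ndarray | None = None
    nuisance_sex: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.formulas)

    def to_frame(self) -> pd.DataFrame:
        diff = np.zeros(self.n, dtype=bool)
        diff[self.differential] = True
        eff = np.zeros(self.n)
        eff[self.differential] = self.effects
        return pd.DataFrame({
            "formula": [format_formula(f) for f in self.formulas],
            "neutral_mass": self.neutral_masses,
            "ion_mass": self.ion_masses,
            "base_log2_intensity": self.base_log_intensity,
            "differential": diff,
            "effect_log2": eff,
            "parent": self.parent_index,
            "parent_block": [b or "" for b in self.parent_block],
        })


@dataclass
class Cohort:
    metadata: pd.DataFrame              # sample_id, group, age, sex
    true_log_intensity: pd.DataFrame    # metabolites x samples, log2 scale


def _plausible(f: ElementalFormula) -> bool:
    """Elemental-ratio plausibility for CHNOPS metabolites."""
    c, h, o = f["C"], f["H"], f["O"]
    if c == 0 or h == 0:
        return False
    hc = h / c
    if not 0.2 <= hc <= 3.0:
        return False
    if o / c > 1.2:
        return False
    return True


_BASE_SEEDS = ["C6H12O6", "C5H9NO4", "C9H16O4", "C10H20O2", "C6H13NO2S",
               "C8H15NO6", "C12H22O11", "C16H32O2", "C9H11NO3", "C6H15O9P"]


def generate_metabolome(cfg: SimulationConfig,
                        catalogue: Sequence[BuildingBlock] | None = None,
                        rng: np.random.Generator | None = None) -> GroundTruth:
    """Sample a connected ground-truth metabolome by block chaining.

    The first metabolite is a plausible base formula; each subsequent one is
    derived from a uniformly chosen existing metabolite by adding one
    catalogue building block (subject to mass range, elemental-ratio
    plausibility and uniqueness), so the ground-truth network is connected.
    Differential metabolites are attached preferentially through the
    configured enriched blocks so that marker-incident edges over-use them.
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    catalogue = list(catalogue) if catalogue is not None else default_building_blocks()
    enriched = [b for b in catalogue if b.label in cfg.enriched_blocks]
    w_plain = np.ones(len(catalogue))
    w_plain /= w_plain.sum()
    w_attach = np.array([
        cfg.enrichment_multiplier if b.label in cfg.enriched_blocks else 1.0
        for b in catalogue])
    w_attach /= w_attach.sum()

    # layout: a backbone of chained metabolites, then the differential
    # features attached to it (block choice tilted toward the enriched
    # blocks), then "companion" neighbours hung off each differential
    # feature through an enriched block so that marker-incident edges
    # over-use those blocks at the configured multiplier.
    n_comp_per_diff = (max(0, int(round(cfg.enrichment_multiplier)) - 1)
                       if enriched and cfg.n_differential else 0)
    n_backbone = cfg.n_metabolites - cfg.n_differential * (1 + n_comp_per_diff)
    if n_backbone < 1:
        raise ValueError(
            f"n_metabolites={cfg.n_metabolites} too small for "
            f"{cfg.n_differential} differential features with "
            f"{n_comp_per_diff} companions each")

    formulas: list[ElementalFormula] = []
    seen: set = set()
    parent_index: list[int] = []
    parent_block: list[str | None] = []
    max_tries = 2000

    def _attach(parents: list[int], block_probs: np.ndarray | None,
                blocks: Sequence[BuildingBlock] | None = None) -> bool:
        """Chain one new metabolite off a random listed parent."""
        blocks = blocks if blocks is not None else catalogue
        for _ in range(max_tries):
            j = parents[int(rng.integers(len(parents)))]
            if block_probs is None:
                b = blocks[int(rng.integers(len(blocks)))]
            else:
                b = blocks[int(rng.choice(len(blocks), p=block_probs))]
            cand = formulas[j] + b.delta_formula
            m = monoisotopic_mass(cand)
            if cand.counts in seen or not cfg.mass_min <= m <= cfg.mass_max:
                continue
            if not _plausible(cand):
                continue
            formulas.append(cand)
            seen.add(cand.counts)
            parent_index.append(j)
            parent_block.append(b.label)
            return True
        return False

    base = parse_formula(str(rng.choice(_BASE_SEEDS)))
    formulas.append(base)
    seen.add(base.counts)
    parent_index.append(-1)
    parent_block.append(None)

    for i in range(1, n_backbone):
        if not _attach(list(range(len(formulas))), w_plain):
            raise RuntimeError(
                f"could not place metabolite {i}: constraints infeasible "
                f"(n_metabolites={cfg.n_metabolites} in "
                f"[{cfg.mass_min}, {cfg.mass_max}])")

    diff_idx: list[int] = []
    backbone = list(range(n_backbone))
    for _ in range(cfg.n_differential):
        if not _attach(backbone, w_attach):
            raise RuntimeError("could not place a differential feature")
        diff_idx.append(len(formulas) - 1)
    for d in diff_idx:
        for _ in range(n_comp_per_diff):
            # companions prefer the enriched blocks; fall back to any block
            if not _attach([d], None, enriched):
                if not _attach([d], w_plain):
                    raise RuntimeError("could not place a companion feature")

    neutral = np.array([monoisotopic_mass(f) for f in formulas])
    ion = np.array([deprotonated_ion_mass(f) for f in formulas])
    base_int = rng.normal(cfg.intensity_log_mean, cfg.base_log_sd, size=len(formulas))

    differential = np.array(sorted(diff_idx), dtype=int)
    signs = np.where(rng.random(len(differential)) < cfg.prob_up, 1.0, -1.0)
    effects = signs * cfg.effect_size * cfg.intensity_log_sd

    n_samples = cfg.n_cases + cfg.n_controls
    calib = np.column_stack([
        rng.normal(0.0, cfg.mass_error_scale_ppm, size=n_samples),
        rng.normal(0.0, cfg.mass_error_scale_ppm, size=n_samples),
    ])

    nuis_age = np.zeros(len(formulas))
    nuis_sex = np.zeros(len(formulas))
    if cfg.nuisance_fraction > 0:
        k = int(round(cfg.nuisance_fraction * len(formulas)))
        pick = rng.choice(len(formulas), size=k, replace=False)
        nuis_age[pick] = cfg.age_effect
        nuis_sex[pick] = cfg.sex_effect

    return GroundTruth(formulas, neutral, ion, base_int, differential, effects,
                       np.array(parent_index), parent_block, calib,
                       nuis_age, nuis_sex)


def _truncated_ages(rng, n, mean, sd, low):
    a = (low - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n,
                               random_state=rng)


def generate_cohort(gt: GroundTruth, cfg: SimulationConfig,
                    rng: np.random.Generator | None = None) -> Cohort:
    """Draw sample metadata and true (pre-instrument) log2 intensities."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    groups = ["case"] * cfg.n_cases + ["control"] * cfg.n_controls
    ages = np.concatenate([
        _truncated_ages(rng, cfg.n_cases, cfg.age_mean_case, cfg.age_sd_case, cfg.min_age),
        _truncated_ages(rng, cfg.n_controls, cfg.age_mean_control,
                        cfg.age_sd_control, cfg.min_age),
    ])
    sexes = np.concatenate([
        rng.permutation(["f"] * cfg.sex_counts_case[0] + ["m"] * cfg.sex_counts_case[1]),
        rng.permutation(["f"] * cfg.sex_counts_control[0] + ["m"] * cfg.sex_counts_control[1]),
    ])
    ids = [f"S{i:03d}" for i in range(len(groups))]
    meta = pd.DataFrame({"sample_id": ids, "group": groups,
                         "age": np.round(ages, 1), "sex": sexes})

    is_case = np.array([g == "case" for g in groups], dtype=float)
    is_f = np.array([s == "f" for s in sexes], dtype=float)
    eff = np.zeros(gt.n)
    eff[gt.differential] = gt.effects

    # log2 intensity = base + group effect + nuisance + sample noise
    log_i = (gt.base_log_intensity[:, None]
             + eff[:, None] * is_case[None, :]
             + (gt.nuisance_age[:, None] * (ages[None, :] - 50.0) / 10.0
                if gt.nuisance_age is not None else 0.0)
             + (gt.nuisance_sex[:, None] * is_f[None, :]
                if gt.nuisance_sex is not None else 0.0)
             + rng.normal(0.0, cfg.intensity_log_sd, size=(gt.n, len(groups))))
    truth = pd.DataFrame(log_i, columns=ids)
    return Cohort(meta, truth)


def mass_error_ppm(coeffs: np.ndarray, mz, mass_min: float = 123.0,
                   mass_max: float = 1000.0):
    """Per-sample systematic error curve: offset + linear drift over the range."""
    x = (np.asarray(mz, dtype=float) - mass_min) / (mass_max - mass_min)
    return coeffs[0] + coeffs[1] * x


def render_peak_lists(gt: GroundTruth, cohort: Cohort, cfg: SimulationConfig,
                      rng: np.random.Generator | None = None) -> dict[str, pd.DataFrame]:
    """Render per-sample centroided (mz, intensity) peak lists.

    Observed m/z = ion mass distorted by the sample's systematic ppm curve
    plus zero-mean jitter of ``sigma_ppm``.  Features drop out
    independently with probability ``dropout``; surviving features spawn a
    13C isotopologue satellite with probability ``isotopologue_prob`` at
    +1.0033548 Da and intensity ~= 1.1% per carbon of the parent; uniform
    chemical-noise peaks are appended at the configured per-sample count.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    n_c = np.array([f["C"] for f in gt.formulas], dtype=float)
    out: dict[str, pd.DataFrame] = {}
    for s_idx, sid in enumerate(cohort.metadata["sample_id"]):
        coeffs = (gt.calib_coeffs[s_idx] if gt.calib_coeffs is not None
                  else np.zeros(2))
        keep = rng.random(gt.n) >= cfg.dropout
        idx = np.flatnonzero(keep)
        ion = gt.ion_masses[idx]
        err = mass_error_ppm(coeffs, ion, cfg.mass_min, cfg.mass_max)
        jitter = rng.normal(0.0, cfg.sigma_ppm, size=len(idx)) if cfg.sigma_ppm > 0 else 0.0
        mz = ion * (1.0 + err * 1e-6) + jitter * ion * 1e-6
        inten = np.exp2(cohort.true_log_intensity.iloc[idx, s_idx].to_numpy())

        rows_mz = [mz]
        rows_int = [inten]
        iso_pick = rng.random(len(idx)) < cfg.isotopologue_prob
        if iso_pick.any():
            rows_mz.append(mz[iso_pick] + C13_SPACING)
            rows_int.append(inten[iso_pick] * 0.011 * n_c[idx][iso_pick])
        if cfg.noise_peaks_per_sample > 0:
            nmz = rng.uniform(cfg.mass_min, cfg.mass_max, size=cfg.noise_peaks_per_sample)
            nint = np.exp2(rng.normal(cfg.intensity_log_mean - 3.0, 1.0,
                                      size=cfg.noise_peaks_per_sample))
            rows_mz.append(nmz)
            rows_int.append(nint)
        all_mz = np.concatenate(rows_mz)
        all_int = np.concatenate(rows_int)
        order = np.argsort(all_mz)
        out[sid] = pd.DataFrame({"mz": all_mz[order], "intensity": all_int[order]})
    return out


def simulate_dataset(cfg: SimulationConfig,
                     catalogue: Sequence[BuildingBlock] | None = None):
    """One-call convenience: metabolome + cohort + peak lists."""
    gt = generate_metabolome(cfg, catalogue)
    cohort = generate_cohort(gt, cfg)
    peaks = render_peak_lists(gt, cohort, cfg)
    return gt, cohort, peaks


def write_peak_lists(peaks: dict[str, pd.DataFrame], cohort: Cohort,
                     out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sid, df in peaks.items():
        df.to_csv(out_dir / f"{sid}.tsv", sep="\t", index=False,
                  float_format="%.8f")
    cohort.metadata.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
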