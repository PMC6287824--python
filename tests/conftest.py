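import numpy as np
import pytest

from mdinet.simulate import (SimulationConfig, generate_cohort,
                             generate_metabolome, render_peak_lists)

# 15 reference compounds with printed neutral and [M-H]- ion masses used as
# worked examples throughout the suite.
TABLE2_ROWS = [
    # (neutral mass, ion mass, molecular formula, compound)
    (129.04261, 128.03534, "C5H7NO3", "5-Oxoproline"),
    (188.01433, 187.00705, "C7H8O4S", "p-cresol sulfate"),
    (186.06411, 185.05684, "C7H10N2O4", "S-AMPA"),
    (192.06343, 191.05616, "C7H12O6", "Quinic acid"),
    (260.02032, 259.01305, "C6H12O9S", "D-Glucose-6-sulfate"),
    (163.09980, 162.09253, "C10H13NO", "N-Acetylphenyl-ethylamine"),
    (210.07402, 209.06675, "C7H14O7", "Sedoheptulose"),
    (268.07956, 267.07228, "C9H16O9", "alpha-mannosylglycerate"),
    (172.14637, 171.13910, "C10H20O2", "Decanoic acid"),
    (188.14116, 187.13389, "C10H20O3", "10-Hydroxydecanoic acid"),
    (234.16207, 233.15480, "C15H22O2", "Valerenic acid"),
    (304.24043, 303.23316, "C20H32O2", "Arachidonic acid"),
    (306.25612, 305.24885, "C20H34O2", "Dihomo-gamma-linolenic acid"),
    (622.55332, 621.54604, "C39H74O5", "DG (36:1)"),
    (747.61377, 746.60650, "C42H86NO7P", "PC/PE"),
]


@pytest.fixture(scope="session")
def small_truth():
    """A small noiseless metabolome + cohort shared across tests."""
    cfg = SimulationConfig(seed=11, n_metabolites=200, n_differential=15,
                           dropout=0.0, sigma_ppm=0.0,
                           mass_error_scale_ppm=0.0,
                           noise_peaks_per_sample=0, isotopologue_prob=0.0)
    gt = generate_metabolome(cfg)
    cohort = generate_cohort(gt, cfg)
    return cfg, gt, cohort


@pytest.fixture(scope="session")
def noisy_dataset():
    """A realistic small dataset with all distortions switched on."""
    cfg = SimulationConfig(seed=23, n_metabolites=250, n_differential=20,
                           noise_peaks_per_sample=50)
    gt = generate_metabolome(cfg)
    cohort = generate_cohort(gt, cfg)
    peaks = render_peak_lists(gt, cohort, cfg)
    return cfg, gt, cohort, peaks
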