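import itertools

import numpy as np
import pandas as pd
import pytest

from mdinet.formulas import (BuildingBlock, default_building_blocks,
                             monoisotopic_mass, neutral_from_ion,
                             packaged_name_table, parse_formula)
from mdinet.network import (FormulaAssignment, annotate_names, build_network,
                            check_assignments, propagate_formulas,
                            remove_isotopologues)
from mdinet.preprocess import FeatureMatrix, align_peaks


def _matrix(mzs, intensities):
    """features x samples FeatureMatrix from raw arrays."""
    ids = pd.Index([f"F{i}" for i in range(len(mzs))], name="feature_id")
    return FeatureMatrix(pd.Series(np.asarray(mzs, float), index=ids),
                         pd.DataFrame(np.asarray(intensities, float),
                                      index=ids,
                                      columns=[f"s{j}" for j in
                                               range(np.shape(intensities)[1])]))


class TestIsotopologueRemoval:
    def test_injected_satellites_are_flagged(self, noisy_dataset):
        cfg, gt, cohort, peaks = noisy_dataset
        fm = align_peaks(peaks, tol_ppm=1.0)
        from mdinet.preprocess import frequency_filter
        fm = frequency_filter(fm, 0.10)
        fm = remove_isotopologues(fm, tol_ppm=1.0)
        flags = fm.flags["isotopologue"]
        mz = fm.mz.to_numpy()
        truth = np.sort(gt.ion_masses)
        # true satellites sit +1.0033548 above a parent, away from any parent
        is_sat = np.array([np.min(np.abs(truth + 1.0033548 - m)) / m * 1e6 < 1.0
                           and np.min(np.abs(truth - m)) / m * 1e6 > 1.0
                           for m in mz])
        if is_sat.sum():
            assert flags[is_sat].mean() >= 0.95
        # no genuine metabolite feature is flagged
        is_parent = np.array([np.min(np.abs(truth - m)) / m * 1e6 < 0.5
                              for m in mz])
        assert flags[is_parent].mean() < 0.05

    def test_no_pair_at_spacing_nothing_flagged(self):
        fm = _matrix([200.0, 203.0], [[10.0], [1.0]])
        out = remove_isotopologues(fm)
        assert not out.flags["isotopologue"].any()

    def test_intensity_ratio_guard(self):
        # heavier peak at the 13C spacing but twice as intense: not a satellite
        fm = _matrix([200.0, 201.0033548], [[10.0], [20.0]])
        out = remove_isotopologues(fm)
        assert not out.flags["isotopologue"].any()
        fm2 = _matrix([200.0, 201.0033548], [[10.0], [1.0]])
        out2 = remove_isotopologues(fm2)
        assert list(out2.flags["isotopologue"]) == [False, True]


class TestBuildNetwork:
    CAT = default_building_blocks()

    def test_single_methylene_pair(self):
        ch2 = [b for b in self.CAT if b.label == "CH2"]
        net = build_network(["a", "b"], np.array([100.0, 114.01565]), ch2,
                           tol_ppm=1.0)
        assert net.n_edges == 1
        (u, v, k), = net.graph.edges(keys=True)
        assert k == "CH2"

    def test_difference_beyond_tolerance(self):
        ch2 = [b for b in self.CAT if b.label == "CH2"]
        net = build_network(["a", "b"], np.array([100.0, 115.0]), ch2, tol_ppm=1.0)
        assert net.n_edges == 0

    def test_empty_catalogue_rejected(self):
        with pytest.raises(ValueError):
            build_network(["a"], np.array([100.0]), [], tol_ppm=1.0)

    def test_matches_brute_force_enumeration(self):
        """Edge set identical to all-pairs x all-blocks enumeration on 200
        random masses."""
        rng = np.random.default_rng(42)
        masses = np.sort(rng.uniform(123, 1000, size=200))
        net = build_network([f"n{i}" for i in range(200)], masses, self.CAT,
                            tol_ppm=1.0)
        fast = {(u, v, k) if u < v else (v, u, k)
                for u, v, k in net.graph.edges(keys=True)}
        brute = set()
        for (i, mi), (j, mj) in itertools.combinations(enumerate(masses), 2):
            for b in self.CAT:
                if abs((mj - mi) - b.delta_mass) <= 1.0 * 1e-6 * mj:
                    e = (f"n{i}", f"n{j}", b.label)
                    brute.add(e if e[0] < e[1] else (e[1], e[0], e[2]))
        assert fast == brute


class TestPropagation:
    CAT = default_building_blocks()

    def test_single_step_methylene_chain(self):
        ch2 = [b for b in self.CAT if b.label == "CH2"]
        f = parse_formula("C10H20O2")
        masses = np.array([monoisotopic_mass(f),
                           monoisotopic_mass(f) + 14.01565006])
        net = build_network(["a", "b"], masses, ch2, tol_ppm=1.0)
        out = {x.feature_id: x for x in propagate_formulas(net, {"a": f})}
        assert out["b"].formula == parse_formula("C11H22O2")
        assert out["b"].provenance == "propagated"
        assert out["a"].provenance == "seed"

    def test_negative_counts_rejected(self):
        # walking down an NH3 edge from an N-free formula would need N = -1
        nh3 = [b for b in self.CAT if b.label == "NH3"]
        f = parse_formula("C6H12O6")
        m = monoisotopic_mass(f)
        masses = np.array([m - 17.02654910, m])
        net = build_network(["lo", "hi"], masses, nh3, tol_ppm=1.0)
        out = {x.feature_id: x for x in propagate_formulas(net, {"hi": f})}
        assert out["lo"].formula is None
        assert out["lo"].provenance == "unassigned"

    def test_inconsistent_seed_rejected(self):
        ch2 = [b for b in self.CAT if b.label == "CH2"]
        net = build_network(["a"], np.array([500.0]), ch2)
        with pytest.warns(UserWarning, match="rejected"):
            out = propagate_formulas(net, {"a": parse_formula("C10H20O2")})
        assert out[0].formula is None

    def test_degree_zero_unassigned_flagged_noise(self):
        ch2 = [b for b in self.CAT if b.label == "CH2"]
        f = parse_formula("C10H20O2")
        masses = np.array([monoisotopic_mass(f), 700.123456])
        net = build_network(["a", "iso"], masses, ch2)
        out = {x.feature_id: x for x in propagate_formulas(net, {"a": f})}
        assert out["iso"].is_noise

    def test_noiseless_simulator_recovery(self, small_truth):
        """With 5% of true formulas as seeds, >=95% of features receive
        their true formula on noiseless data."""
        cfg, gt, cohort = small_truth
        order = np.argsort(gt.neutral_masses)
        masses = gt.neutral_masses[order]
        ids = [f"F{i}" for i in range(gt.n)]
        net = build_network(ids, masses, self.CAT, tol_ppm=1.0)
        rng = np.random.default_rng(3)
        seed_pos = rng.choice(gt.n, size=max(1, gt.n // 20), replace=False)
        seeds = {ids[np.searchsorted(masses, gt.neutral_masses[k])]:
                 gt.formulas[k] for k in seed_pos}
        out = propagate_formulas(net, seeds, tol_ppm=1.0)
        truth = {ids[i]: gt.formulas[order[i]] for i in range(gt.n)}
        correct = sum(a.assigned and a.formula == truth[a.feature_id]
                      for a in out)
        assert correct / gt.n >= 0.95
        # post-pass validation finds nothing inconsistent
        chk = check_assignments(out, dict(zip(ids, masses)), net, tol_ppm=1.0)
        assert chk["n_invalid"].iloc[0] == 0

    def test_propagation_deterministic(self, small_truth):
        cfg, gt, cohort = small_truth
        order = np.argsort(gt.neutral_masses)
        masses = gt.neutral_masses[order]
        ids = [f"F{i}" for i in range(gt.n)]
        net = build_network(ids, masses, self.CAT, tol_ppm=1.0)
        seeds = {ids[0]: gt.formulas[order[0]], ids[5]: gt.formulas[order[5]]}
        r1 = propagate_formulas(net, seeds)
        r2 = propagate_formulas(net, dict(reversed(list(seeds.items()))))
        assert [(a.feature_id, a.formula) for a in r1] == \
           [(a.feature_id, a.formula) for a in r2]


def test_annotate_names_covers_reference_compounds():
    table = packaged_name_table()
    assigns = [
        FormulaAssignment("f1", parse_formula("C20H32O2"), 0.0, "seed"),
        FormulaAssignment("f2", parse_formula("C7H8O4S"), 0.0, "propagated"),
        FormulaAssignment("f3", None, float("nan"), "unassigned"),
    ]
    ann = annotate_names(assigns, table).set_index("feature_id")
    assert "Arachidonic acid" in ann.loc["f1", "names"]
    assert "p-cresol sulfate" in ann.loc["f2", "names"]
    assert ann.loc["f3", "names"] == ""
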