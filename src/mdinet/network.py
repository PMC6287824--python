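"""Mass-difference network construction and formula propagation.

An ultra-high-resolution spectrum resolves mass differences between
features to sub-ppm accuracy, so exact differences matching biochemical
building blocks (CH2, H2O, CO2, ...) identify putative reactant/product
pairs.  The resulting graph — features as nodes, matching differences as
labelled edges — lets molecular formulas propagate from a handful of seed
annotations through the whole connected metabolome: a neighbour of an
assigned node inherits the assigned formula plus/minus the edge's block.

Propagation here is a deterministic breadth-first fixpoint.  When several
candidate formulas reach a node, the one whose mass error sits closest to
the network's median error wins (spectra have a coherent intrinsic error
distribution, so the most consistent candidate is the most probable one);
remaining ties go to the smaller absolute error, then the lexicographically
smallest formula.  Isotopologue satellites and degree-zero unassigned
features are flagged and excluded from annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .formulas import (
    C13_SPACING,
    BuildingBlock,
    ElementalFormula,
    format_formula,
    monoisotopic_mass,
    neutral_from_ion,
    ppm_error,
)
from .preprocess import FeatureMatrix

__all__ = ["MassDiffNetwork", "FormulaAssignment", "remove_isotopologues",
           "build_network", "propagate_formulas", "annotate_names",
           "check_assignments"]


@dataclass
class MassDiffNetwork:
    """Graph of features connected by building-block mass differences.

    ``graph`` is an undirected networkx MultiGraph keyed by feature id;
    each edge carries the block label and the signed ppm deviation of the
    observed difference from the block's exact mass.  Node attribute
    ``mass`` is the *neutral* mass (ion m/z + proton).
    """

    graph: nx.MultiGraph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [(u, v, k, d["ppm_error"])
                for u, v, k, d in self.graph.edges(keys=True, data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "block", "ppm_error"])


@dataclass
class FormulaAssignment:
    feature_id: str
    formula: ElementalFormula | None
    error_ppm: float
    provenance: str          # seed | propagated | unassigned
    is_noise: bool = False
    is_isotopologue: bool = False

    @property
    def assigned(self) -> bool:
        return self.formula is not None


def remove_isotopologues(matrix: FeatureMatrix, tol_ppm: float = 1.0,
                         spacing: float = C13_SPACING,
                         max_iso_ratio: float = 0.6) -> FeatureMatrix:
    """Flag probable 13C satellites: +1.0033548 Da above a stronger feature.

    A feature is flagged when some feature ``spacing`` below it (within
    ``tol_ppm`` of the heavier m/z) has a median intensity (over samples
    where the lighter is detected) such that heavy/light < ``max_iso_ratio``.
    The returned matrix carries an ``isotopologue`` flag; rows are kept so
    downstream stages can exclude them explicitly.
    """
    mz = matrix.mz.to_numpy()
    inten = matrix.intensities.to_numpy()
    n = len(mz)
    flag = np.zeros(n, dtype=bool)
    target = mz - spacing
    lo = np.searchsorted(mz, target - tol_ppm * 1e-6 * mz)
    hi = np.searchsorted(mz, target + tol_ppm * 1e-6 * mz, side="right")
    for i in range(n):
        for j in range(lo[i], hi[i]):
            if j == i:
                continue
            both = inten[j] > 0
            if not both.any():
                continue
            med_light = np.median(inten[j][both])
            med_heavy = np.median(inten[i][both])
            if med_light > 0 and med_heavy / med_light < max_iso_ratio:
                flag[i] = True
                break
    out = FeatureMatrix(matrix.mz, matrix.intensities, matrix.metadata,
                        dict(matrix.flags))
    out.flags["isotopologue"] = flag
    return out


def build_network(feature_ids: Sequence[str], neutral_masses: np.ndarray,
                  catalogue: Sequence[BuildingBlock],
                  tol_ppm: float = 1.0) -> MassDiffNetwork:
    """All edges (i, j, block) with |(m_j - m_i) - delta| <= tol * m_j * 1e-6.

    Implemented as a sorted two-pointer sweep per block, O(n * |catalogue|)
    in the expected sparse case.  ``neutral_masses`` must be sorted
    ascending and aligned with ``feature_ids``.
    """
    if not catalogue:
        raise ValueError("building-block catalogue is empty")
    m = np.asarray(neutral_masses, dtype=float)
    if np.any(np.diff(m) < 0):
        raise ValueError("neutral_masses must be sorted ascending")
    g = nx.MultiGraph()
    for fid, mass in zip(feature_ids, m):
        g.add_node(fid, mass=float(mass))
    ids = list(feature_ids)
    for block in catalogue:
        delta = block.delta_mass
        target = m + delta
        tol = tol_ppm * 1e-6 * target
        lo = np.searchsorted(m, target - tol)
        hi = np.searchsorted(m, target + tol, side="right")
        for i in np.flatnonzero(hi > lo):
            for j in range(lo[i], hi[i]):
                if j == i:
                    continue
                # signed deviation of the observed difference, expressed in
                # ppm of the heavier mass (the edge-invariant scale)
                err = ((m[j] - m[i]) - delta) / m[j] * 1e6
                if abs(err) <= tol_ppm and not g.has_edge(ids[i], ids[j], key=block.label):
                    g.add_edge(ids[i], ids[j], key=block.label, ppm_error=float(err),
                               delta=block.delta_formula)
    return MassDiffNetwork(g)


def _candidate_error(mass: float, formula: ElementalFormula) -> float:
    return ppm_error(mass, monoisotopic_mass(formula))


def propagate_formulas(network: MassDiffNetwork,
                       seeds: Mapping[str, ElementalFormula],
                       tol_ppm: float = 1.0,
                       max_rounds: int = 50) -> list[FormulaAssignment]:
    """Breadth-first fixpoint propagation of formulas from seed nodes.

    Seeds whose formula mass disagrees with the node mass beyond
    ``tol_ppm`` are rejected (with a warning entry, provenance stays
    ``unassigned``).  Each round, every unassigned neighbour of an
    assigned node collects candidates (assigned formula +/- edge block,
    direction set by which node is heavier); a candidate must have
    non-negative counts and |ppm error| <= tol.  The winner is the
    candidate closest to the current median network error, ties broken by
    |error| then formula string.  Rounds repeat until no change.
    """
    g = network.graph
    mass = nx.get_node_attributes(g, "mass")
    assigned: dict[str, tuple[ElementalFormula, float, str]] = {}
    rejected_seeds: list[str] = []
    for fid, f in seeds.items():
        if fid not in mass:
            continue
        err = _candidate_error(mass[fid], f)
        if abs(err) <= tol_ppm:
            assigned[fid] = (f, err, "seed")
        else:
            rejected_seeds.append(fid)
    if rejected_seeds:
        import warnings
        warnings.warn(f"rejected {len(rejected_seeds)} seed(s) with mass "
                      f"mismatch beyond {tol_ppm} ppm: {rejected_seeds[:5]}...",
                      stacklevel=2)

    for _ in range(max_rounds):
        errors = np.array([e for _, e, _ in assigned.values()])
        median_err = float(np.median(errors)) if len(errors) else 0.0
        candidates: dict[str, list[tuple[float, float, str, ElementalFormula]]] = {}
        for fid, (f, _, _) in assigned.items():
            for _, nbr, block, data in g.edges(fid, keys=True, data=True):
                if nbr in assigned:
                    continue
                sign = 1 if mass[nbr] > mass[fid] else -1
                cand = f.shift(data["delta"], sign)
                if not cand.is_valid() or not cand:
                    continue
                err = _candidate_error(mass[nbr], cand)
                if abs(err) > tol_ppm:
                    continue
                key = (abs(err - median_err), abs(err), format_formula(cand))
                candidates.setdefault(nbr, []).append((*key, cand))
        if not candidates:
            break
        for nbr, cands in candidates.items():
            cands.sort(key=lambda t: (t[0], t[1], t[2]))
            best = cands[0]
            assigned[nbr] = (best[3], _candidate_error(mass[nbr], best[3]), "propagated")

    out: list[FormulaAssignment] = []
    for fid in g.nodes:
        if fid in assigned:
            f, err, prov = assigned[fid]
            out.append(FormulaAssignment(fid, f, err, prov))
        else:
            noise = g.degree(fid) == 0
            out.append(FormulaAssignment(fid, None, float("nan"), "unassigned",
                                         is_noise=noise))
    return out


def check_assignments(assignments: Sequence[FormulaAssignment],
                      masses: Mapping[str, float],
                      network: MassDiffNetwork | None = None,
                      tol_ppm: float = 1.0) -> pd.DataFrame:
    """Independent post-pass validation of every accepted assignment.

    Re-derives the ppm error of each assigned formula against its node
    mass, and (when the network is given) marks edges between assigned
    nodes whose formula difference does not equal the edge block as
    conflicting.  Returns a one-row summary frame.
    """
    n_assigned = 0
    n_bad = 0
    for a in assignments:
        if not a.assigned:
            continue
        n_assigned += 1
        if abs(ppm_error(masses[a.feature_id], monoisotopic_mass(a.formula))) > tol_ppm:
            n_bad += 1
    n_conflict = 0
    n_edges_checked = 0
    if network is not None:
        fmap = {a.feature_id: a.formula for a in assignments if a.assigned}
        mass = nx.get_node_attributes(network.graph, "mass")
        for u, v, block, data in network.graph.edges(keys=True, data=True):
            if u in fmap and v in fmap:
                n_edges_checked += 1
                lo, hi = (u, v) if mass[u] < mass[v] else (v, u)
                if fmap[hi] - fmap[lo] != data["delta"]:
                    n_conflict += 1
    return pd.DataFrame([{
        "n_assigned": n_assigned,
        "n_invalid": n_bad,
        "edges_between_assigned": n_edges_checked,
        "conflicting_edges": n_conflict,
        "conflicting_fraction": (n_conflict / n_edges_checked
                                 if n_edges_checked else 0.0),
    }])


def annotate_names(assignments: Sequence[FormulaAssignment],
                   lookup: Mapping[str, list[str]] | None = None) -> pd.DataFrame:
    """Attach candidate compound names from the offline lookup table."""
    if lookup is None:
        from .formulas import packaged_name_table
        lookup = packaged_name_table()
    rows = []
    for a in assignments:
        names = (lookup.get(format_formula(a.formula), []) if a.assigned else [])
        rows.append({"feature_id": a.feature_id,
                     "formula": format_formula(a.formula) if a.assigned else "",
                     "names": "; ".join(names)})
    return pd.DataFrame(rows)
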