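"""Mass-difference enrichment analysis (MDEA).

Given a mass-difference network over the full annotated metabolome and a
set of marker features, MDEA asks which building blocks (i.e. which
elementary biochemical transformations) connect the markers to the rest
of the metabolome more often than chance.  For each block the network's
edges are cross-classified into a 2x2 table — carries this block or not,
touches at least one marker node or not — and enrichment is evaluated by
the one-sided Fisher exact (hypergeometric) test.  A Z-score standardises
the marker-touching block-edge count by its hypergeometric null moments
(margins fixed), so Z ~ 2 corresponds to p ~ 0.05 and Z ~ 2.5 to p ~ 0.01
in the large-sample limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formulas import BuildingBlock
from .network import MassDiffNetwork

__all__ = ["EnrichmentRow", "mdea", "z_to_p"]


@dataclass
class EnrichmentRow:
    block: str
    a: int          # edges with this block touching >= 1 marker
    b: int          # edges with this block touching no marker
    c: int          # other-block edges touching >= 1 marker
    d: int          # remaining edges
    odds_ratio: float
    p_fisher: float # one-sided (enrichment)
    z: float


def _hypergeom_moments(N: int, K: int, n: int) -> tuple[float, float]:
    """Mean and variance of a hypergeometric count (N total, K block
    edges, n marker-touching edges)."""
    if N <= 1:
        return 0.0, 0.0
    mean = n * K / N
    var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
    return mean, var


def mdea(network: MassDiffNetwork, markers: Collection[str],
         catalogue: Sequence[BuildingBlock] | None = None,
         touch_rule: str = "any") -> pd.DataFrame:
    """Per-block enrichment of marker-touching edges; rows sorted by Z.

    ``touch_rule`` — "any": an edge touches the marker set when >= 1 of
    its endpoints is a marker (default); "one": exactly one endpoint,
    i.e. edges *linking* markers to the non-marker metabolome.
    """
    markers = set(markers)
    extra = markers - set(network.graph.nodes)
    if extra:
        raise ValueError(f"{len(extra)} marker(s) not in the network, "
                         f"e.g. {sorted(extra)[:3]}")
    if touch_rule not in ("any", "one"):
        raise ValueError("touch_rule must be 'any' or 'one'")

    edges = [(u, v, k) for u, v, k in network.graph.edges(keys=True)]
    labels = sorted({k for _, _, k in edges})
    if catalogue is not None:
        labels = sorted(set(labels) | {b.label for b in catalogue})
    touches = np.array([
        ((u in markers) != (v in markers)) if touch_rule == "one"
        else ((u in markers) or (v in markers))
        for u, v, _ in edges], dtype=bool)
    block_of = np.array([k for _, _, k in edges])
    N = len(edges)
    n_touch = int(touches.sum())

    rows = []
    for lbl in labels:
        is_block = block_of == lbl if N else np.zeros(0, dtype=bool)
        K = int(is_block.sum())
        a = int((is_block & touches).sum())
        b = K - a
        c = n_touch - a
        d = N - K - c
        mean, var = _hypergeom_moments(N, K, n_touch)
        if K == 0 or var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (a - mean) / np.sqrt(var)
            p = float(stats.hypergeom.sf(a - 1, N, K, n_touch))
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append(EnrichmentRow(lbl, a, b, c, d, odds, p, float(z)))
    out = pd.DataFrame([r.__dict__ for r in rows])
    return out.sort_values("z", ascending=False, kind="stable").reset_index(drop=True)


def z_to_p(z: float) -> float:
    """Two-sided standard-normal tail probability, 2 * (1 - Phi(|z|))."""
    return float(2.0 * stats.norm.sf(abs(z)))
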