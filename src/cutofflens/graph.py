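"""Graph-theoretical stiffness indicators on the residue contact graph.

Local connectivity is the node degree; closeness centrality is the
inverse mean unweighted shortest-path length (edge count, not Euclidean
length) from a residue to every other residue in its connected
component. Both gauge topological stiffness: how embedded a residue is
in the interaction network.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

from .enm import ContactGraph
from .patterns import IndicatorPattern

__all__ = ["connectivity", "closeness"]


def connectivity(g: ContactGraph) -> IndicatorPattern:
    """Degree c_i of every residue (number of incident contacts)."""
    return IndicatorPattern(
        indicator="conn", cutoff=g.cutoff,
        values=g.degrees().astype(float),
    )


def closeness(g: ContactGraph) -> IndicatorPattern:
    """Within-component closeness centrality.

    For node i in a component of size n_i ≥ 2,
    CC_i = (n_i − 1) / Σ_j d_ij with d_ij the unweighted shortest-path
    length to the other members of the component; isolated nodes get 0.
    Values lie in (0, 1]. Disconnected graphs are legitimate at small
    cutoffs and produce a warning listing component sizes; no
    cross-component rescaling is applied.
    """
    adj = g.adjacency().tocsr()
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"closeness on a disconnected graph at R_c={g.cutoff:g} Å: "
            f"component sizes {np.bincount(labels).tolist()}",
            stacklevel=2,
        )
    # BFS from every node (unweighted=True selects breadth-first search)
    dist = shortest_path(adj, method="auto", directed=False, unweighted=True)
    cc = np.zeros(g.n_nodes)
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        if len(members) < 2:
            continue
        d = dist[np.ix_(members, members)].sum(axis=1)
        cc[members] = (len(members) - 1) / d
    return IndicatorPattern(indicator="cc", cutoff=g.cutoff, values=cc)
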