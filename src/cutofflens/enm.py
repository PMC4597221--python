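"""Elastic network model: contact graph, mass-weighted Hessian, normal modes.

The model joins every pair of Cα particles closer than a cutoff R_c with
identical Hookean springs anchored at the crystallographic positions. All
particles carry the same mass M (average residue mass), so mass weighting
is a uniform 1/M scale. Diagonalizing the mass-weighted Hessian yields 3N
normal modes, of which six are rigid-body (zero-frequency) modes for a
connected, non-collinear structure. The spectral stiffness indicator χ_i
sums the squared components of the few highest-frequency modes at residue
i: fast modes localize on stiff, highly connected regions, so χ flags
candidate functional sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .patterns import IndicatorPattern
from .structures import CAStructure

__all__ = [
    "ENMParams",
    "ContactGraph",
    "NormalModeSet",
    "DegenerateStructureError",
    "CoincidentAtomsError",
    "build_contact_graph",
    "build_hessian",
    "compute_modes",
    "spectral_stiffness",
]


class DegenerateStructureError(ValueError):
    """Structure too small to carry an elastic network (N < 2)."""


class CoincidentAtomsError(ValueError):
    """Two residues within the cutoff sit at identical coordinates."""


@dataclass(frozen=True)
class ENMParams:
    """Spring constant k2 (kcal/mol/Å²), residue mass M (Da), and the
    number of high-frequency modes entering the stiffness indicator.

    Defaults follow the standard residue-level parametrization: k2 = 5
    kcal/mol/Å², M = 120 Da, five top modes. Eigenvalues are reported in
    k2/M units; only their ordering matters downstream, so no conversion
    to physical frequencies is performed.
    """

    k2: float = 5.0
    M: float = 120.0
    n_top_modes: int = 5
    zero_tol: float = 1e-8
    mode_weighting: str = "uniform"  # or "inverse_omega2"

    def __post_init__(self) -> None:
        if self.k2 <= 0 or self.M <= 0:
            raise ValueError("k2 and M must be positive")
        if self.n_top_modes < 1:
            raise ValueError("n_top_modes must be >= 1")
        if self.mode_weighting not in ("uniform", "inverse_omega2"):
            raise ValueError(f"unknown mode_weighting {self.mode_weighting!r}")


@dataclass
class ContactGraph:
    """Cutoff-parameterized residue contact graph.

    ``edges`` holds each unordered pair once, as (i, j) with i < j;
    ``eq_dist`` the equilibrium separations R_ij (Å) and ``unit_vectors``
    the normalized bond vectors R_ij / |R_ij|, edge-aligned.
    """

    n_nodes: int
    cutoff: float
    edges: np.ndarray  # (E, 2) int, i < j
    eq_dist: np.ndarray  # (E,)
    unit_vectors: np.ndarray  # (E, 3)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def adjacency(self) -> coo_matrix:
        """Symmetric boolean adjacency as a sparse matrix."""
        if self.n_edges == 0:
            return coo_matrix((self.n_nodes, self.n_nodes), dtype=np.int8)
        i, j = self.edges[:, 0], self.edges[:, 1]
        ones = np.ones(2 * self.n_edges, dtype=np.int8)
        return coo_matrix(
            (ones, (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_nodes, self.n_nodes),
        )

    def components(self) -> tuple[int, np.ndarray]:
        """(number of connected components, per-node labels)."""
        n, labels = connected_components(self.adjacency(), directed=False)
        return int(n), labels


@dataclass
class NormalModeSet:
    """Full spectrum of the mass-weighted Hessian.

    ``eigenvalues`` ascend (units k2/M); ``eigenvectors[:, k]`` is the
    orthonormal mode k with Cartesian layout (residue i, axis α) ↦ 3i + α.
    ``n_zero`` counts near-zero eigenvalues (|λ| below ``zero_tol`` times
    the spectral radius): 6 rigid-body modes for a connected non-collinear
    network; more when the graph is disconnected (3+3 per rigid component)
    or collinear (pairwise springs leave transverse motions floppy: a
    collinear N-chain has 2N+1 zeros).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero: int
    zero_tol: float = 1e-8

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def build_contact_graph(s: CAStructure, cutoff: float) -> ContactGraph:
    """All residue pairs with |R_i − R_j| ≤ R_c (inclusive) become edges."""
    if len(s) < 2:
        raise DegenerateStructureError(
            f"{s.structure_id}: need at least 2 residues, got {len(s)}"
        )
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = s.coords()
    pairs = cKDTree(coords).query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs):
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    vec = coords[pairs[:, 1]] - coords[pairs[:, 0]] if len(pairs) else np.empty((0, 3))
    dist = np.linalg.norm(vec, axis=1)
    if np.any(dist == 0.0):
        k = int(np.argmin(dist))
        raise CoincidentAtomsError(
            f"{s.structure_id}: residues {pairs[k, 0]} and {pairs[k, 1]} coincide"
        )
    unit = vec / dist[:, None] if len(pairs) else vec
    return ContactGraph(
        n_nodes=len(s), cutoff=float(cutoff),
        edges=pairs.astype(int), eq_dist=dist, unit_vectors=unit,
    )


def build_hessian(g: ContactGraph, params: ENMParams = ENMParams()) -> np.ndarray:
    """Assemble the dense 3N×3N mass-weighted Hessian.

    Each edge (i, j) contributes the off-diagonal 3×3 block
    −(k2/M)·(û⊗û) with û the unit bond vector; the diagonal block of i is
    minus the sum of its off-diagonal blocks, which enforces translation
    invariance (vanishing row sums per Cartesian component).
    """
    if g.n_edges == 0:
        raise ValueError("contact graph has no edges")
    if np.any(g.eq_dist == 0.0):
        raise CoincidentAtomsError("graph contains a zero-length edge")
    n = g.n_nodes
    gamma = params.k2 / params.M
    blocks = gamma * np.einsum("ea,eb->eab", g.unit_vectors, g.unit_vectors)
    h = np.zeros((3 * n, 3 * n))
    i, j = g.edges[:, 0], g.edges[:, 1]
    for e in range(g.n_edges):
        bi, bj, b = 3 * i[e], 3 * j[e], blocks[e]
        h[bi:bi + 3, bj:bj + 3] -= b
        h[bj:bj + 3, bi:bi + 3] -= b
        h[bi:bi + 3, bi:bi + 3] += b
        h[bj:bj + 3, bj:bj + 3] += b
    return h


def compute_modes(h: np.ndarray, zero_tol: float = 1e-8) -> NormalModeSet:
    """Diagonalize the Hessian: full ascending spectrum, orthonormal modes."""
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ValueError("Hessian must be square")
    if not np.allclose(h, h.T, rtol=1e-10, atol=1e-12):
        raise ValueError("Hessian must be symmetric")
    eigenvalues, eigenvectors = scipy.linalg.eigh(h)
    scale = max(abs(eigenvalues[0]), abs(eigenvalues[-1]))
    n_zero = int(np.sum(np.abs(eigenvalues) < zero_tol * scale)) if scale > 0 else len(eigenvalues)
    return NormalModeSet(eigenvalues, eigenvectors, n_zero, zero_tol)


def spectral_stiffness(
    modes: NormalModeSet,
    params: ENMParams = ENMParams(),
    structure_id: str = "",
    cutoff: float = float("nan"),
) -> IndicatorPattern:
    """Per-residue weight of the highest-frequency normal modes.

    With uniform weighting, χ_i = Σ_{k ∈ top n} Σ_α (ξ^k_{iα})², so
    orthonormality forces Σ_i χ_i = n_top_modes. The alternative
    ``inverse_omega2`` weighting scales each mode by 1/λ_k (fluctuation
    amplitude); peak locations are essentially unchanged because the
    weights are near-uniform across the narrow top band.
    """
    n_internal = modes.n_modes - modes.n_zero
    if params.n_top_modes > n_internal:
        raise ValueError(
            f"requested {params.n_top_modes} top modes but only {n_internal} "
            f"non-zero modes exist; reduce n_top_modes"
        )
    top = modes.eigenvectors[:, -params.n_top_modes:]
    sq = (top ** 2).reshape(-1, 3, params.n_top_modes).sum(axis=1)  # (N, n_top)
    if params.mode_weighting == "uniform":
        chi = sq.sum(axis=1)
    else:
        lam = modes.eigenvalues[-params.n_top_modes:]
        chi = (sq / lam[None, :]).sum(axis=1)
    return IndicatorPattern(
        indicator="chi", cutoff=float(cutoff), values=chi, structure_id=structure_id
    )


def report_connectivity(g: ContactGraph) -> tuple[bool, list[int]]:
    """(is_connected, component sizes); disconnection is reported, not fatal."""
    n, labels = g.components()
    sizes = np.bincount(labels).tolist()
    if n > 1:
        warnings.warn(
            f"contact graph at R_c={g.cutoff:g} Å has {n} components "
            f"(sizes {sizes}); indicators are computed per component",
            stacklevel=2,
        )
    return n == 1, sizes
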