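"""Deterministic toy Cα structures for exercising the full pipeline.

Four generators emulate the geometric features of real Cα traces that
the method depends on — ~3.8 Å consecutive spacing, compact packing, a
buried high-connectivity site, and a two-chain assembly — without
requiring any structure downloads:

- ``make_helix``: ideal α-helical trace (analytic geometry);
- ``make_globule``: self-avoiding chain grown inside a spherical
  envelope by rejection sampling;
- ``make_planted_hub``: a nested-shell decoy with a dense hub buried at
  its center, built so the hub's contact count at a 10 Å cutoff
  strictly exceeds every other residue's — a known "catalytic" site the
  indicators must find;
- ``make_dimer``: two globular chains (A, B) in contact, for
  cross-chain sequence-distance semantics.

All draws go through ``numpy.random.Generator(PCG64(seed))``; generation
is a pure function of (parameters, seed), and the generator algorithm
tag is recorded in emitted PDB headers so fixtures stay stable across
releases. Coordinates are rounded to 3 decimals (PDB precision) so
structures round-trip exactly through the PDB writer/reader.
"""

from __future__ import annotations

import math

import numpy as np

from .structures import AnnotationSet, CAStructure, Residue

__all__ = [
    "PackingError",
    "make_helix",
    "make_globule",
    "make_planted_hub",
    "make_dimer",
    "GENERATOR_TAG",
]

GENERATOR_TAG = "cutofflens-synth/1 rng=PCG64"

CA_SPACING = 3.8  # Å, consecutive Cα–Cα distance in real chains

# Planted-hub study conditions (defaults): a two-layer decoy of 137
# residues. An inner layer of 55 residues occupies the 6.5-11.5 Å
# spherical annulus (dense, clumpy: many competing stiff spots at small
# cutoffs), an outer shell of 80 residues occupies 18.5-20.4 Å (keeps
# degree contrast alive at the ~22 Å lensing cutoffs), and a 2-residue
# hub sits at the center: one member exactly at the origin (the
# annotated site) plus one satellite on a 1.6 Å shell. The origin sees
# the entire structure at every cutoff >= ~22 Å, while every rival
# sits off-center and misses part of it, so the hub's contact count
# dominates at 10 Å by construction (verified, with seed retries).
HUB_INNER_N = 55
HUB_OUTER_N = 80
HUB_SIZE = 2
HUB_INNER_RANGE = (6.5, 11.5)
HUB_OUTER_RANGE = (18.5, 20.4)
HUB_SHELL_RADIUS = 1.6
HUB_DOMINANCE_CUTOFF = 10.0


class PackingError(RuntimeError):
    """Chain growth or hub planting failed within the retry budget."""


def _structure(structure_id: str, coords: np.ndarray, chain_id: str = "A",
               start: int = 1) -> CAStructure:
    coords = np.round(np.asarray(coords, dtype=float), 3)
    residues = [
        Residue(chain_id, start + i, "", tuple(c)) for i, c in enumerate(coords)
    ]
    return CAStructure(structure_id=structure_id, residues=residues)


def make_helix(n: int, structure_id: str = "helix") -> CAStructure:
    """Ideal α-helix Cα trace: radius 2.3 Å, rise 1.5 Å, 100°/residue.

    This geometry gives a consecutive Cα–Cα distance of ≈3.8 Å.
    """
    if n < 2:
        raise ValueError("need at least 2 residues")
    t = np.arange(n) * math.radians(100.0)
    coords = np.stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)], axis=1)
    return _structure(structure_id, coords)


def _grow_chain(
    n: int,
    rng: np.random.Generator,
    min_spacing: float,
    center: np.ndarray,
    r_max: float,
    r_min: float = 0.0,
    max_step_tries: int = 400,
    max_restarts: int = 300,
) -> np.ndarray:
    """Self-avoiding chain with fixed bond length inside a spherical annulus.

    Consecutive residues sit exactly ``min_spacing`` apart; every
    non-consecutive pair is kept at least ``min_spacing`` apart by
    rejection. The whole chain restarts when growth gets stuck.
    """
    annulus_volume = (4 / 3) * math.pi * (r_max ** 3 - r_min ** 3)
    if n * min_spacing ** 3 / math.sqrt(2) > annulus_volume:
        raise PackingError(
            f"N={n} at spacing {min_spacing} Å cannot pack into the "
            f"[{r_min}, {r_max}] Å annulus"
        )
    for _ in range(max_restarts):
        pts = np.empty((n, 3))
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts[0] = center + d * (r_min + (r_max - r_min) * rng.random())
        ok = True
        for i in range(1, n):
            placed = False
            for _ in range(max_step_tries):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                cand = pts[i - 1] + min_spacing * d
                r = np.linalg.norm(cand - center)
                if r > r_max or r < r_min:
                    continue
                if i >= 2 and np.min(
                    np.linalg.norm(pts[: i - 1] - cand, axis=1)
                ) < min_spacing:
                    continue
                pts[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return pts
    raise PackingError(
        f"failed to grow a self-avoiding chain of N={n} in the "
        f"[{r_min}, {r_max}] Å annulus after {max_restarts} restarts"
    )


def make_globule(
    n: int,
    seed: int,
    min_spacing: float = CA_SPACING,
    envelope_radius: float = 17.0,
    structure_id: str | None = None,
) -> CAStructure:
    """Compact self-avoiding Cα chain inside a spherical envelope."""
    if n < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.Generator(np.random.PCG64(seed))
    pts = _grow_chain(n, rng, min_spacing, np.zeros(3), envelope_radius)
    return _structure(structure_id or f"globule-{seed}", pts)


def _hub_coords(hub_size: int, shell_radius: float) -> np.ndarray:
    """Hub cluster: one member at the origin, the rest on a small shell."""
    pts = [np.zeros(3)]
    golden = math.pi * (3 - math.sqrt(5))
    n_shell = hub_size - 1
    for k in range(n_shell):
        z = 1 - 2 * (k + 0.5) / max(1, n_shell)
        r = math.sqrt(max(0.0, 1 - z * z))
        phi = golden * k
        pts.append(
            shell_radius * np.array([r * math.cos(phi), r * math.sin(phi), z])
        )
    return np.asarray(pts)


def _degrees_at(coords: np.ndarray, cutoff: float) -> np.ndarray:
    """Brute-force contact counts at a cutoff (small-N helper)."""
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    adj = (d <= cutoff) & ~np.eye(len(coords), dtype=bool)
    return adj.sum(axis=1)


def make_planted_hub(
    seed: int = 0,
    n_inner: int = HUB_INNER_N,
    n_outer: int = HUB_OUTER_N,
    hub_size: int = HUB_SIZE,
    min_spacing: float = CA_SPACING,
    inner_range: tuple[float, float] = HUB_INNER_RANGE,
    outer_range: tuple[float, float] = HUB_OUTER_RANGE,
    shell_radius: float = HUB_SHELL_RADIUS,
    max_seed_tries: int = 60,
    structure_id: str | None = None,
) -> tuple[CAStructure, AnnotationSet, list[int]]:
    """Nested-shell decoy with a buried hub whose 10 Å contact count wins.

    The chain runs inner layer → hub → outer shell; the hub run is
    consecutive mid-chain, its first member at the exact center (the
    annotated "catalytic" residue). The minimum hub degree at 10 Å must
    strictly exceed the maximum non-hub degree; if a draw fails that
    check the seed is incremented and the structure re-grown (bounded).

    Returns (structure, single-site annotation, hub index list).
    """
    n = n_inner + hub_size + n_outer
    if hub_size < 1 or hub_size >= n / 4:
        raise ValueError("hub_size must be >= 1 and below N/4")
    hub = list(range(n_inner, n_inner + hub_size))
    hub_pts = _hub_coords(hub_size, shell_radius)
    last_error: Exception | None = None
    for attempt in range(max_seed_tries):
        trial = seed * 1000 + attempt
        rng = np.random.Generator(np.random.PCG64(trial))
        try:
            inner = _grow_chain(
                n_inner, rng, min_spacing, np.zeros(3),
                r_max=inner_range[1], r_min=inner_range[0],
            )
            outer = _grow_chain(
                n_outer, rng, min_spacing, np.zeros(3),
                r_max=outer_range[1], r_min=outer_range[0],
            )
        except PackingError as exc:
            last_error = exc
            continue
        pts = np.round(np.vstack([inner, hub_pts, outer]), 3)
        deg = _degrees_at(pts, HUB_DOMINANCE_CUTOFF)
        if deg[hub].min() <= np.delete(deg, hub).max():
            continue  # hub not dominant for this draw
        sid = structure_id or f"hub-{seed}"
        s = _structure(sid, pts)
        center = s.residues[hub[0]]
        ann = AnnotationSet(structure_id=sid, sites={center.key})
        return s, ann, hub
    raise PackingError(
        f"could not plant a dominant hub within {max_seed_tries} attempts "
        f"from seed {seed}"
        + (f" (last growth error: {last_error})" if last_error else "")
    )


def make_dimer(
    n_per_chain: int,
    seed: int,
    min_spacing: float = CA_SPACING,
    envelope_radius: float = 11.0,
    gap: float = 4.0,
    structure_id: str | None = None,
) -> CAStructure:
    """Two globular chains A and B with an inter-chain interface.

    Chain centers sit ``2·envelope_radius + gap`` apart along x, so the
    closest inter-chain approach is around ``gap``: inter-chain contacts
    exist at moderate cutoffs while the chains remain distinct sequences
    (cross-chain sequence distance is infinite by definition).
    """
    if n_per_chain < 2:
        raise ValueError("need at least 2 residues per chain")
    rng = np.random.Generator(np.random.PCG64(seed))
    offset = np.array([2 * envelope_radius + gap, 0.0, 0.0])
    pts_a = _grow_chain(n_per_chain, rng, min_spacing, np.zeros(3), envelope_radius)
    pts_b = _grow_chain(n_per_chain, rng, min_spacing, offset, envelope_radius)
    coords = np.round(np.vstack([pts_a, pts_b]), 3)
    residues = [
        Residue("A", i + 1, "", tuple(c)) for i, c in enumerate(coords[:n_per_chain])
    ] + [
        Residue("B", i + 1, "", tuple(c)) for i, c in enumerate(coords[n_per_chain:])
    ]
    return CAStructure(structure_id=structure_id or f"dimer-{seed}", residues=residues)
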