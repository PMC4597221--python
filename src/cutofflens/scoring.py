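"""Combined per-residue and per-structure scores.

Each indicator is computed at its own optimal cutoff (stiffness 22 Å,
connectivity 20 Å, closeness 28 Å), reduced to peaks, and renormalized
so that every peak carries mass 1/N_p. The combined score
S_i = Σ_ind w_ind · σ_i^(ind), with equal weights 1/3 by default, so
Σ_i S_i = 1 whenever all three patterns have at least one peak. For an
annotated structure the global score S_Δn adds up all S_i within Δn
residues of a catalytic site — a fraction-like confidence in [0, 1] —
and predictions for unannotated structures follow the sequential
inspection: broad connectivity regions, narrowed by closeness, refined
by stiffness, with combined-score ranking last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enm import ENMParams
from .patterns import FilterConfig, ReducedPattern, reduce_pattern
from .scan import sequence_distance
from .structures import CAStructure

__all__ = [
    "ScoreConfig",
    "ScoreProfile",
    "PredictionReport",
    "renormalize",
    "combined_score",
    "global_score",
    "predict",
]

#: Optimal cutoff per indicator (Å): the lensing optima of the scan.
DEFAULT_CUTOFFS_BY_INDICATOR: dict[str, float] = {"chi": 22.0, "conn": 20.0, "cc": 28.0}

SEQUENCE_ORDER = ("conn", "cc", "chi")  # broad → narrowed → refined


@dataclass(frozen=True)
class ScoreConfig:
    """Weights, per-indicator cutoffs, and zero-peak weight handling.

    ``redistribute=True`` (default) shares the weight of an indicator
    whose reduced pattern has no peaks equally among the indicators that
    do, keeping Σ_i S_i = 1 and S_Δn interpretable as a fraction; with
    ``redistribute=False`` weights stay fixed and total score mass drops.
    """

    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # chi, conn, cc
    cutoffs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CUTOFFS_BY_INDICATOR)
    )
    redistribute: bool = True

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or not math.isclose(w.sum(), 1.0):
            raise ValueError("weights must be 3 non-negative numbers summing to 1")

    def weight_for(self, indicator: str) -> float:
        return dict(zip(("chi", "conn", "cc"), self.weights))[indicator]


@dataclass
class ScoreProfile:
    """Combined score S_i with its renormalized components."""

    structure_id: str
    S: np.ndarray
    components: dict[str, np.ndarray]  # indicator -> σ pattern
    weights_used: dict[str, float]
    cutoffs_used: dict[str, float]
    n_peaks: dict[str, int]


def renormalize(rp: ReducedPattern) -> np.ndarray:
    """σ pattern: 1/N_p at every peak, 0 elsewhere (all-zero when no peaks)."""
    sigma = np.zeros(len(rp.filtered))
    if rp.n_peaks:
        sigma[rp.peaks] = 1.0 / rp.n_peaks
    return sigma


def combined_score(
    reduced: Mapping[str, ReducedPattern],
    cfg: ScoreConfig = ScoreConfig(),
    structure_id: str = "",
) -> ScoreProfile:
    """Weighted sum of the renormalized peak patterns of the 3 indicators."""
    if set(reduced) != {"chi", "conn", "cc"}:
        raise ValueError("need reduced patterns for chi, conn and cc")
    lengths = {len(rp.filtered) for rp in reduced.values()}
    if len(lengths) != 1:
        raise ValueError(f"pattern length mismatch: {sorted(lengths)}")
    sigmas = {ind: renormalize(rp) for ind, rp in reduced.items()}
    weights = {ind: cfg.weight_for(ind) for ind in sigmas}
    if cfg.redistribute:
        with_peaks = [ind for ind in sigmas if reduced[ind].n_peaks > 0]
        lost = sum(weights[ind] for ind in sigmas if reduced[ind].n_peaks == 0)
        if with_peaks and lost > 0:
            for ind in sigmas:
                if reduced[ind].n_peaks == 0:
                    weights[ind] = 0.0
                else:
                    weights[ind] += lost / len(with_peaks)
    S = sum(weights[ind] * sigmas[ind] for ind in sigmas)
    return ScoreProfile(
        structure_id=structure_id, S=S, components=sigmas,
        weights_used=weights,
        cutoffs_used={ind: reduced[ind].cutoff for ind in reduced},
        n_peaks={ind: reduced[ind].n_peaks for ind in reduced},
    )


def global_score(
    sp: ScoreProfile, catalytic: Iterable[int], dn: int, s: CAStructure
) -> float:
    """S_Δn: total combined score within Δn residues of a catalytic site.

    Each residue contributes once even when within Δn of several
    catalytic residues (set semantics), so 0 ≤ S_Δn ≤ Σ_i S_i ≤ 1, and
    S_Δn > 0 exactly when at least one prediction lands near a known site.
    """
    catalytic = sorted(set(catalytic))
    if not catalytic:
        raise ValueError("global_score is undefined with no catalytic residues")
    near = {
        i
        for i in range(len(sp.S))
        for c in catalytic
        if sequence_distance(i, c, s) <= dn
    }
    return float(sum(sp.S[i] for i in near))


@dataclass
class PredictionReport:
    """Sequential-inspection output for one structure.

    Stages 1–3 list the peak residues of connectivity (broad regions),
    closeness (narrowed) and stiffness (refined) at their optimal
    cutoffs; stage 4 ranks combined-score peaks by S_i (ties by index).
    """

    structure_id: str
    stages: dict[str, list[int]]  # indicator -> peak indices
    ranked: list[tuple[int, float]]  # (index, S_i), S descending
    profile: ScoreProfile
    notes: list[str]

    def to_frame(self, s: CAStructure) -> pd.DataFrame:
        chains = s.chain_ids()
        res_seq = [r.res_seq for r in s.residues]
        rows = [
            {
                "rank": k + 1, "index": i, "chain_id": chains[i],
                "res_seq": res_seq[i], "S": score,
            }
            for k, (i, score) in enumerate(self.ranked)
        ]
        return pd.DataFrame(rows, columns=["rank", "index", "chain_id", "res_seq", "S"])

    def to_text(self, s: CAStructure) -> str:
        chains = s.chain_ids()
        res_seq = [r.res_seq for r in s.residues]

        def fmt(idx: Sequence[int]) -> str:
            return ", ".join(f"{chains[i]}{res_seq[i]}" for i in idx) or "(none)"

        lines = [
            f"Sequential site inspection for {self.structure_id} "
            f"(N = {len(s)} residues)",
            f"[1] connectivity peaks @ "
            f"{self.profile.cutoffs_used['conn']:g} A (broad regions): "
            f"{fmt(self.stages['conn'])}",
            f"[2] closeness peaks    @ "
            f"{self.profile.cutoffs_used['cc']:g} A (narrowed):       "
            f"{fmt(self.stages['cc'])}",
            f"[3] stiffness peaks    @ "
            f"{self.profile.cutoffs_used['chi']:g} A (refined):       "
            f"{fmt(self.stages['chi'])}",
            "[4] combined score ranking:",
        ]
        for k, (i, score) in enumerate(self.ranked):
            lines.append(f"    {k + 1:2d}. {chains[i]}{res_seq[i]:<6d} S = {score:.4f}")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines) + "\n"


def predict(
    s: CAStructure,
    params: ENMParams = ENMParams(),
    filter_cfg: FilterConfig = FilterConfig(),
    score_cfg: ScoreConfig = ScoreConfig(),
) -> PredictionReport:
    """Full entry point for an unannotated structure.

    Computes each indicator at its optimal cutoff, reduces to peaks,
    combines into S_i, and emits the 4-stage sequential report.
    Deterministic: identical input yields byte-identical reports.
    """
    from .enm import build_contact_graph, build_hessian, compute_modes, spectral_stiffness
    from .graph import closeness, connectivity

    reduced: dict[str, ReducedPattern] = {}
    for ind in ("chi", "conn", "cc"):
        cutoff = score_cfg.cutoffs[ind]
        g = build_contact_graph(s, cutoff)
        if ind == "chi":
            modes = compute_modes(build_hessian(g, params), params.zero_tol)
            pattern = spectral_stiffness(
                modes, params, structure_id=s.structure_id, cutoff=cutoff
            )
        elif ind == "conn":
            pattern = connectivity(g)
        else:
            pattern = closeness(g)
        pattern.structure_id = s.structure_id
        reduced[ind] = reduce_pattern(pattern, filter_cfg)
    profile = combined_score(reduced, score_cfg, structure_id=s.structure_id)
    notes = []
    for ind in ("chi", "conn", "cc"):
        if reduced[ind].n_peaks == 0:
            what = (
                "weight redistributed over remaining indicators"
                if score_cfg.redistribute
                else "weight retained (no redistribution)"
            )
            notes.append(f"indicator {ind!r} has no surviving peaks; {what}")
    order = np.lexsort((np.arange(len(profile.S)), -profile.S))
    ranked = [(int(i), float(profile.S[i])) for i in order if profile.S[i] > 0]
    return PredictionReport(
        structure_id=s.structure_id,
        stages={ind: list(reduced[ind].peaks) for ind in SEQUENCE_ORDER},
        ranked=ranked,
        profile=profile,
        notes=notes,
    )
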