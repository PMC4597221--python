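"""Run configuration: validated parameters for every pipeline stage.

Configuration files are flat TOML key–value tables (dotted keys);
command-line flags override file values. Every output file written by
the CLI carries the hash of the fully resolved configuration so runs
are traceable and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

from .enm import ENMParams
from .patterns import FilterConfig
from .scan import DEFAULT_CUTOFFS, DEFAULT_DN
from .scoring import DEFAULT_CUTOFFS_BY_INDICATOR, ScoreConfig

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Malformed or unknown configuration keys."""


_KNOWN_KEYS = {
    "enm.k2", "enm.M", "enm.n_top_modes", "enm.zero_tol", "enm.mode_weighting",
    "filter.chi_nsigma", "filter.conn_nsigma", "filter.cc_nsigma",
    "smoothing.cc",
    "score.weights", "score.cutoffs", "score.redistribute",
    "scan.cutoffs", "scan.dn",
    "eval.size_classes",
    "out_dir", "seed",
}


@dataclass
class RunConfig:
    """Resolved configuration for one invocation."""

    enm: ENMParams = field(default_factory=ENMParams)
    filters: FilterConfig = field(default_factory=FilterConfig)
    score: ScoreConfig = field(default_factory=ScoreConfig)
    scan_cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    dn: tuple[int, ...] = DEFAULT_DN
    size_classes: tuple[int, ...] | None = None
    out_dir: str = "."
    seed: int = 0

    def hash(self) -> str:
        """Short stable hash of the resolved configuration."""
        blob = json.dumps(
            {
                "enm": asdict(self.enm),
                "filters": asdict(self.filters),
                "score": {
                    "weights": list(self.score.weights),
                    "cutoffs": dict(self.score.cutoffs),
                    "redistribute": self.score.redistribute,
                },
                "scan_cutoffs": list(self.scan_cutoffs),
                "dn": list(self.dn),
                "size_classes": list(self.size_classes) if self.size_classes else None,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _flatten(d: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict) and key not in ("score.cutoffs",):
            out.update(_flatten(v, f"{key}."))
        else:
            out[key] = v
    return out


def load_config(
    path: str | Path | None = None, overrides: Mapping[str, Any] | None = None
) -> RunConfig:
    """Build a RunConfig from an optional TOML file plus overrides.

    Unknown keys are rejected; overrides (typically CLI flags) take
    precedence over file values.
    """
    flat: dict[str, Any] = {}
    if path is not None:
        with open(path, "rb") as fh:
            flat.update(_flatten(tomllib.load(fh)))
    if overrides:
        flat.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(flat) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")

    try:
        enm = ENMParams(
            k2=float(flat.get("enm.k2", 5.0)),
            M=float(flat.get("enm.M", 120.0)),
            n_top_modes=int(flat.get("enm.n_top_modes", 5)),
            zero_tol=float(flat.get("enm.zero_tol", 1e-8)),
            mode_weighting=str(flat.get("enm.mode_weighting", "uniform")),
        )
        filters = FilterConfig(
            chi_nsigma=float(flat.get("filter.chi_nsigma", 1.0)),
            conn_nsigma=float(flat.get("filter.conn_nsigma", 1.0)),
            cc_nsigma=float(flat.get("filter.cc_nsigma", 0.5)),
            smooth_cc=bool(flat.get("smoothing.cc", True)),
        )
        score_cutoffs = dict(DEFAULT_CUTOFFS_BY_INDICATOR)
        score_cutoffs.update(
            {k: float(v) for k, v in dict(flat.get("score.cutoffs", {})).items()}
        )
        if set(score_cutoffs) != {"chi", "conn", "cc"}:
            raise ConfigError(f"score.cutoffs keys must be chi/conn/cc")
        score = ScoreConfig(
            weights=tuple(float(w) for w in flat.get("score.weights", (1 / 3,) * 3)),
            cutoffs=score_cutoffs,
            redistribute=bool(flat.get("score.redistribute", True)),
        )
        scan_cutoffs = tuple(float(c) for c in flat.get("scan.cutoffs", DEFAULT_CUTOFFS))
        dn = tuple(int(x) for x in flat.get("scan.dn", DEFAULT_DN))
        size_classes = flat.get("eval.size_classes")
        if size_classes is not None:
            size_classes = tuple(int(x) for x in size_classes)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    return RunConfig(
        enm=enm, filters=filters, score=score,
        scan_cutoffs=scan_cutoffs, dn=dn, size_classes=size_classes,
        out_dir=str(flat.get("out_dir", ".")), seed=int(flat.get("seed", 0)),
    )
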