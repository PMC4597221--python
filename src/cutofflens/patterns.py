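"""Reduction of raw indicator profiles to peak patterns.

Raw per-residue indicators (spectral stiffness χ, connectivity c,
closeness centrality CC) are rugged; candidate sites are the peaks that
survive a high-pass filter keeping only values more than n_sigma
population standard deviations above the profile mean. Closeness
profiles are additionally passed through a 4-point moving average after
filtering so that clusters of quasi-degenerate peaks coalesce into a
single prediction. Max-normalization is provided for display only and
never affects peak detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IndicatorPattern",
    "ReducedPattern",
    "FilterConfig",
    "high_pass_filter",
    "smooth4",
    "detect_peaks",
    "reduce_pattern",
    "normalize_to_max",
]

INDICATORS = ("chi", "conn", "cc")


@dataclass
class IndicatorPattern:
    """Raw per-residue values of one indicator at one cutoff."""

    indicator: str  # "chi" | "conn" | "cc"
    cutoff: float   # Å
    values: np.ndarray
    structure_id: str = ""

    def __post_init__(self) -> None:
        if self.indicator not in INDICATORS:
            raise ValueError(f"unknown indicator {self.indicator!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("pattern values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pattern values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ReducedPattern:
    """Filtered profile plus the surviving peak indices.

    ``filtered`` is the post-pipeline profile (zeros where suppressed; for
    closeness, after smoothing); ``peaks`` are strictly increasing 0-based
    residue indices, one per surviving local maximum.
    """

    indicator: str
    cutoff: float
    structure_id: str
    filtered: np.ndarray
    peaks: list[int]
    n_sigma: float

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class FilterConfig:
    """High-pass thresholds per indicator, in population-SD units.

    Closeness gets the permissive default (its profiles are flat and
    overly rugged, and rely on the post-filter smoothing); stiffness and
    connectivity use one full standard deviation.
    """

    chi_nsigma: float = 1.0
    conn_nsigma: float = 1.0
    cc_nsigma: float = 0.5
    smooth_cc: bool = True

    def nsigma_for(self, indicator: str) -> float:
        return {"chi": self.chi_nsigma, "conn": self.conn_nsigma,
                "cc": self.cc_nsigma}[indicator]


def high_pass_filter(values: np.ndarray, n_sigma: float) -> np.ndarray:
    """Keep values strictly above mean + n_sigma · SD; zero the rest.

    The standard deviation is the population (1/N) SD over the whole
    profile. A constant profile has SD 0 and the strict inequality kills
    every entry.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to filter")
    threshold = values.mean() + n_sigma * values.std()
    return np.where(values > threshold, values, 0.0)


def smooth4(values: np.ndarray) -> np.ndarray:
    """4-point moving average, window i−1 .. i+2, truncated at boundaries.

    Boundary windows average only the in-range entries, so a constant
    profile is a fixed point. Profiles shorter than 4 are returned
    unchanged with a warning.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 4:
        warnings.warn("profile shorter than 4; smoothing skipped", stacklevel=2)
        return values.copy()
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - 1), min(n, i + 3)
        out[i] = values[lo:hi].mean()
    return out


def detect_peaks(values: np.ndarray) -> list[int]:
    """Indices of surviving peaks in a (filtered) profile.

    A peak is a maximal run of equal positive values strictly greater
    than both flanking values, with boundaries counting as −∞ flanks. A
    plateau run contributes one index: its lower median.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    peaks: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left = v[i - 1] if i > 0 else -np.inf
        right = v[j + 1] if j + 1 < n else -np.inf
        if v[i] > 0 and v[i] > left and v[i] > right:
            peaks.append(i + (j - i) // 2)
        i = j + 1
    return peaks


def reduce_pattern(p: IndicatorPattern, cfg: FilterConfig = FilterConfig()) -> ReducedPattern:
    """Filter → (smooth, closeness only) → peak detection."""
    n_sigma = cfg.nsigma_for(p.indicator)
    filtered = high_pass_filter(p.values, n_sigma)
    if p.indicator == "cc" and cfg.smooth_cc:
        filtered = smooth4(filtered)
    peaks = detect_peaks(filtered)
    return ReducedPattern(
        indicator=p.indicator, cutoff=p.cutoff, structure_id=p.structure_id,
        filtered=filtered, peaks=peaks, n_sigma=n_sigma,
    )


def normalize_to_max(values: np.ndarray) -> np.ndarray:
    """Scale a profile to [0, 1] by its maximum; all-zero input unchanged.

    Display-only: peak detection always runs on unnormalized profiles.
    """
    values = np.asarray(values, dtype=float)
    m = values.max(initial=0.0)
    if m <= 0:
        return values.copy()
    return values / m
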