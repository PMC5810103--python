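"""Competitive-index fitness analysis of wild-type vs. mutant co-cultures.

Strain ratios at inoculation (t = 0) and at the endpoint are measured as
percentages (e.g., from Sanger chromatogram peak heights at a discriminating
position) and combined into the competitive index

    CI = (mutant_end * wildtype_start) / (mutant_start * wildtype_end)

CI = 1 means no fitness difference; CI > 1 a mutant advantage.  Replicate
CIs are aggregated by geometric mean by default (a CI is a ratio);
arithmetic mean is available by flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "CompetitionObservation",
    "peak_ratio_to_pct",
    "normalize_t0",
    "competitive_index",
    "aggregate_ci",
]


@dataclass
class CompetitionObservation:
    """Start/end strain percentages for one replicate of one condition."""

    condition: str
    wt_start_pct: float
    mut_start_pct: float
    wt_end_pct: float
    mut_end_pct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        for name in ("wt_start_pct", "mut_start_pct", "wt_end_pct", "mut_end_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        for a, b in ((self.wt_start_pct, self.mut_start_pct),
                     (self.wt_end_pct, self.mut_end_pct)):
            if abs(a + b - 100.0) > 0.01:
                raise ValueError(f"percentages {a} + {b} do not sum to 100")


def peak_ratio_to_pct(h_wt: float, h_mut: float, noise_floor: float = 0.0) -> tuple[float, float]:
    """Convert chromatogram peak heights to percentages summing to 100.

    Heights below ``noise_floor`` are clamped to the floor with a warning
    rather than producing degenerate 0/100 ratios downstream.
    """
    if h_wt < 0 or h_mut < 0:
        raise ValueError("peak heights must be non-negative")
    if noise_floor > 0:
        if h_wt < noise_floor or h_mut < noise_floor:
            warnings.warn("peak height below noise floor; clamping", stacklevel=2)
        h_wt = max(h_wt, noise_floor)
        h_mut = max(h_mut, noise_floor)
    total = h_wt + h_mut
    if total <= 0:
        raise ValueError("peak heights sum to zero")
    return 100.0 * h_wt / total, 100.0 * h_mut / total


def normalize_t0(obs: CompetitionObservation) -> CompetitionObservation:
    """Rescale an observation to a 50:50 start ratio.

    Each strain's endpoint percentage is divided by its start fraction (the
    per-strain correction factor that maps the start to 50:50) and the
    endpoint pair is re-normalized to 100.  An observation already at 50:50
    is returned unchanged; if the start and end ratios are equal the
    normalized endpoint is 50:50 (no net change).
    """
    if obs.wt_start_pct <= 0 or obs.mut_start_pct <= 0:
        raise ValueError("cannot normalize: a strain is absent at t = 0")
    wt = obs.wt_end_pct * (50.0 / obs.wt_start_pct)
    mut = obs.mut_end_pct * (50.0 / obs.mut_start_pct)
    total = wt + mut
    if total <= 0:
        raise ValueError("degenerate endpoint after normalization")
    return CompetitionObservation(
        condition=obs.condition,
        wt_start_pct=50.0,
        mut_start_pct=50.0,
        wt_end_pct=100.0 * wt / total,
        mut_end_pct=100.0 * mut / total,
        replicate=obs.replicate,
    )


def competitive_index(obs: CompetitionObservation) -> float:
    """CI = (mut_end * wt_start) / (mut_start * wt_end).

    Raises on a zero denominator (a strain absent at start or the wild type
    extinct at the end leaves the CI undefined).  Swapping the strain labels
    maps CI to 1/CI; multiplying all four percentages by a constant leaves
    CI unchanged.
    """
    denom = obs.mut_start_pct * obs.wt_end_pct
    if denom <= 0:
        raise ZeroDivisionError("competitive index undefined: zero denominator")
    if obs.mut_end_pct <= 0 or obs.wt_start_pct <= 0:
        raise ZeroDivisionError("competitive index degenerate: zero numerator")
    return (obs.mut_end_pct * obs.wt_start_pct) / denom


def aggregate_ci(cis: Sequence[float], method: str = "geometric") -> float:
    """Summarize replicate CIs (geometric mean by default)."""
    if not cis:
        raise ValueError("no replicate CIs to aggregate")
    if method == "geometric":
        return math.exp(sum(math.log(c) for c in cis) / len(cis))
    if method == "arithmetic":
        return sum(cis) / len(cis)
    raise ValueError(f"unknown aggregation method {method!r}")
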