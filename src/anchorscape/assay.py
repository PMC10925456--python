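"""Measurement-derived statistics from fluorescence medians and phage titers.

All operations here consume *medians* (or raw event values for
:func:`median_of_events` only) and are deterministic given their inputs.
Negative background-subtracted values raise rather than clamp: callers are
expected to handle noisy data upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class TiterPair:
    """Initial and final phage titers (p.f.u./ml) across a passage."""

    initial: float
    final: float

    def __post_init__(self) -> None:
        if not (self.initial > 0 and self.final > 0):
            raise ValueError("titers must be positive")


def fold_repression(uninduced: float, induced: float, background: float) -> float:
    """(uninduced − background) / (induced − background).

    The fitness readout for repressor variants: background cell
    autofluorescence is subtracted from both groups, then the unrepressed
    (no repressor) median is divided by the repressed (repressor expressed)
    median.
    """
    u, i = uninduced - background, induced - background
    if i <= 0:
        raise ValueError("induced median must exceed background")
    if u <= 0:
        raise ValueError("uninduced median must exceed background")
    return u / i


def relative_expression(variant: float, background: float, standard: float) -> float:
    """(variant − background) / standard.

    The standard value is used as-is, without background subtraction.
    """
    if standard <= 0:
        raise ValueError("standard value must be positive")
    return (variant - background) / standard


def circuit_score(on_medians: Iterable[float], off_medians: Iterable[float]) -> float:
    """Lowest ON-state signal divided by highest OFF-state signal."""
    on = list(on_medians)
    off = list(off_medians)
    if not on or not off:
        raise ValueError("ON and OFF collections must be nonempty")
    hi_off = max(off)
    if hi_off <= 0:
        raise ValueError("highest OFF signal must be positive")
    return min(on) / hi_off


def resistance_index(with_inhibitor: float, without_inhibitor: float) -> float:
    """Reporter median with inhibitor over without; >1 means inhibitor-enhanced."""
    if without_inhibitor <= 0:
        raise ValueError("denominator median must be positive")
    return with_inhibitor / without_inhibitor


def fold_propagation(t: TiterPair) -> float:
    """Final over initial phage titer: the selection-strength readout."""
    return t.final / t.initial


def ratio_fold_repression(
    mcherry_r: float,
    bfp_r: float,
    mcherry_u: float,
    bfp_u: float,
    mcherry0: float,
    bfp0: float,
) -> float:
    """Fold repression from mCherry:BFP ratios in mammalian cells.

    Each state's activity is the background-subtracted mCherry over
    background-subtracted BFP; the unrepressed ratio is divided by the
    repressed ratio.
    """
    bfp_u_s, bfp_r_s = bfp_u - bfp0, bfp_r - bfp0
    if bfp_u_s <= 0 or bfp_r_s <= 0:
        raise ValueError("background-subtracted BFP must be positive")
    ratio_u = (mcherry_u - mcherry0) / bfp_u_s
    ratio_r = (mcherry_r - mcherry0) / bfp_r_s
    if ratio_r <= 0:
        raise ValueError("repressed mCherry:BFP ratio must be positive")
    return ratio_u / ratio_r


def median_of_events(values: Sequence[float]) -> float:
    """Sample median of raw cytometry event values (average of middle two)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty event collection")
    return float(np.median(arr))
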