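"""Growth-curve kinetics for the quantitative yeast two-hybrid readout.

In the two-hybrid assay, interaction strength between a bait and prey
pair is proxied by how fast the reporter strain grows in selective
medium.  Exponential growth follows OD_t = OD_0 * 2^(t/T), so the
generation (doubling) time T is 1 / slope of a least-squares fit of
log2(OD) against time.  Interaction affinities of two constructs are
compared as the ratio of their mean growth rates (1/T) with a pooled
two-sample Student's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["GrowthCurve", "FoldChangeResult", "generation_time", "affinity_fold_change"]


@dataclass(frozen=True)
class GrowthCurve:
    """OD600 readings over time (hours) for one culture."""

    time: tuple[float, ...]
    od: tuple[float, ...]
    strain: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.time)
        o = tuple(float(x) for x in self.od)
        if len(t) != len(o) or len(t) < 2:
            raise ValueError("need >= 2 matching (time, OD) points")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("time points must be strictly increasing")
        if any(x <= 0 for x in o):
            raise ValueError("OD readings must be positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "od", o)


def _exponential_window(t: np.ndarray, od: np.ndarray) -> np.ndarray:
    """Default window: readings between 1.5x the initial OD and half the
    final reading (a plateau proxy); falls back to all points when fewer
    than two qualify, so short ideal curves are fitted whole."""
    mask = (od >= 1.5 * od[0]) & (od <= 0.5 * od[-1])
    if mask.sum() < 2:
        return np.ones_like(mask, dtype=bool)
    return mask


def generation_time(
    curve: GrowthCurve, window: tuple[float, float] | None = None
) -> float:
    """Doubling time T (hours) from a log2-linear fit of the growth curve.

    ``window`` restricts the fit to an explicit time interval; by default
    an OD-based exponential-phase window is used (see above).  A
    non-positive fitted slope (no growth) raises ``ValueError``.
    """
    t = np.asarray(curve.time)
    od = np.asarray(curve.od)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        if mask.sum() < 2:
            raise ValueError("fewer than 2 points in the requested window")
    else:
        mask = _exponential_window(t, od)
    slope, _ = np.polyfit(t[mask], np.log2(od[mask]), 1)
    if slope <= 0:
        raise ValueError(f"non-positive growth slope ({slope:.4g}): no growth")
    return float(1.0 / slope)


@dataclass(frozen=True)
class FoldChangeResult:
    """Growth-rate ratio of two arms with the pooled t-test on rates."""

    fold_change: float
    t_statistic: float
    p_value: float
    n_mutant: int
    n_wildtype: int


def affinity_fold_change(
    mutant_T: Sequence[float], wildtype_T: Sequence[float]
) -> FoldChangeResult:
    """Compare replicate generation times of a mutant arm against wild type.

    The compared quantity is the growth rate 1/T (the interaction-strength
    proxy): fold change = mean mutant rate / mean wild-type rate, with a
    pooled two-sample Student's t-test on the rates.
    """
    mt = np.asarray(mutant_T, dtype=float)
    wt = np.asarray(wildtype_T, dtype=float)
    if mt.size < 2 or wt.size < 2:
        raise ValueError("need >= 2 replicates per arm")
    if (mt <= 0).any() or (wt <= 0).any():
        raise ValueError("generation times must be positive")
    rate_m = 1.0 / mt
    rate_w = 1.0 / wt
    t_stat, p = stats.ttest_ind(rate_m, rate_w, equal_var=True)
    return FoldChangeResult(
        fold_change=float(rate_m.mean() / rate_w.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        n_mutant=mt.size,
        n_wildtype=wt.size,
    )
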