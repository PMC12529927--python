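"""Per-position reactivity from chemical-probing gel lanes.

Hydroxyl-radical (and periodate) probing reads out solvent accessibility of
the guide backbone: each lane resolves the ladder of cleavage products, and
the fraction of total lane signal at a band reports cleavage at that
position.  Relative reactivity at a position is

    (S - Q) / (N - Q)

where S is the signal fraction in the probed sample, Q in the pre-quenched
negative control (workup background), and N in the free-guide positive
control (maximal accessibility).  Positions where the free-guide control
does not rise above the quenched background are not determined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LaneProfile",
    "ReactivityProfile",
    "lane_fractions",
    "relative_reactivity",
    "reactivity_profile",
    "aggregate_replicates",
]

ND = float("nan")  # not-determined marker


@dataclass
class LaneProfile:
    """Band intensities per guide position for one gel lane."""

    lane_id: str
    intensities: np.ndarray  # arbitrary units >= 0, index = guide position - 1
    role: str = "sample"     # sample | pre_quenched | free_guide

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if (self.intensities < 0).any():
            raise ValueError("band intensities must be >= 0")
        if not (self.intensities > 0).any():
            raise ValueError(f"lane {self.lane_id}: no positive band")


def lane_fractions(lane: LaneProfile) -> np.ndarray:
    """Fraction of total lane signal attributed to each band (sums to 1)."""
    total = lane.intensities.sum()
    return lane.intensities / total


def relative_reactivity(s: float, q: float, n_free: float) -> float:
    """(S - Q) / (N - Q); NaN (not determined) when the free-guide control
    does not exceed the quenched background."""
    if n_free <= q:
        return ND
    return (s - q) / (n_free - q)


@dataclass
class ReactivityProfile:
    """Per-position relative reactivity with out-of-range flags.

    Values outside [0, 1] can occur with noise and are reported as
    computed, flagged rather than clipped.
    """

    reactivity: np.ndarray
    flags: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.reactivity) + 1),
                "reactivity": self.reactivity,
                "flag": self.flags,
            }
        )


def reactivity_profile(
    sample: LaneProfile, pre_quenched: LaneProfile, free_guide: LaneProfile
) -> ReactivityProfile:
    """Full lane-fractions -> relative-reactivity pipeline for one sample."""
    s = lane_fractions(sample)
    q = lane_fractions(pre_quenched)
    n = lane_fractions(free_guide)
    if not (len(s) == len(q) == len(n)):
        raise ValueError("lanes must cover the same positions")
    vals = np.array(
        [relative_reactivity(si, qi, ni) for si, qi, ni in zip(s, q, n)]
    )
    flags = []
    for v in vals:
        if math.isnan(v):
            flags.append("not_determined")
        elif v < 0 or v > 1:
            flags.append("out_of_range")
        else:
            flags.append("ok")
    return ReactivityProfile(vals, flags)


def aggregate_replicates(
    profiles: Sequence[ReactivityProfile],
) -> pd.DataFrame:
    """Mean reactivity across replicates with range (n=2) or 95% CI (n>=3).

    Positions not determined in any replicate are aggregated over the
    remaining replicates; all-ND positions stay ND.
    """
    if not profiles:
        raise ValueError("no profiles")
    mat = np.vstack([p.reactivity for p in profiles])
    n_pos = mat.shape[1]
    n_rep = np.sum(~np.isnan(mat), axis=0)
    mean = np.full(n_pos, np.nan)
    lo = np.full(n_pos, np.nan)
    hi = np.full(n_pos, np.nan)
    for j in range(n_pos):
        vals = mat[~np.isnan(mat[:, j]), j]
        if len(vals) == 0:
            continue
        mean[j] = vals.mean()
        if len(vals) <= 2:
            lo[j], hi[j] = vals.min(), vals.max()   # error bars: range
        else:
            from scipy import stats

            sem = vals.std(ddof=1) / np.sqrt(len(vals))
            t = stats.t.ppf(0.975, len(vals) - 1)
            lo[j], hi[j] = vals.mean() - t * sem, vals.mean() + t * sem
    return pd.DataFrame(
        {
            "position": np.arange(1, n_pos + 1),
            "reactivity": mean,
            "n": n_rep,
            "err_lo": lo,
            "err_hi": hi,
        }
    )
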