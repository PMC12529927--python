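"""Multiplicative decomposition of compound-site binding affinities.

Compound sites combine a pattern of 3' complementarity, a pattern of seed
complementarity, and an offset.  Across many such combinations, the
negative log10 relative Kd is well described by a product of one
coefficient per element:

    -log10(Kd_rel) = A_threep * B_seed * C_offset

Fitting is ordinary least squares after a log transform, which turns the
product into an additive three-way categorical model.  The raw coefficient
scale is arbitrary (two compensating scale freedoms); for reporting, each
family is min-max rescaled to [0, 1], and the raw values are also kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

__all__ = [
    "CompoundDecomposition",
    "MultiplicativeFit",
    "fit_multiplicative",
    "predict_logkd",
]


@dataclass(frozen=True)
class CompoundDecomposition:
    """One compound site's elements and its -log10 relative Kd (y > 0)."""

    threep_pattern: str
    seed_pattern: str
    offset: int
    y: float


@dataclass
class MultiplicativeFit:
    """Fitted coefficients per family, raw and min-max rescaled."""

    A: dict[str, float]
    B: dict[str, float]
    C: dict[int, float]
    A_scaled: dict[str, float]
    B_scaled: dict[str, float]
    C_scaled: dict[int, float]
    r_pearson: float
    r_spearman: float
    residual_ss: float
    n_obs: int
    rejects: list[CompoundDecomposition] = field(default_factory=list)

    def coefficient_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "threep": pd.DataFrame(
                {"level": list(self.A), "coef": list(self.A.values()),
                 "coef_scaled": list(self.A_scaled.values())}
            ),
            "seed": pd.DataFrame(
                {"level": list(self.B), "coef": list(self.B.values()),
                 "coef_scaled": list(self.B_scaled.values())}
            ),
            "offset": pd.DataFrame(
                {"level": list(self.C), "coef": list(self.C.values()),
                 "coef_scaled": list(self.C_scaled.values())}
            ),
        }


def _minmax(d: dict) -> dict:
    vals = np.array(list(d.values()), dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return {k: 1.0 for k in d}
    return {k: float((v - lo) / (hi - lo)) for k, v in d.items()}


def _connected(obs: Sequence[tuple[int, int, int]], sizes) -> Optional[str]:
    """Union-find over coefficient levels; returns a disconnected level
    label or None."""
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    total = offsets[-1]
    parent = list(range(total))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for u, v, w in obs:
        union(offsets[0] + u, offsets[1] + v)
        union(offsets[1] + v, offsets[2] + w)
    roots = {find(i) for i in range(total)}
    if len(roots) == 1:
        return None
    main = find(obs[0][0])
    for i in range(total):
        if find(i) != main:
            fam = int(np.searchsorted(offsets, i, side="right")) - 1
            return f"family {['threep', 'seed', 'offset'][fam]} level index {i - offsets[fam]}"
    return None


def fit_multiplicative(
    decomps: Sequence[CompoundDecomposition],
    weights: Optional[Sequence[float]] = None,
) -> MultiplicativeFit:
    """Least-squares fit of log y = log A_u + log B_v + log C_w.

    Sites with y <= 0 (relative Kd >= 1) cannot enter the log model; they
    are dropped into ``rejects``.  Identifiability is fixed by rescaling so
    max(A) = max(B) = 1, absorbing the scale into C.
    """
    rejects = [d for d in decomps if d.y <= 0]
    fitted = [d for d in decomps if d.y > 0]
    if not fitted:
        raise ValueError("no observations with y > 0")
    a_levels = sorted({d.threep_pattern for d in fitted})
    b_levels = sorted({d.seed_pattern for d in fitted})
    c_levels = sorted({d.offset for d in fitted})
    ai = {l: i for i, l in enumerate(a_levels)}
    bi = {l: i for i, l in enumerate(b_levels)}
    ci = {l: i for i, l in enumerate(c_levels)}
    obs = [(ai[d.threep_pattern], bi[d.seed_pattern], ci[d.offset]) for d in fitted]
    bad = _connected(obs, [len(a_levels), len(b_levels), len(c_levels)])
    if bad is not None:
        raise ValueError(f"disconnected coefficient design at {bad}")

    na, nb, nc = len(a_levels), len(b_levels), len(c_levels)
    X = np.zeros((len(fitted), na + nb + nc))
    for r, (u, v, w) in enumerate(obs):
        X[r, u] = 1.0
        X[r, na + v] = 1.0
        X[r, na + nb + w] = 1.0
    logy = np.log([d.y for d in fitted])
    if weights is not None:
        wts = np.sqrt(np.asarray(weights, dtype=float)[[d.y > 0 for d in decomps]])
        X = X * wts[:, None]
        logy = logy * wts
    beta, *_ = np.linalg.lstsq(X, logy, rcond=None)
    la, lb, lc = beta[:na], beta[na : na + nb], beta[na + nb :]
    # fix the two scale freedoms: max(A) = max(B) = 1, C absorbs the rest
    sa, sb = la.max(), lb.max()
    la, lb, lc = la - sa, lb - sb, lc + sa + sb
    A = {l: float(np.exp(v)) for l, v in zip(a_levels, la)}
    B = {l: float(np.exp(v)) for l, v in zip(b_levels, lb)}
    C = {l: float(np.exp(v)) for l, v in zip(c_levels, lc)}

    pred = np.exp(la[[o[0] for o in obs]] + lb[[o[1] for o in obs]]
                  + lc[[o[2] for o in obs]])
    y = np.array([d.y for d in fitted])
    if len(y) > 1 and np.std(y) > 0 and np.std(pred) > 0:
        r_p = float(pearsonr(y, pred)[0])
        r_s = float(spearmanr(y, pred)[0])
    else:
        r_p = r_s = np.nan
    resid = float(np.sum((np.log(y) - np.log(pred)) ** 2))
    return MultiplicativeFit(
        A=A, B=B, C=C,
        A_scaled=_minmax(A), B_scaled=_minmax(B), C_scaled=_minmax(C),
        r_pearson=r_p, r_spearman=r_s,
        residual_ss=resid, n_obs=len(fitted), rejects=rejects,
    )


def predict_logkd(fit: MultiplicativeFit, site: CompoundDecomposition) -> float:
    """Model-predicted -log10 relative Kd; refuses unseen levels."""
    for fam, levels, key in (
        ("threep", fit.A, site.threep_pattern),
        ("seed", fit.B, site.seed_pattern),
        ("offset", fit.C, site.offset),
    ):
        if key not in levels:
            raise KeyError(f"unseen {fam} level {key!r}; no extrapolation")
    return fit.A[site.threep_pattern] * fit.B[site.seed_pattern] * fit.C[site.offset]
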