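"""Response of endogenous mRNAs to miRNA transfection.

Starting from a batch-normalized log10 TPM matrix over a panel of
miRNA-transfection samples, each gene's log2 fold-change for a given miRNA
is computed leave-one-out: its logTPM in that sample minus the mean of its
logTPM in the other samples, converted from log10 to log2 units.  Cohorts
of site-containing genes are then compared to UTR-length-matched no-site
control cohorts with a one-sided Kolmogorov-Smirnov test for a shift
toward repression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortResult",
    "leave_one_out_fc",
    "match_controls",
    "ks_one_sided",
    "cohort_response",
    "cdf_coordinates",
]

LOG2_PER_LOG10 = float(np.log2(10.0))
MIN_COHORT_SIZE = 10


def leave_one_out_fc(matrix: pd.DataFrame, mirna: str) -> pd.Series:
    """Per-gene log2 fold-change of one sample versus the mean of the rest.

    ``matrix`` holds log10 TPM values, genes x samples.  Genes with missing
    values are dropped with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if mirna not in matrix.columns:
        raise KeyError(f"sample {mirna!r} not in matrix")
    missing = matrix.isna().any(axis=1)
    if missing.any():
        warnings.warn(
            f"dropping {int(missing.sum())} genes with missing values",
            stacklevel=2,
        )
        matrix = matrix[~missing]
    others = matrix.drop(columns=[mirna])
    return (matrix[mirna] - others.mean(axis=1)) * LOG2_PER_LOG10


def match_controls(
    cohort_lengths: Mapping[str, float],
    candidate_lengths: Mapping[str, float],
    seed: int = 0,
    n_strata: int = 10,
) -> list[str]:
    """Sample a control cohort whose UTR-length distribution matches.

    Candidates are stratified by deciles of the cohort's length
    distribution; each stratum contributes as many controls as the cohort
    has members there, spilling into the nearest stratum (with a warning)
    when a stratum runs dry.  Deterministic given the seed.
    """
    cohort = pd.Series(cohort_lengths, dtype=float)
    pool = pd.Series(candidate_lengths, dtype=float)
    if len(pool) < len(cohort):
        raise ValueError("candidate pool smaller than cohort")
    rng = np.random.default_rng(seed)
    if len(cohort) == 1:
        target = cohort.iloc[0]
        return [(pool - target).abs().idxmin()]
    edges = np.quantile(cohort, np.linspace(0, 1, n_strata + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    cohort_bins = np.digitize(cohort, edges[1:-1])
    pool_bins = pd.Series(np.digitize(pool, edges[1:-1]), index=pool.index)
    chosen: list[str] = []
    available = set(pool.index)
    for stratum in range(n_strata):
        need = int((cohort_bins == stratum).sum())
        if need == 0:
            continue
        here = [g for g in pool_bins.index[pool_bins == stratum] if g in available]
        rng.shuffle(here)
        take = here[:need]
        short = need - len(take)
        if short > 0:
            warnings.warn(
                f"stratum {stratum}: only {len(take)}/{need} candidates; "
                "relaxing to nearest lengths",
                stacklevel=2,
            )
            mid = np.median(cohort[cohort_bins == stratum])
            rest = pool[[g for g in available if g not in take]]
            extra = (rest - mid).abs().sort_values().index[:short].tolist()
            take = take + extra
        chosen.extend(take)
        available -= set(take)
    return chosen


def ks_one_sided(
    cohort_fc: Sequence[float], control_fc: Sequence[float]
) -> tuple[float, float]:
    """One-sided two-sample KS test for the cohort being shifted toward
    repression (stochastically smaller than controls).

    Returns (D, p) with the asymptotic p-value.  Small samples (n < 5) are
    flagged with a warning as low-power.
    """
    cohort_fc = np.asarray(cohort_fc, dtype=float)
    control_fc = np.asarray(control_fc, dtype=float)
    if len(cohort_fc) == 0 or len(control_fc) == 0:
        raise ValueError("both samples must be nonempty")
    if min(len(cohort_fc), len(control_fc)) < 5:
        warnings.warn("fewer than 5 observations: low-power KS test",
                      stacklevel=2)
    # alternative="greater": the cohort's empirical CDF lies above the
    # control's, i.e. cohort values are shifted downward (repressed)
    res = stats.ks_2samp(cohort_fc, control_fc, alternative="greater",
                         method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class CohortResult:
    """KS comparison of one site cohort against length-matched controls."""

    cohort: str
    genes: list[str]
    controls: list[str]
    log2fc: np.ndarray
    control_log2fc: np.ndarray
    ks_d: float
    p_value: float
    low_power: bool = False


def cohort_response(
    matrix: pd.DataFrame,
    mirna: str,
    cohort_genes: Sequence[str],
    utr_lengths: Mapping[str, float],
    no_site_genes: Sequence[str],
    seed: int = 0,
    cohort_name: Optional[str] = None,
) -> CohortResult:
    """End-to-end cohort test: fold-changes, matched controls, one-sided KS."""
    fc = leave_one_out_fc(matrix, mirna)
    cohort_genes = [g for g in cohort_genes if g in fc.index]
    controls = match_controls(
        {g: utr_lengths[g] for g in cohort_genes},
        {g: utr_lengths[g] for g in no_site_genes if g in fc.index},
        seed=seed,
    )
    d, p = ks_one_sided(fc[cohort_genes].to_numpy(), fc[controls].to_numpy())
    return CohortResult(
        cohort=cohort_name or f"{mirna}-cohort",
        genes=list(cohort_genes),
        controls=controls,
        log2fc=fc[cohort_genes].to_numpy(),
        control_log2fc=fc[controls].to_numpy(),
        ks_d=d,
        p_value=p,
        low_power=len(cohort_genes) < MIN_COHORT_SIZE,
    )


def cdf_coordinates(values: Sequence[float]) -> pd.DataFrame:
    """Empirical CDF (x, F(x)) pairs for plotting cumulative distributions."""
    x = np.sort(np.asarray(values, dtype=float))
    return pd.DataFrame({"x": x, "cdf": np.arange(1, len(x) + 1) / len(x)})
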