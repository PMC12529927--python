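"""Equilibrium binding curves, association kinetics, and binding energetics.

Single-target filter-binding measurements are fit to the fractional
saturation equation

    theta_B = [AGO-miR]_total / ([AGO-miR]_total + Kd)

and association time courses, acquired with AGO-miR in pseudo-first-order
excess over trace target, to the integrated rate equation

    AR(t) = AR_eq * (1 - exp(-kon * A_T * t)).

Dissociation rates follow from Kd = koff/kon.  Binding free energies are
compared between the AGO context (ΔG° = RT ln Kd from relative Kd values)
and the prediction for the equivalent duplex free in solution from
nearest-neighbor stacking rules.

Reporting conventions for curves that cannot be fit: targets with
negligible binding (theta < 0.2 everywhere) carry a Kd lower bound of
10 nM; targets already saturated at the lowest concentration
(theta >= 0.8) carry an upper bound of 5 pM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from .site_grammar import MirnaGuide, revcomp

__all__ = [
    "BindingCurve",
    "SaturationFit",
    "KineticsSeries",
    "AssociationFit",
    "EnergyRecord",
    "NNParamTable",
    "fit_saturation",
    "fit_association",
    "fit_association_pooled",
    "derive_koff",
    "delta_g_observed",
    "delta_g_predicted_nn",
    "load_nn_params",
    "GAS_CONSTANT_KCAL",
    "ASSAY_TEMPERATURE_K",
    "LOWER_BOUND_KD",
    "UPPER_BOUND_KD",
]

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal / (mol K)
ASSAY_TEMPERATURE_K = 310.15   # assays at 37 C
LOWER_BOUND_KD = 10e-9         # negligible binding at the top concentration
UPPER_BOUND_KD = 5e-12         # saturated at the lowest concentration
PSEUDO_FIRST_ORDER_MIN = 80e-12


@dataclass
class BindingCurve:
    """Fraction bound versus total AGO-miR concentration (molar)."""

    ago_total: np.ndarray
    theta: np.ndarray
    replicate: Optional[np.ndarray] = None

    def __post_init__(self):
        self.ago_total = np.asarray(self.ago_total, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.ago_total.shape != self.theta.shape:
            raise ValueError("ago_total and theta must align")
        if (self.ago_total <= 0).any():
            raise ValueError("concentrations must be positive")
        order = np.argsort(self.ago_total, kind="stable")
        self.ago_total = self.ago_total[order]
        self.theta = self.theta[order]
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)[order]
        self.clipped = bool(((self.theta < 0) | (self.theta > 1)).any())
        self.theta = np.clip(self.theta, 0.0, 1.0)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BindingCurve":
        return cls(
            df["ago_total"].to_numpy(),
            df["theta"].to_numpy(),
            df["replicate"].to_numpy() if "replicate" in df else None,
        )


@dataclass
class SaturationFit:
    kd: float
    ci95: tuple[float, float]
    bound_flag: str = "measured"  # or lower_bound_10nM / upper_bound_5pM

    @property
    def is_bound(self) -> bool:
        return self.bound_flag != "measured"


def saturation_theta(conc, kd):
    return conc / (conc + kd)


def fit_saturation(
    curve: BindingCurve,
    n_boot: int = 200,
    seed: int = 0,
    low_theta: float = 0.2,
    high_theta: float = 0.8,
) -> SaturationFit:
    """Nonlinear least-squares fit of the fractional saturation equation.

    The 95% CI is a parametric bootstrap: Gaussian noise at the residual sd
    is re-drawn around the fitted curve and the fit repeated.
    """
    conc, theta = curve.ago_total, curve.theta
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 concentration points")
    by_conc = pd.Series(theta).groupby(pd.Series(conc)).mean()
    if theta.max() < low_theta:
        return SaturationFit(LOWER_BOUND_KD, (LOWER_BOUND_KD, np.inf),
                             "lower_bound_10nM")
    if by_conc.iloc[0] >= high_theta:
        return SaturationFit(UPPER_BOUND_KD, (0.0, UPPER_BOUND_KD),
                             "upper_bound_5pM")

    def fit_once(y):
        half = conc[np.argmin(np.abs(y - 0.5))]
        popt, _ = curve_fit(
            lambda c, logkd: saturation_theta(c, np.exp(logkd)),
            conc,
            y,
            p0=[np.log(half)],
            maxfev=10_000,
        )
        return float(np.exp(popt[0]))

    kd = fit_once(theta)
    resid_sd = float(np.std(theta - saturation_theta(conc, kd), ddof=1))
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        y = saturation_theta(conc, kd) + rng.normal(0, resid_sd, size=len(conc))
        try:
            draws.append(fit_once(np.clip(y, 0, 1)))
        except RuntimeError:
            continue
    if draws:
        ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
    else:
        ci = (np.nan, np.nan)
    return SaturationFit(kd, ci)


@dataclass
class KineticsSeries:
    """Bound-complex signal AR(t) at fixed total AGO concentration."""

    times: np.ndarray
    ar: np.ndarray
    a_total: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ar = np.asarray(self.ar, dtype=float)
        if self.times.shape != self.ar.shape:
            raise ValueError("times and ar must align")
        if (self.times < 0).any() or (np.diff(np.unique(self.times)) <= 0).any():
            raise ValueError("times must be nonnegative and increasing")
        if self.a_total < PSEUDO_FIRST_ORDER_MIN:
            raise ValueError(
                "a_total below 80 pM violates the pseudo-first-order guard"
            )


@dataclass
class AssociationFit:
    kon: float           # 1/M/s
    ar_eq: float
    ci95_kon: tuple[float, float]
    warning: Optional[str] = None


def association_ar(t, kon, a_total, ar_eq):
    return ar_eq * (1.0 - np.exp(-kon * a_total * t))


def fit_association(
    series: KineticsSeries, n_boot: int = 200, seed: int = 0
) -> AssociationFit:
    """Least-squares fit of the pseudo-first-order association equation."""
    t, ar = series.times, series.ar
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 timepoints")
    warning = None
    tail = ar[t > np.median(t)]
    head = ar[t <= np.median(t)]
    if tail.size and head.size and tail.mean() <= head.mean():
        warning = "signal does not increase over time; kon CI will be wide"
        warnings.warn(warning, stacklevel=2)

    def fit_once(y):
        ar_eq0 = max(y.max(), 1e-12)
        # crude half-time initialization
        half_idx = np.argmin(np.abs(y - 0.5 * ar_eq0))
        t_half = max(t[half_idx], t[t > 0].min() if (t > 0).any() else 1.0)
        k0 = np.log(2) / (series.a_total * t_half)
        popt, _ = curve_fit(
            lambda tt, logk, ae: association_ar(tt, np.exp(logk), series.a_total, ae),
            t,
            y,
            p0=[np.log(k0), ar_eq0],
            maxfev=10_000,
        )
        return float(np.exp(popt[0])), float(popt[1])

    kon, ar_eq = fit_once(ar)
    resid = ar - association_ar(t, kon, series.a_total, ar_eq)
    sd = float(np.std(resid, ddof=1))
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        y = association_ar(t, kon, series.a_total, ar_eq) + rng.normal(
            0, sd, size=len(t)
        )
        try:
            draws.append(fit_once(y)[0])
        except RuntimeError:
            continue
    if draws:
        ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
    else:
        ci = (np.nan, np.nan)
    if warning:
        ci = (min(ci[0], kon / 100), max(ci[1], kon * 100))
    return AssociationFit(kon, ar_eq, ci, warning)


def fit_association_pooled(series_list: Sequence[KineticsSeries]) -> AssociationFit:
    """One kon shared across series at different AGO concentrations,
    each with its own plateau."""
    if not series_list:
        raise ValueError("no series given")

    def residuals(x):
        logk = x[0]
        out = []
        for s, ae in zip(series_list, x[1:]):
            out.append(s.ar - association_ar(s.times, np.exp(logk), s.a_total, ae))
        return np.concatenate(out)

    k0 = np.log(
        np.mean([fit_association(s, n_boot=0).kon for s in series_list])
    )
    x0 = np.array([k0] + [max(s.ar.max(), 1e-12) for s in series_list])
    res = least_squares(residuals, x0)
    return AssociationFit(float(np.exp(res.x[0])), float(np.mean(res.x[1:])),
                          (np.nan, np.nan))


def derive_koff(kd: float, kon: float, bound_flag: str = "measured"):
    """koff = Kd * kon; the dissociation rate inherits any Kd bound flag."""
    if kd <= 0 or kon <= 0:
        raise ValueError("kd and kon must be positive")
    koff = kd * kon
    if bound_flag == "measured":
        return koff
    return koff, bound_flag


def delta_g_observed(
    rel_kd: float, temperature: float = ASSAY_TEMPERATURE_K
) -> float:
    """Observed binding free energy, ΔG° = RT ln(Kd), kcal/mol."""
    if rel_kd <= 0:
        raise ValueError("rel_kd must be positive")
    return GAS_CONSTANT_KCAL * temperature * float(np.log(rel_kd))


@dataclass
class NNParamTable:
    """Nearest-neighbor stack terms plus initiation and terminal-AU terms."""

    stacks: dict[str, float]
    init: float
    terminal_au: float

    def __post_init__(self):
        expected = {
            a + b
            for a in "ACGU"
            for b in "ACGU"
        }
        missing = expected - set(self.stacks)
        if missing:
            raise ValueError(f"incomplete stack table, missing {sorted(missing)}")
        for d, v in self.stacks.items():
            partner = revcomp(d)
            if abs(self.stacks[partner] - v) > 1e-9:
                raise ValueError(f"stack table not reversal-symmetric at {d}")


def load_nn_params() -> NNParamTable:
    """Load the packaged Turner-style stack table."""
    text = resources.files("seedless").joinpath("nn_stacks.tsv").read_text()
    stacks, init, term = {}, None, None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("param"):
            continue
        kind, key, val = line.split("\t")
        if kind == "stack":
            stacks[key] = float(val)
        elif kind == "init":
            init = float(val)
        elif kind == "terminal_au":
            term = float(val)
    return NNParamTable(stacks, init, term)


def delta_g_predicted_nn(
    guide_segment: str, params: NNParamTable | None = None
) -> float:
    """ΔG° of the perfect Watson-Crick duplex of a guide segment in solution.

    Sum of stack terms over adjacent base pairs, plus duplex initiation,
    plus a terminal-AU penalty for each helix end closed by an A-U pair.
    """
    from .site_grammar import normalize_rna

    seg = normalize_rna(guide_segment)
    if len(seg) < 2:
        raise ValueError("segment must have length >= 2")
    params = params or load_nn_params()
    dg = params.init
    for i in range(len(seg) - 1):
        d = seg[i : i + 2]
        if d not in params.stacks:
            raise KeyError(f"no stack parameter for {d}")
        dg += params.stacks[d]
    for end in (seg[0], seg[-1]):
        if end in "AU":
            dg += params.terminal_au
    return dg


@dataclass
class EnergyRecord:
    """Observed vs nearest-neighbor-predicted ΔG° for one site."""

    site: str
    dg_obs: float
    dg_pred: float
    temperature: float = ASSAY_TEMPERATURE_K
    gas_constant: float = GAS_CONSTANT_KCAL


def energy_comparison(
    guide: MirnaGuide,
    rel_kd: Mapping[str, float],
    params: NNParamTable | None = None,
    temperature: float = ASSAY_TEMPERATURE_K,
) -> pd.DataFrame:
    """Observed ΔG° from relative Kd versus nearest-neighbor prediction.

    Sites with a non-pairing A1 interaction (8mer, 7mer-A1, 6mer-A1) are
    excluded: their adenosine across from position 1 contributes binding
    without base pairing, so no in-solution duplex is equivalent.
    """
    from .site_grammar import parse_site_name

    params = params or load_nn_params()
    rows = []
    for name, kd in rel_kd.items():
        if name == "none":
            continue
        d = parse_site_name(name)
        if d.seed is not None and d.seed.a1:
            continue
        segments = []
        if d.threep is not None:
            segments.append(guide.segment(d.threep.start, d.threep.end))
        if d.seed is not None:
            segments.append(guide.segment(d.seed.start, d.seed.end))
        dg_pred = sum(delta_g_predicted_nn(s, params) for s in segments)
        if d.threep is not None and d.seed is not None:
            dg_pred -= params.init  # one duplex, one initiation
        rows.append(
            {
                "site": name,
                "category": d.category,
                "dg_obs": delta_g_observed(kd, temperature),
                "dg_pred": dg_pred,
            }
        )
    return pd.DataFrame(rows)
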