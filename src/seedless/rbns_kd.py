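"""Relative dissociation constants from AGO bind-n-seq read pools.

In an AGO-RBNS experiment an RNA library is equilibrated with purified
AGO-miRNA complex at several concentrations and the bound fraction is
sequenced.  For each site class the *enrichment* at a given concentration is
the proportion of bound reads assigned to the class divided by its
proportion in the input library.  The full enrichment profile across
concentrations is explained by an equilibrium occupancy model:

    occupancy of class j in sample i:  p_ij = a_i / (a_i + kappa_j)

where ``kappa_j`` is the dissociation constant of class j *relative to the
no-site background* (kappa of "none" is pinned to 1) and ``a_i`` is the
latent free-AGO concentration of sample i in the same units.  Bound reads
are multinomial with class frequencies

    g_ij = f_j p_ij / sum_k f_k p_ik

with f the input-library class frequencies.  ``fit_relative_kd`` maximizes
this multinomial likelihood over {log kappa_j, log a_i}; confidence
intervals come from a nonparametric bootstrap over reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .site_grammar import (
    ClassifyConfig,
    GuideMatcher,
    MirnaGuide,
    ThreePrimeSegment,
    parse_site_name,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RbnsCountTable",
    "EnrichmentProfile",
    "RelKdFit",
    "FitOptions",
    "FitError",
    "classify_pool",
    "enrichment",
    "fit_relative_kd",
    "bootstrap_ci",
    "stratify_by_flank",
]

NO_SITE_KEY = "none"


class FitError(RuntimeError):
    """Optimizer failure, carrying the scipy diagnostics."""

    def __init__(self, message, result=None):
        super().__init__(message)
        self.result = result


@dataclass
class RbnsCountTable:
    """Reads-per-site counts for the input sample and each bound sample.

    ``samples[0]`` is the input library; the remaining samples are bound
    fractions ordered by nominal AGO dilution.
    """

    sites: list[str]
    samples: list[str]
    counts: np.ndarray  # shape (n_sites, n_samples), integer

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sites), len(self.samples)):
            raise ValueError("counts shape does not match sites x samples")
        if NO_SITE_KEY not in self.sites:
            raise ValueError(f"table must contain a {NO_SITE_KEY!r} row")
        if self.counts[self.sites.index(NO_SITE_KEY), 0] <= 0:
            raise ValueError("no-site background absent from the input sample")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def depths(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def bound_samples(self) -> list[str]:
        return self.samples[1:]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sites, columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RbnsCountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    @classmethod
    def from_reads(
        cls,
        pools: Mapping[str, Sequence[str]],
        guide: MirnaGuide,
        config: ClassifyConfig | None = None,
        input_sample: str = "input",
        site_list: Optional[Sequence[str]] = None,
    ) -> "RbnsCountTable":
        """Classify raw read pools and tabulate counts per site class.

        ``pools`` maps sample name to its reads; it must contain
        ``input_sample``.  Bound pools typically repeat input molecules, so
        classification is cached per distinct sequence.

        When ``site_list`` is given, reads assigned to any other class are
        counted as no-site background.  Fitting a curated list against a
        pooled background is strongly preferred for Kd inference: leaving
        thousands of incidental low-count classes in the table lets their
        noisy kappa estimates soak up free AGO and bias the shared
        parameters.
        """
        if input_sample not in pools:
            raise ValueError(f"pools must contain the input sample {input_sample!r}")
        matcher = GuideMatcher(guide, config or ClassifyConfig())
        keep = set(site_list) if site_list is not None else None
        cache: dict[str, str] = {}

        def name_of(read: str) -> str:
            site = cache.get(read)
            if site is None:
                site = matcher.assign(read).name
                if keep is not None and site not in keep:
                    site = NO_SITE_KEY
                cache[read] = site
            return site

        samples = [input_sample] + [s for s in pools if s != input_sample]
        per_sample = []
        sites: dict[str, int] = {NO_SITE_KEY: 0}
        for s in samples:
            counts: dict[str, int] = {}
            for read in pools[s]:
                n = name_of(read)
                counts[n] = counts.get(n, 0) + 1
                if n not in sites:
                    sites[n] = len(sites)
            per_sample.append(counts)
        site_list = list(sites)
        mat = np.zeros((len(site_list), len(samples)), dtype=np.int64)
        for col, counts in enumerate(per_sample):
            for n, c in counts.items():
                mat[sites[n], col] = c
        return cls(site_list, samples, mat)


def classify_pool(
    reads: Iterable[str], guide: MirnaGuide, config: ClassifyConfig | None = None
) -> list[str]:
    """Site name for every read (cached per distinct sequence)."""
    matcher = GuideMatcher(guide, config or ClassifyConfig())
    cache: dict[str, str] = {}
    out = []
    for read in reads:
        site = cache.get(read)
        if site is None:
            site = cache[read] = matcher.assign(read).name
        out.append(site)
    return out


@dataclass
class EnrichmentProfile:
    """Per-site enrichment in each bound sample; omitted sites had zero
    input proportion at zero pseudocount."""

    enrichment: pd.DataFrame
    omitted: list[str] = field(default_factory=list)


def enrichment(table: RbnsCountTable, pseudocount: float = 0.0) -> EnrichmentProfile:
    """Bound-over-input proportion ratio per site and bound sample."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    depths = table.depths
    if depths[0] <= 0:
        raise ValueError("input sample has zero depth")
    n = table.counts.astype(float) + pseudocount
    props = n / n.sum(axis=0)
    keep = props[:, 0] > 0
    omitted = [s for s, k in zip(table.sites, keep) if not k]
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = props[keep, 1:] / props[keep, 0][:, None]
    df = pd.DataFrame(
        enr,
        index=[s for s, k in zip(table.sites, keep) if k],
        columns=table.bound_samples,
    )
    return EnrichmentProfile(df, omitted)


@dataclass
class FitOptions:
    """Options for the relative-Kd maximum-likelihood fit.

    min_reads: sites with fewer total bound reads are reported as
        not-determined (NaN) rather than fitted.
    input_pseudocount: added to input counts for the plug-in frequencies f.
    """

    min_reads: int = 50
    input_pseudocount: float = 1.0
    tol: float = 1e-8
    maxiter: int = 5000
    init_free_ago: float = 0.1
    # known relative dilution factors of the bound samples; when given, the
    # per-sample free-AGO scales are constrained to a_i = A * dilutions[i]
    # with a single latent stock scale A.  Without this tie the likelihood
    # has a soft ridge (shifting all a_i and the smallest kappas by the same
    # additive amount barely changes the bound frequencies), so tying the
    # samples to the dilution series is strongly recommended whenever the
    # series is known.
    dilutions: Optional[Sequence[float]] = None


@dataclass
class RelKdFit:
    """Point estimates (and, after bootstrap, 95% CIs) for relative Kd."""

    kappa: dict[str, float]
    free_ago: dict[str, float]
    loglik: float
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    not_determined: list[str] = field(default_factory=list)
    n_boot_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for site, k in self.kappa.items():
            lo, hi = self.ci95.get(site, (np.nan, np.nan))
            rows.append({"site": site, "kappa": k, "ci_lo": lo, "ci_hi": hi})
        for site in self.not_determined:
            rows.append(
                {"site": site, "kappa": np.nan, "ci_lo": np.nan, "ci_hi": np.nan}
            )
        return pd.DataFrame(rows)


def _prepare(table: RbnsCountTable, options: FitOptions):
    """Split a table into fitted sites and not-determined sites."""
    bound = table.counts[:, 1:]
    total_bound = bound.sum(axis=1)
    keep = (total_bound >= options.min_reads) | np.array(
        [s == NO_SITE_KEY for s in table.sites]
    )
    sites = [s for s, k in zip(table.sites, keep) if k]
    dropped = [s for s, k in zip(table.sites, keep) if not k]
    f = (table.counts[keep, 0] + options.input_pseudocount).astype(float)
    if (f <= 0).any():
        raise FitError("a fitted site has zero input frequency")
    f = f / f.sum()
    n = bound[keep].astype(float)
    return sites, dropped, f, n


def _negloglik_and_grad(x, f, n, j_none, n_sites, n_samp, log_dil=None):
    # x layout: [log kappa for all sites except none] + either
    # [log a per sample] or, with a dilution series, [log A_stock]
    lk = np.zeros(n_sites)
    mask = np.arange(n_sites) != j_none
    lk[mask] = x[: n_sites - 1]
    if log_dil is None:
        la = x[n_sites - 1 :]
    else:
        la = x[n_sites - 1] + log_dil
    kappa = np.exp(lk)
    a = np.exp(la)  # (n_samp,)
    p = a[:, None] / (a[:, None] + kappa[None, :])  # (n_samp, n_sites)
    fp = f[None, :] * p
    S = fp.sum(axis=1)  # (n_samp,)
    g = fp / S[:, None]
    ll = float((n.T * np.log(g)).sum())
    nt = n.T  # (n_samp, n_sites)
    Ni = nt.sum(axis=1)  # (n_samp,)
    q = 1.0 - p
    dlk = (-nt * q + (Ni / S)[:, None] * fp * q).sum(axis=0)  # (n_sites,)
    dla = (nt * q).sum(axis=1) - (Ni / S) * (fp * q).sum(axis=1)  # (n_samp,)
    if log_dil is not None:
        dla = np.array([dla.sum()])
    grad = np.concatenate([dlk[mask], dla])
    return -ll, -grad


def fit_relative_kd(
    table: RbnsCountTable,
    options: FitOptions | None = None,
    _init: Optional[np.ndarray] = None,
) -> RelKdFit:
    """Multinomial maximum-likelihood fit of relative Kd values.

    The no-site class is pinned at kappa = 1, which absorbs the joint scale
    freedom of (kappa, a): multiplying every kappa and every a by the same
    constant leaves all bound frequencies unchanged.
    """
    options = options or FitOptions()
    if len(table.samples) < 3:
        raise ValueError("need at least 2 bound samples")
    sites, dropped, f, n = _prepare(table, options)
    n_sites, n_samp = n.shape
    j_none = sites.index(NO_SITE_KEY)
    log_dil = None
    if options.dilutions is not None:
        if len(options.dilutions) != n_samp:
            raise ValueError("dilutions must match the bound samples")
        log_dil = np.log(np.asarray(options.dilutions, dtype=float))

    if _init is not None:
        x0 = _init
    else:
        # moment-style start: kappa ~ 1 / max enrichment; a flat
        depths = n.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            enr = np.where(f[:, None] > 0, (n / depths[None, :]) / f[:, None], np.nan)
        enr = np.where(enr > 0, enr, np.nan)
        enr[np.all(np.isnan(enr), axis=1), 0] = 1.0
        e = np.nanmax(enr, axis=1)
        e = np.where(np.isfinite(e) & (e > 0), e, 1.0)
        k0 = np.clip(1.0 / e, 1e-6, 1e3)
        a0 = (
            np.full(n_samp, np.log(options.init_free_ago))
            if log_dil is None
            else np.array([np.log(options.init_free_ago)])
        )
        x0 = np.concatenate([np.log(k0[np.arange(n_sites) != j_none]), a0])

    res = minimize(
        _negloglik_and_grad,
        x0,
        args=(f, n, j_none, n_sites, n_samp, log_dil),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": options.maxiter, "ftol": options.tol * 1e-4,
                 "gtol": 1e-9},
    )
    if not res.success and "ROUNDING" not in str(res.message).upper():
        raise FitError(f"relative-Kd fit did not converge: {res.message}", res)
    lk = np.zeros(n_sites)
    mask = np.arange(n_sites) != j_none
    lk[mask] = res.x[: n_sites - 1]
    kappa = {s: float(np.exp(v)) for s, v in zip(sites, lk)}
    kappa[NO_SITE_KEY] = 1.0
    if log_dil is None:
        la = res.x[n_sites - 1 :]
    else:
        la = res.x[n_sites - 1] + log_dil
    free_ago = {
        s: float(np.exp(v)) for s, v in zip(table.bound_samples, la)
    }
    return RelKdFit(
        kappa=kappa,
        free_ago=free_ago,
        loglik=float(-res.fun),
        not_determined=dropped,
    )


def loglik_at(
    table: RbnsCountTable,
    kappa: Mapping[str, float],
    free_ago: Sequence[float],
    options: FitOptions | None = None,
) -> float:
    """Multinomial log-likelihood of arbitrary parameters (model checks).

    Unlike the fit, this does not pin the no-site kappa, so it can
    demonstrate the joint scale freedom directly.
    """
    options = options or FitOptions()
    sites, _, f, n = _prepare(table, options)
    k = np.array([kappa.get(s, 1.0) for s in sites])
    a = np.asarray(free_ago, dtype=float)
    p = a[:, None] / (a[:, None] + k[None, :])
    fp = f[None, :] * p
    g = fp / fp.sum(axis=1, keepdims=True)
    return float((n.T * np.log(g)).sum())


def bootstrap_ci(
    table: RbnsCountTable,
    fit: RelKdFit,
    n_boot: int = 200,
    seed: int = 0,
    options: FitOptions | None = None,
) -> RelKdFit:
    """Percentile 95% CIs from a nonparametric bootstrap over reads.

    Each replicate resamples every sample's reads with replacement
    (multinomially over site classes at the original depth) and refits.
    Replicates whose fit fails are dropped with a warning; at least 90% must
    succeed.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    options = options or FitOptions()
    rng = np.random.default_rng(seed)
    depths = table.depths
    probs = table.counts / depths[None, :]
    sites_fit = [s for s in table.sites if s not in fit.not_determined]
    draws: dict[str, list[float]] = {s: [] for s in fit.kappa}
    failed = 0
    for _ in range(n_boot):
        counts = np.column_stack(
            [rng.multinomial(depths[i], probs[:, i]) for i in range(len(depths))]
        )
        try:
            boot_table = RbnsCountTable(list(table.sites), list(table.samples), counts)
            bfit = fit_relative_kd(boot_table, options)
        except (FitError, ValueError) as exc:
            failed += 1
            logger.warning("bootstrap replicate failed: %s", exc)
            continue
        for s in draws:
            if s in bfit.kappa:
                draws[s].append(bfit.kappa[s])
    if failed > 0.1 * n_boot:
        raise FitError(f"{failed}/{n_boot} bootstrap replicates failed")
    ci = {}
    for s, vals in draws.items():
        if vals:
            ci[s] = (
                float(np.percentile(vals, 2.5)),
                float(np.percentile(vals, 97.5)),
            )
    return RelKdFit(
        kappa=fit.kappa,
        free_ago=fit.free_ago,
        loglik=fit.loglik,
        ci95=ci,
        not_determined=fit.not_determined,
        n_boot_failed=failed,
    )


def stratify_by_flank(
    pools: Mapping[str, Sequence[str]],
    guide: MirnaGuide,
    base_site: ThreePrimeSegment | str,
    config: ClassifyConfig | None = None,
    input_sample: str = "input",
) -> tuple[RbnsCountTable, int]:
    """Split a 3'-only site class by the target base across from guide
    position start-1.

    A 3'-only site mX_Y whose flanking target base happens to complement
    guide position X-1 is, by maximality, classified as m(X-1)_Y; those
    reads are folded into the complementary-flank subclass here, so the four
    subclasses partition all reads carrying 3' pairing that covers [X, Y].
    Reads whose flank falls outside the read are excluded (and counted in
    the second return value).  All other reads form the "none" row, so the
    resulting table drops straight into :func:`fit_relative_kd`.
    """
    if isinstance(base_site, str):
        base_site = parse_site_name(base_site).threep
    config = config or ClassifyConfig()
    matcher = GuideMatcher(guide, config)
    if base_site.start - 1 < config.min_3p_start:
        raise ValueError(
            "flank stratification needs guide position start-1 inside the 3' region"
        )
    samples = [input_sample] + [s for s in pools if s != input_sample]
    subclasses = [f"{base_site.name}:flank={nt}" for nt in "ACGU"]
    sites = subclasses + [NO_SITE_KEY]
    mat = np.zeros((len(sites), len(samples)), dtype=np.int64)
    excluded = 0
    cache: dict[str, tuple[Optional[str], bool]] = {}

    def subclass_of(read: str) -> tuple[Optional[str], bool]:
        hit = cache.get(read)
        if hit is not None:
            return hit
        desc = matcher.assign(read)
        out: tuple[Optional[str], bool] = (None, False)
        if desc.category == "3p_only":
            seg = desc.threep
            if seg.end == base_site.end and seg.start <= base_site.start:
                a, b = desc.target_span
                flank_pos = b + seg.start - base_site.start + 1  # 1-based
                if flank_pos > len(read):
                    out = (None, True)
                else:
                    out = (f"{base_site.name}:flank={read[flank_pos - 1]}", False)
        cache[read] = out
        return out

    for col, s in enumerate(samples):
        for read in pools[s]:
            name, out_of_read = subclass_of(read)
            if out_of_read:
                excluded += 1
            elif name is not None:
                mat[sites.index(name), col] += 1
            else:
                mat[-1, col] += 1
    return RbnsCountTable(sites, samples, mat), excluded
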