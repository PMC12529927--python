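"""Massively parallel reporter assay: design, fold-changes, occupancy model.

The reporter library places each site architecture (canonical, 3'-only,
compound, or no-site control) into 20 sequence contexts.  After
transfection, counts per variant are converted to CPM, summed per site
across its contexts, and turned into fold-changes (miRNA versus mock)
normalized to the no-site controls.  Repression is then explained by a
two-parameter biochemical model

    fold-repression = 1 + b * N,   N = a_free / (a_free + kappa)

where N is fractional AGO-miR occupancy given the site's relative Kd, b is
the unit repression per unit occupancy, and a_free the free AGO-miR
concentration in relative-Kd units; (b, a_free) are fit globally.  The
predicted steady-state log2 fold-change of a site is -log2(1 + b N).

Slicing-prone variants are flagged by comparing each zero-offset compound
architecture with its positive-offset counterpart: because positive offsets
normally bind and repress *better*, significantly stronger repression of the
zero-offset version (Tukey's post-hoc test, Bonferroni-corrected) indicates
cleavage rather than occupancy-driven repression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .site_grammar import (
    MirnaGuide,
    SeedSegment,
    ThreePrimeSegment,
    parse_site_name,
    site_sequence,
)

__all__ = [
    "MpraDesign",
    "MiRnaDesignSpec",
    "FoldChangeTable",
    "OccupancyModelFit",
    "SlicingCall",
    "enumerate_seed_patterns",
    "build_design",
    "default_design_spec",
    "default_contexts",
    "fold_changes",
    "fit_occupancy_model",
    "predicted_log2fc",
    "detect_slicing",
    "fold_repression_from_log2",
    "relative_efficacy",
]


def enumerate_seed_patterns(
    min_len: int, max_len: int, region_end: int = 8
) -> list[SeedSegment]:
    """All contiguous seed windows with length in [min_len, max_len] within
    positions 1..region_end, ordered by (length, start).

    With (2, 8, 8) this enumerates the 28 patterns of seed complementarity
    used in the reporter design.
    """
    if not 1 <= min_len <= max_len <= region_end:
        raise ValueError("need 1 <= min_len <= max_len <= region_end")
    out = []
    for length in range(min_len, max_len + 1):
        for start in range(1, region_end - length + 2):
            out.append(SeedSegment(start, start + length - 1))
    return out


@dataclass
class MiRnaDesignSpec:
    """Site list for one miRNA in the reporter library.

    canonical architectures = 6 canonical classes x 5 upstream pads;
    compound block = len(compound_threeps) x 28 seed patterns x
    len(compound_offsets).
    """

    guide: MirnaGuide
    threep_registers: list[str]
    compound_threeps: list[str]
    compound_offsets: list[int]
    canonical_pads: list[str]
    no_site_seqs: list[str]
    seed_min: int = 2
    seed_max: int = 8

    CANONICAL_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer", "6mer-m8", "6mer-A1")

    def architectures(self) -> list[tuple[str, str, str, bool]]:
        """(arch_id, site_name, site_region_sequence, is_no_site) tuples."""
        out = []
        for cls in self.CANONICAL_CLASSES:
            core = site_sequence(self.guide, cls)
            for i, pad in enumerate(self.canonical_pads, 1):
                out.append((f"{cls}~pad{i}", cls, pad + core, False))
        for name in self.threep_registers:
            out.append((name, name, site_sequence(self.guide, name), False))
        seeds = enumerate_seed_patterns(self.seed_min, self.seed_max)
        for tp in self.compound_threeps:
            for off in self.compound_offsets:
                for seed in seeds:
                    name = f"{tp}|{off:+d}|m{seed.start}_{seed.end}"
                    out.append((name, name, site_sequence(self.guide, name), False))
        for i, seq in enumerate(self.no_site_seqs, 1):
            out.append((f"no_site~{i}", "none", seq, True))
        return out


@dataclass
class MpraDesign:
    """All (site, context) reporter variants plus per-category counts."""

    variants: pd.DataFrame  # mirna, arch_id, site_name, context, variant_id,
    #                         sequence, is_no_site
    category_counts: pd.DataFrame

    @property
    def n_variants(self) -> int:
        return len(self.variants)


def _categorize(site_name: str, is_no_site: bool) -> str:
    if is_no_site:
        return "no_site"
    d = parse_site_name(site_name)
    if d.category == "compound":
        return "compound"
    if d.category == "3p_only":
        return "3p_only"
    return "canonical"


def build_design(
    specs: Mapping[str, MiRnaDesignSpec],
    contexts: tuple[Sequence[str], Sequence[str]],
) -> MpraDesign:
    """Expand per-miRNA site lists into the full variant table.

    ``contexts`` is (upstream flanks, downstream flanks); context i pairs
    the i-th of each.  Duplicate variant sequences abort with the list of
    collisions.
    """
    ups, downs = contexts
    if len(ups) != len(downs):
        raise ValueError("need equal numbers of upstream and downstream flanks")
    rows = []
    for mirna, spec in specs.items():
        for arch_id, site_name, region, is_no_site in spec.architectures():
            for ctx in range(1, len(ups) + 1):
                seq = ups[ctx - 1] + region + downs[ctx - 1]
                rows.append(
                    {
                        "mirna": mirna,
                        "arch_id": arch_id,
                        "site_name": site_name,
                        "category": _categorize(site_name, is_no_site),
                        "context": ctx,
                        "variant_id": f"{mirna}:{arch_id}:ctx{ctx:02d}",
                        "sequence": seq,
                        "is_no_site": is_no_site,
                    }
                )
    df = pd.DataFrame(rows)
    dup = df[df.duplicated("sequence", keep=False)]
    if len(dup):
        collisions = dup.groupby("sequence")["variant_id"].apply(list).tolist()
        raise ValueError(f"duplicate variant sequences: {collisions[:5]}")
    counts = (
        df[df.context == 1]
        .groupby(["mirna", "category"])
        .size()
        .rename("n_sites")
        .reset_index()
    )
    return MpraDesign(df, counts)


def _deterministic_rna(seed: int, length: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=length))


def _clean_random_seq(guides, length: int, seed: int, max_run: int = 3):
    """Deterministic sequence with no complementary run > max_run to any of
    the given guides (rejection over a seeded stream)."""
    from .site_grammar import _maximal_common_runs, revcomp

    if isinstance(guides, MirnaGuide):
        guides = [guides]
    grcs = [revcomp(g.sequence) for g in guides]
    for attempt in range(10_000):
        cand = _deterministic_rna(seed * 10_000 + attempt, length)
        if all(not _maximal_common_runs(cand, grc, max_run + 1) for grc in grcs):
            return cand
    raise RuntimeError("could not build a clean sequence")


def default_design_spec(guide: MirnaGuide, flavor: str, seed: int = 0) -> MiRnaDesignSpec:
    """Default reporter site lists for the two library flavors.

    flavor="miR-155": 30 canonical + 20 3'-only + 168 compound + 5 no-site
    (223 sites); flavor="miR-124": 30 + 15 + 168 + 5 (218 sites).  The
    3'-only register grids and the synthetic pad/no-site sequences stand in
    for the original (supplementary) sequence sets; counts and structure are
    what the arithmetic checks exercise.
    """
    if flavor == "miR-155":
        registers = [
            f"m{x}_{y}" for x in range(9, 14) for y in range(20, 24)
        ]  # 5 x 4 = 20
        threeps = ["m13_20", "m13_22", "m11_23"]
        offsets = [0, 2]
    elif flavor == "miR-124":
        registers = [
            f"m{x}_{y}" for x in range(9, 14) for y in range(18, 21)
        ]  # 5 x 3 = 15
        threeps = ["m13_20", "m9_19", "m9_22"]
        offsets = [0, 3]
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    pads = [_clean_random_seq(guide, 8, seed * 100 + i) for i in range(5)]
    no_sites = [_clean_random_seq(guide, 30, seed * 100 + 50 + i) for i in range(5)]
    return MiRnaDesignSpec(
        guide=guide,
        threep_registers=registers,
        compound_threeps=threeps,
        compound_offsets=offsets,
        canonical_pads=pads,
        no_site_seqs=no_sites,
    )


def default_contexts(
    guides: Sequence[MirnaGuide], n: int = 20, flank_len: int = 50, seed: int = 1
):
    """n upstream and n downstream flanks free of complementary runs > 3 nt
    to any of the given guides."""
    ups = [_clean_random_seq(guides, flank_len, seed * 1000 + i) for i in range(n)]
    downs = [
        _clean_random_seq(guides, flank_len, seed * 1000 + 500 + i) for i in range(n)
    ]
    return ups, downs


# ------------------------------------------------------------ fold-changes


@dataclass
class FoldChangeTable:
    """Per-architecture log2 fold-changes (miRNA vs mock, no-site
    normalized), with per-replicate values and SEM."""

    table: pd.DataFrame          # index arch_id; log2fc, sem, flag columns
    replicates: pd.DataFrame     # arch_id x replicate log2fc values

    def log2fc(self, arch_id: str) -> float:
        return float(self.table.loc[arch_id, "log2fc"])


def fold_changes(
    counts: pd.DataFrame,
    design: MpraDesign,
    sample_pairs: Sequence[tuple[str, str]],
    mirna: Optional[str] = None,
) -> FoldChangeTable:
    """CPM-sum per site across contexts, then no-site-normalized fold-change.

    ``counts`` is variant_id x sample columns; ``sample_pairs`` lists
    (miRNA-transfected, mock-transfected) replicate column pairs.
    """
    var = design.variants
    if mirna is not None:
        var = var[var.mirna == mirna]
    counts = counts.loc[var.variant_id]
    cpm = counts / counts.sum(axis=0) * 1e6
    cpm = cpm.assign(arch_id=var.set_index("variant_id").arch_id)
    site_cpm = cpm.groupby("arch_id").sum()
    no_site_ids = var[var.is_no_site].arch_id.unique()

    rep_cols = {}
    flags = {}
    for r, (mir_col, mock_col) in enumerate(sample_pairs, 1):
        mock = site_cpm[mock_col]
        zero_mock = mock <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = site_cpm[mir_col] / mock
        norm = np.nanmedian(fc.loc[no_site_ids])
        fc = fc / norm
        fc[zero_mock] = np.nan
        rep_cols[f"rep{r}"] = np.log2(fc)
        for a in fc.index[zero_mock]:
            flags[a] = "zero_mock_cpm"
    reps = pd.DataFrame(rep_cols)
    table = pd.DataFrame(
        {
            "log2fc": reps.mean(axis=1),
            "sem": reps.std(axis=1, ddof=1) / np.sqrt(reps.shape[1]),
            "flag": [flags.get(a, "") for a in reps.index],
        }
    )
    meta = var[var.context == 1].set_index("arch_id")[
        ["mirna", "site_name", "category", "is_no_site"]
    ]
    table = table.join(meta)
    return FoldChangeTable(table, reps)


# --------------------------------------------------------- occupancy model


@dataclass
class OccupancyModelFit:
    """Globally fitted (b, a_free) and per-site fractional occupancy."""

    b: float
    a_free: float
    occupancy: dict[str, float]
    residual_ss: float

    def predicted_log2fc(self, kappa: float) -> float:
        n = self.a_free / (self.a_free + kappa)
        return -np.log2(1.0 + self.b * n)


def predicted_log2fc(b: float, a_free: float, kappa) -> np.ndarray:
    kappa = np.asarray(kappa, dtype=float)
    n = a_free / (a_free + kappa)
    return -np.log2(1.0 + b * n)


def fit_occupancy_model(
    log2fc: Mapping[str, float],
    kappa: Mapping[str, float],
    min_sites: int = 5,
    min_kappa_range: float = 100.0,
) -> OccupancyModelFit:
    """Fit (b, a_free) to site-level log2 fold-changes given relative Kd.

    Only sites present in both mappings enter the fit.  Requires enough
    sites spanning a wide enough kappa range for the two parameters to be
    identifiable.
    """
    common = [s for s in log2fc if s in kappa and np.isfinite(log2fc[s])]
    if len(common) < min_sites:
        raise ValueError(f"need >= {min_sites} sites with both FC and kappa")
    k = np.array([kappa[s] for s in common], dtype=float)
    y = np.array([log2fc[s] for s in common], dtype=float)
    if k.max() / k.min() < min_kappa_range:
        raise ValueError(
            f"kappa range {k.max() / k.min():.1f}-fold is degenerate "
            f"(need >= {min_kappa_range:.0f}-fold)"
        )

    def resid(x):
        return y - predicted_log2fc(np.exp(x[0]), np.exp(x[1]), k)

    best = None
    for b0 in (0.5, 3.0, 10.0):
        for a0 in (k.min(), np.sqrt(k.min() * k.max()), k.max()):
            res = least_squares(resid, np.array([np.log(b0), np.log(a0)]))
            if best is None or res.cost < best.cost:
                best = res
    b, a_free = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    occ = {s: float(a_free / (a_free + kappa[s])) for s in common}
    return OccupancyModelFit(b, a_free, occ, float(2 * best.cost))


def bootstrap_occupancy_ci(
    fc: FoldChangeTable,
    kappa: Mapping[str, float],
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[OccupancyModelFit, dict[str, tuple[float, float]]]:
    """Hierarchical bootstrap 95% CIs for the occupancy-model parameters.

    Each replicate draw resamples both the replicate columns (the dominant,
    common-mode noise: transfection and normalization shifts move every
    site together) and the sites.  With B replicates, resampling them with
    replacement underestimates the between-replicate variance by a factor
    (B-1)/B, so deviations from the point estimate are inflated by
    sqrt(B/(B-1)) before the percentile interval is taken.
    """
    reps = fc.replicates.loc[[s for s in fc.replicates.index if s in kappa]]
    sites = list(reps.index)
    point = fit_occupancy_model(reps.mean(axis=1).to_dict(), kappa)
    rng = np.random.default_rng(seed)
    inflate = np.sqrt(reps.shape[1] / max(1, reps.shape[1] - 1))
    draws = {"b": [], "a_free": []}
    for _ in range(n_boot):
        cols = rng.choice(reps.columns, size=reps.shape[1], replace=True)
        pick = rng.choice(sites, size=len(sites), replace=True)
        y = reps.loc[pick, cols].mean(axis=1)
        sub_y = {f"r{i}": v for i, v in enumerate(y)}
        sub_k = {f"r{i}": kappa[s] for i, s in enumerate(pick)}
        try:
            bfit = fit_occupancy_model(sub_y, sub_k)
        except ValueError:
            continue
        draws["b"].append(bfit.b)
        draws["a_free"].append(bfit.a_free)
    ci = {}
    for name, center in (("b", point.b), ("a_free", point.a_free)):
        vals = np.asarray(draws[name])
        if len(vals) < 2:
            ci[name] = (np.nan, np.nan)
            continue
        spread = center + (vals - center) * inflate
        ci[name] = (
            float(np.percentile(spread, 2.5)),
            float(np.percentile(spread, 97.5)),
        )
    return point, ci


# ---------------------------------------------------------------- slicing


@dataclass
class SlicingCall:
    """Zero-offset vs positive-offset comparison for one architecture."""

    zero_offset: str
    positive_offset: str
    mean_diff: float        # zero minus positive (negative = more repressed)
    p_adj: float
    flagged: bool


def detect_slicing(
    fc: FoldChangeTable,
    pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
) -> list[SlicingCall]:
    """Flag probable slicing substrates among zero/positive offset pairs.

    For each pair, replicate log2 fold-changes are compared by Tukey's
    honest-significant-difference test, Bonferroni-corrected across all
    tested pairs; a pair is flagged only when the zero-offset variant is
    the more repressed one.  Pairs with fewer than 3 replicates are skipped.
    """
    calls = []
    testable = []
    for zero, pos in pairs:
        z = fc.replicates.loc[zero].dropna().to_numpy()
        p = fc.replicates.loc[pos].dropna().to_numpy()
        if len(z) < 3 or len(p) < 3:
            warnings.warn(
                f"pair ({zero}, {pos}): <3 replicates, skipped", stacklevel=2
            )
            continue
        testable.append((zero, pos, z, p))
    n_tests = len(testable)
    for zero, pos, z, p in testable:
        if np.allclose(z, z[0]) and np.allclose(p, p[0]) and z[0] == p[0]:
            pval = 1.0
        else:
            pval = float(stats.tukey_hsd(z, p).pvalue[0, 1])
        p_adj = min(1.0, pval * n_tests)
        diff = float(z.mean() - p.mean())
        calls.append(
            SlicingCall(zero, pos, diff, p_adj, bool(diff < 0 and p_adj < alpha))
        )
    return calls


# ------------------------------------------------- reporter arithmetic


def fold_repression_from_log2(log2fc: float) -> float:
    """Fold-repression implied by a (negative) log2 fold-change."""
    return float(2.0 ** (-log2fc))


def relative_efficacy(log2fc_a: float, log2fc_b: float) -> float:
    """How many times more effective site arrangement a is than b, on the
    log2 fold-change scale."""
    if log2fc_b == 0:
        raise ZeroDivisionError("reference arrangement has zero fold-change")
    return float(log2fc_a / log2fc_b)
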