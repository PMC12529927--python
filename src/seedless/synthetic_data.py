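"""Generators for every input the pipeline consumes, with known truth.

Each generator draws data from the same forward model its downstream
analysis stage inverts, and returns a :class:`SimTruth` carrying the exact
parameters used, so parameter-recovery tests need no external data:

* ``gen_rbns_pools`` — bind-n-seq input/bound read pools from the
  equilibrium occupancy model over a half-random / half-programmed library;
* ``gen_mpra_counts`` — negative-binomial reporter counts under the
  occupancy-repression model 1 + b*N;
* ``gen_utrs`` — UTR sequences with planted sites and clean backgrounds;
* ``gen_binding_data`` — saturation binding curves and association time
  courses with Gaussian noise;
* ``gen_expression`` — logTPM matrices with planted cohort shifts.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .site_grammar import (
    ClassifyConfig,
    GuideMatcher,
    MirnaGuide,
    ThreePrimeSegment,
    parse_site_name,
    revcomp,
    site_sequence,
)

__all__ = [
    "SimTruth",
    "RbnsLibraryDesign",
    "gen_rbns_pools",
    "gen_mpra_counts",
    "gen_utrs",
    "gen_binding_data",
    "gen_expression",
    "random_rna",
]

GENERATOR_VERSION = "seedless-sim-1"


@dataclass
class SimTruth:
    """Ground truth serialized alongside every generated dataset."""

    seed: int
    params: dict
    version: str = GENERATOR_VERSION

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"seed": self.seed, "version": self.version, "params": self.params},
            indent=2,
            default=_jsonable,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def random_rna(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n uniform random RNA strings of the given length."""
    idx = rng.integers(0, 4, size=n * length)
    flat = np.frombuffer(b"ACGU", dtype=np.uint8)[idx].tobytes().decode()
    return [flat[i * length : (i + 1) * length] for i in range(n)]


# ------------------------------------------------------------------ RBNS


@dataclass(frozen=True)
class RbnsLibraryDesign:
    """Input-library composition for bind-n-seq simulation.

    Half the molecules are fully random; the other half are "programmed"
    with a fixed segment complementary to an 8-nt window of the guide 3'
    region, placed centrally in the random region, which boosts coverage of
    extended 3' matches.
    """

    random_len: int = 40
    programmed_fraction: float = 0.5
    programmed_segment: tuple[int, int] = (13, 20)

    def programmed_insert(self, guide: MirnaGuide) -> str:
        s, e = self.programmed_segment
        return revcomp(guide.segment(s, e))


def gen_rbns_pools(
    guide: MirnaGuide,
    kappa_map: Mapping[str, float],
    a_list: Sequence[float],
    depth: int,
    design: RbnsLibraryDesign | None = None,
    seed: int = 0,
    config: ClassifyConfig | None = None,
    flank_kappa: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> tuple[dict[str, list[str]], SimTruth]:
    """Simulate an input pool and one bound pool per free-AGO scale.

    Every input molecule is classified with the site grammar; a molecule
    assigned site j is carried into the bound pool at scale ``a`` with
    probability proportional to its equilibrium occupancy a/(a + kappa_j).
    Site classes absent from ``kappa_map`` fall back to the no-site kappa of
    1 (occurrences are tallied in the returned truth).  ``flank_kappa``
    optionally refines a 3'-only class by the identity of the target base
    across from guide position start-1.
    """
    if depth < 10_000:
        raise ValueError("depth must be >= 10^4 for a usable pool")
    design = design or RbnsLibraryDesign()
    config = config or ClassifyConfig()
    rng = np.random.default_rng(seed)
    n_prog = int(round(depth * design.programmed_fraction))
    reads = random_rna(rng, depth, design.random_len)
    insert = design.programmed_insert(guide)
    start = (design.random_len - len(insert)) // 2
    for i in range(n_prog):
        r = reads[i]
        reads[i] = r[:start] + insert + r[start + len(insert) :]
    rng.shuffle(reads)

    matcher = GuideMatcher(guide, config)
    fallback: dict[str, int] = {}
    kappas = np.empty(len(reads))
    assigned = []
    for i, read in enumerate(reads):
        desc = matcher.assign(read)
        name = desc.name
        assigned.append(name)
        k = kappa_map.get(name)
        if k is None:
            k = 1.0
            fallback[name] = fallback.get(name, 0) + 1
        if flank_kappa and name in flank_kappa and desc.category == "3p_only":
            b = desc.target_span[1]
            if b < len(read):
                k = flank_kappa[name].get(read[b], k)
        kappas[i] = k

    pools = {"input": reads}
    for i, a in enumerate(a_list):
        w = a / (a + kappas)
        w = w / w.sum()
        picks = rng.choice(len(reads), size=depth, replace=True, p=w)
        pools[f"bound_{i}"] = [reads[j] for j in picks]
    truth = SimTruth(
        seed=seed,
        params={
            "kappa": dict(kappa_map),
            "flank_kappa": {k: dict(v) for k, v in (flank_kappa or {}).items()},
            "free_ago": list(a_list),
            "depth": depth,
            "design": {
                "random_len": design.random_len,
                "programmed_fraction": design.programmed_fraction,
                "programmed_segment": list(design.programmed_segment),
            },
            "fallback_to_background": fallback,
            "assigned_input_sites": None,  # large; available via classify_pool
        },
    )
    return pools, truth


# ------------------------------------------------------------------ MPRA


def gen_mpra_counts(
    design: pd.DataFrame,
    kappa_map: Mapping[str, float],
    b: float,
    a_free: float,
    depth: int = 2_000_000,
    dispersion: float = 0.05,
    n_replicates: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Reporter counts under the occupancy-repression model.

    ``design`` needs columns variant_id, site_name, is_no_site.  Mock counts
    are proportional to a lognormal per-variant abundance; miRNA-transfected
    counts are divided by the predicted fold-repression 1 + b*N(kappa) and
    renormalized to the sample depth.  Counts are negative binomial with the
    given dispersion (variance mu + dispersion*mu^2); the replicate
    structure emulates two plates in each of two experiments.
    """
    rng = np.random.default_rng(seed)
    nv = len(design)
    abundance = rng.lognormal(mean=0.0, sigma=0.5, size=nv)
    abundance /= abundance.sum()
    kappa = np.array(
        [
            np.inf if row.is_no_site else kappa_map[row.site_name]
            for row in design.itertuples()
        ]
    )
    occ = np.where(np.isinf(kappa), 0.0, a_free / (a_free + kappa))
    repression = 1.0 + b * occ
    mir_rel = abundance / repression
    mir_rel /= mir_rel.sum()

    def draw(mean):
        if dispersion <= 0:
            return rng.poisson(mean)
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + mean))

    cols = {}
    for rep in range(1, n_replicates + 1):
        cols[f"mock_rep{rep}"] = draw(depth * abundance)
        cols[f"mir_rep{rep}"] = draw(depth * mir_rel)
    counts = pd.DataFrame(cols, index=design["variant_id"].to_numpy())
    truth = SimTruth(
        seed=seed,
        params={
            "b": b,
            "a_free": a_free,
            "depth": depth,
            "dispersion": dispersion,
            "n_replicates": n_replicates,
            "kappa": dict(kappa_map),
        },
    )
    return counts, truth


# ------------------------------------------------------------------ UTRs


def gen_utrs(
    guide: MirnaGuide,
    n: int,
    length: int = 1000,
    plants: Optional[Sequence[tuple[str, int]]] = None,
    seed: int = 0,
    config: ClassifyConfig | None = None,
    max_tries: int = 200,
) -> tuple[list[tuple[str, str]], SimTruth]:
    """UTR sequences with planted sites and site-free backgrounds.

    ``plants`` lists (site name, count-per-UTR) pairs; each planted site's
    sequence is synthesized from the guide and inserted at a random
    position.  Backgrounds (and the final planted sequence) are
    rejection-sampled so that no accidental instance of any planted
    category remains.  Returns (utr_id, sequence) pairs.
    """
    from .targetome_survey import UtrRecord, scan_utr

    rng = np.random.default_rng(seed)
    config = config or ClassifyConfig.survey()
    matcher = GuideMatcher(guide, config)
    plants = list(plants or [])
    expected_cat = {name: _expected_category(name, config) for name, _ in plants}
    for name, _ in plants:
        if len(site_sequence(guide, name)) > length:
            raise ValueError(f"site {name} longer than UTR ({length} nt)")

    utrs = []
    truth_spans = []
    for u in range(n):
        spans = None
        for _ in range(max_tries):
            seq = random_rna(rng, 1, length)[0]
            if not plants:
                # plain uniform background; accidental sites are the point
                # of background-rate studies, so no rejection
                spans = []
                break
            if scan_utr(UtrRecord("bg", seq), guide, config, matcher=matcher):
                continue  # background must be free of every survey category
            seq, spans = _place_plants(
                seq, guide, plants, rng, length, max_tries
            )
            if spans is None:
                continue
            anns = scan_utr(UtrRecord("q", seq), guide, config, matcher=matcher)
            want = sorted((expected_cat[name], s) for name, s, _ in spans)
            got = sorted((a.category, a.start) for a in anns)
            if want == got:
                break
            spans = None
        if spans is None:
            raise RuntimeError("could not build a UTR with clean planted sites")
        utr_id = f"utr{u:05d}"
        utrs.append((utr_id, seq))
        truth_spans.append({"utr": utr_id, "sites": spans})
    truth = SimTruth(
        seed=seed,
        params={
            "n": n,
            "length": length,
            "plants": [list(p) for p in plants],
            "spans": truth_spans,
        },
    )
    return utrs, truth


def _expected_category(name: str, config: ClassifyConfig) -> str:
    """Survey category a planted site should be recovered as."""
    d = parse_site_name(name)
    if d.threep is None:
        return d.category
    if d.seed is None:
        if d.threep.length < config.min_threep_len:
            raise ValueError(
                f"{name}: 3' run shorter than the survey minimum "
                f"({config.min_threep_len} nt), would not be recoverable"
            )
        return "3p_only"
    ms_lo, ms_hi = config.microseed_range or (3, 5)
    if ms_lo <= d.seed.length <= ms_hi:
        return "3p_microseed"
    raise ValueError(
        f"{name}: seed run of {d.seed.length} nt has no unambiguous survey "
        "category; plant a microseed-length compound or a canonical site"
    )


def _place_plants(seq, guide, plants, rng, length, max_tries):
    spans = []
    for name, count in plants:
        ins = site_sequence(guide, name)
        for _ in range(count):
            for _ in range(max_tries):
                pos = int(rng.integers(0, length - len(ins) + 1))
                if not _plant_collides(pos, len(ins), spans):
                    seq = seq[:pos] + ins + seq[pos + len(ins) :]
                    spans.append((name, pos + 1, pos + len(ins)))
                    break
            else:
                return seq, None
    return seq, spans


def _plant_collides(pos, ins_len, spans, margin=12):
    return any(
        pos + ins_len + margin >= s - margin and pos - margin <= e + margin
        for _, s, e in spans
    )


# ----------------------------------------------------------- binding data


def gen_binding_data(
    kind: str,
    params: Mapping[str, float],
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Forward-simulated binding measurements.

    kind="saturation": params kd (molar) and concentrations (list, molar);
    fraction bound follows the fractional saturation curve
    theta = c / (c + Kd), plus Gaussian noise, clipped to [0, 1] with clip
    events recorded.

    kind="kinetics": params kon (1/M/s), a_total (molar, >= 80 pM for the
    pseudo-first-order regime), ar_eq and times (s); signal follows
    AR(t) = AR_eq (1 - exp(-kon * A_T * t)).
    """
    rng = np.random.default_rng(seed)
    clipped = 0
    if kind == "saturation":
        conc = np.asarray(params["concentrations"], dtype=float)
        if (conc <= 0).any() or (np.diff(conc) <= 0).any():
            raise ValueError("concentrations must be positive and increasing")
        kd = float(params["kd"])
        rows = []
        for rep in range(replicates):
            theta = conc / (conc + kd)
            obs = theta + rng.normal(0, noise_sd, size=theta.shape)
            clipped += int(((obs < 0) | (obs > 1)).sum())
            obs = np.clip(obs, 0.0, 1.0)
            rows.append(
                pd.DataFrame(
                    {"replicate": rep + 1, "ago_total": conc, "theta": obs}
                )
            )
        df = pd.concat(rows, ignore_index=True)
    elif kind == "kinetics":
        a_total = float(params["a_total"])
        if a_total < 80e-12:
            import warnings

            warnings.warn(
                "a_total below 80 pM: pseudo-first-order assumption is dubious",
                stacklevel=2,
            )
        times = np.asarray(params["times"], dtype=float)
        kon = float(params["kon"])
        ar_eq = float(params.get("ar_eq", 1.0))
        rows = []
        for rep in range(replicates):
            ar = ar_eq * (1.0 - np.exp(-kon * a_total * times))
            obs = ar + rng.normal(0, noise_sd * ar_eq, size=ar.shape)
            rows.append(
                pd.DataFrame({"replicate": rep + 1, "time_s": times, "ar": obs})
            )
        df = pd.concat(rows, ignore_index=True)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    truth = SimTruth(
        seed=seed,
        params={
            "kind": kind,
            **{k: v for k, v in params.items()},
            "noise_sd": noise_sd,
            "replicates": replicates,
            "clipped_points": clipped,
        },
    )
    return df, truth


# ------------------------------------------------------------ expression


def gen_expression(
    n_genes: int,
    n_mirnas: int,
    shift_map: Mapping[tuple[str, str], float] | None = None,
    cohorts: Mapping[str, Sequence[int]] | None = None,
    noise: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """logTPM matrix (genes x miRNA-transfection samples) with planted
    repression.

    ``cohorts`` maps cohort name to gene indices; ``shift_map`` maps
    (miRNA sample name, cohort name) to a log2 fold-change applied to those
    genes in that sample only (converted internally to log10 units).
    ``noise`` is the per-sample Gaussian sd in log10 units.
    """
    rng = np.random.default_rng(seed)
    samples = [f"miR_{i + 1}" for i in range(n_mirnas)]
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    base = rng.normal(1.5, 0.5, size=n_genes)
    mat = base[:, None] + rng.normal(0, noise, size=(n_genes, n_mirnas))
    log2_to_log10 = np.log10(2.0)
    for (sample, cohort), shift in (shift_map or {}).items():
        j = samples.index(sample)
        idx = np.asarray((cohorts or {})[cohort], dtype=int)
        mat[idx, j] += shift * log2_to_log10
    df = pd.DataFrame(mat, index=genes, columns=samples)
    truth = SimTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_mirnas": n_mirnas,
            "noise": noise,
            "shifts": {f"{s}|{c}": v for (s, c), v in (shift_map or {}).items()},
            "cohorts": {k: list(map(int, v)) for k, v in (cohorts or {}).items()},
        },
    )
    return df, truth
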