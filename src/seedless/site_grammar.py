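"""Target-site grammar for miRNA guides.

Defines the taxonomy of miRNA target sites and the machinery to find them in
arbitrary RNA sequences.  A site is described by up to three elements:

* **seed pairing** — Watson–Crick complementarity to guide nucleotides 2–7
  (optionally extended to nucleotide 8 and/or an adenosine across from
  nucleotide 1), which produces the canonical classes
  8mer > 7mer-m8 > 7mer-A1 > 6mer > 6mer-m8 > 6mer-A1;
* **3' pairing** — a contiguous complementary run to the guide 3' region
  (nucleotide 9 onwards), written ``mX_Y`` for pairing to guide positions
  X through Y inclusive;
* **offset** — for compound sites combining both elements, the number of
  target nucleotides bridging the two complementary segments minus the
  guide-coordinate distance between them, so that a site is serialized as
  e.g. ``m13_20|+2|m2_7``.

All positions are 1-based: guide positions from the guide 5' end, target
spans inclusive on the scanned sequence.  Complementarity is strict
Watson–Crick (no G:U) unless a config explicitly enables wobble.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "MirnaGuide",
    "SeedSegment",
    "ThreePrimeSegment",
    "SiteDescriptor",
    "ClassifyConfig",
    "GuideMatcher",
    "revcomp",
    "compute_offset",
    "classify_canonical",
    "find_threep_matches",
    "assign_site",
    "parse_site_name",
    "format_site_name",
    "site_sequence",
    "CANONICAL_RANKING",
]

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_TO_RNA = str.maketrans("Tt", "Uu")
_VALID_RNA = frozenset("ACGU")

# Wobble-aware pair test: maps (guide base, target base) -> paired?
_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = _WC_PAIRS | {("G", "U"), ("U", "G")}


def normalize_rna(seq: str) -> str:
    """Uppercase, map T->U, and validate the alphabet."""
    s = seq.strip().upper().translate(_DNA_TO_RNA)
    bad = set(s) - _VALID_RNA
    if bad:
        raise ValueError(f"invalid RNA characters: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string (Watson-Crick, 5'->3')."""
    return seq.translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MirnaGuide:
    """A miRNA guide sequence with 1-based position accessors.

    The seed window is positions 2-7, the subseed 2-5, and the 3' region
    runs from a configurable start (default 9) to the guide 3' end.
    """

    name: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if not 18 <= len(self.sequence) <= 26:
            raise ValueError(
                f"guide {self.name!r}: length {len(self.sequence)} outside 18-26 nt"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def segment(self, start: int, end: int) -> str:
        """Guide subsequence for 1-based inclusive positions [start, end]."""
        if not 1 <= start <= end <= self.length:
            raise ValueError(f"positions {start}-{end} outside guide 1-{self.length}")
        return self.sequence[start - 1 : end]

    def base(self, pos: int) -> str:
        return self.segment(pos, pos)


@dataclass(frozen=True)
class SeedSegment:
    """Contiguous complementarity to guide positions [start, end] within 1-8.

    ``a1`` marks an adenosine on the target across from guide position 1
    (a non-pairing interaction recognized by AGO, not a Watson-Crick pair).
    """

    start: int
    end: int
    a1: bool = False

    def __post_init__(self):
        if not 1 <= self.start <= self.end <= 8:
            raise ValueError(f"seed segment {self.start}-{self.end} outside 1-8")
        if self.a1 and self.start < 2:
            raise ValueError("a1 requires seed pairing to start at position >= 2")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ThreePrimeSegment:
    """Contiguous complementarity to guide 3'-region positions [start, end]."""

    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"3' segment start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def name(self) -> str:
        return f"m{self.start}_{self.end}"


CANONICAL_RANKING = ("8mer", "7mer-m8", "7mer-A1", "6mer", "6mer-m8", "6mer-A1")

_CANONICAL_SEEDS = {
    "8mer": SeedSegment(2, 8, a1=True),
    "7mer-m8": SeedSegment(2, 8),
    "7mer-A1": SeedSegment(2, 7, a1=True),
    "6mer": SeedSegment(2, 7),
    "6mer-m8": SeedSegment(3, 8),
    "6mer-A1": SeedSegment(2, 6, a1=True),
}


@dataclass(frozen=True)
class SiteDescriptor:
    """One classified site: canonical class, 3' register, offset, location."""

    category: str
    threep: Optional[ThreePrimeSegment] = None
    seed: Optional[SeedSegment] = None
    offset: Optional[int] = None
    target_span: Optional[tuple[int, int]] = None
    ambiguous: bool = False

    @property
    def name(self) -> str:
        return format_site_name(self)

    def __str__(self) -> str:
        return self.name


NO_SITE = SiteDescriptor(category="none")


def compute_offset(seed_end: int, threep_start: int, bridge_len: int) -> int:
    """Offset between a 3' segment and a downstream seed segment.

    ``bridge_len`` counts the target nucleotides bridging the two
    complementary segments.  The offset is that bridge minus the
    guide-coordinate distance between the 3'-segment start and the seed-segment
    end; e.g. an m13_20 segment bridged by 8 nt to an m2_7 seed match gives
    8 - (13 - 7) = +2.  Positive offsets bulge the target, negative offsets
    bulge the guide.
    """
    if threep_start <= seed_end:
        raise ValueError(
            f"threep_start ({threep_start}) must exceed seed_end ({seed_end})"
        )
    if bridge_len < 0:
        raise ValueError(f"bridge_len must be >= 0, got {bridge_len}")
    return bridge_len - (threep_start - seed_end)


@dataclass(frozen=True)
class ClassifyConfig:
    """Tunable rules for read/window classification.

    Two presets mirror the two stages of the analysis: ``rbns`` (read
    assignment for bind-n-seq pools) and ``survey`` (endogenous 3'-UTR
    scanning).  They differ in the minimum 3'-run length, the maximum
    contiguous seed run still counted as "3'-only", the compound offset
    window, and whether offset-6mer canonical classes are reported.
    """

    min_3p_start: int = 9
    min_threep_len: int = 8
    # a 3'-only call tolerates contiguous seed runs up to this length
    max_seed_run_for_3p_only: int = 1
    offset_window: tuple[int, int] = (-8, 16)
    # survey mode: seed runs of microseed_range at a valid offset make a
    # 3'+microseed compound; longer runs revert to canonical counting
    microseed_range: Optional[tuple[int, int]] = None
    include_offset_6mers: bool = True
    allow_wobble: bool = False

    @classmethod
    def rbns(cls, **kw) -> "ClassifyConfig":
        return cls(**kw)

    @classmethod
    def survey(cls, **kw) -> "ClassifyConfig":
        defaults = dict(
            min_threep_len=10,
            max_seed_run_for_3p_only=2,
            offset_window=(-4, 6),
            microseed_range=(3, 5),
            include_offset_6mers=False,
        )
        defaults.update(kw)
        return cls(**defaults)


def _maximal_common_runs(a: str, b: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal common substrings of ``a`` and ``b`` with length >= min_len.

    Returns (a_start, b_start, length) triples, 0-based.  Diagonal scan;
    intended for short strings (the seed region) and as a reference
    implementation for the k-mer fast path used on the 3' region.
    """
    runs = []
    la, lb = len(a), len(b)
    for d in range(-(lb - 1), la):
        j0 = max(0, -d)
        j1 = min(lb, la - d)
        run = 0
        for j in range(j0, j1):
            if a[j + d] == b[j]:
                run += 1
            else:
                if run >= min_len:
                    runs.append((j + d - run, j - run, run))
                run = 0
        if run >= min_len:
            runs.append((j1 + d - run, j1 - run, run))
    return runs


class GuideMatcher:
    """Precomputed search tables for one (guide, config) pair.

    Caches the canonical site strings, the reverse complement of the guide
    3' region with a k-mer position index, and the reverse complement of the
    seed region, so that per-read classification is a handful of string
    searches.
    """

    def __init__(self, guide: MirnaGuide, config: ClassifyConfig | None = None):
        self.guide = guide
        self.config = config or ClassifyConfig()
        if self.config.allow_wobble:
            raise NotImplementedError(
                "wobble-tolerant matching is exposed for exploration but the "
                "site definitions used throughout are strict Watson-Crick"
            )
        g = guide.sequence
        # canonical patterns, strongest first; searching in rank order is
        # sufficient because every stronger class string contains the weaker
        core6 = revcomp(g[1:7])   # complements g2..g7
        core7 = revcomp(g[1:8])   # complements g2..g8
        self._canonical_patterns = [
            ("8mer", core7 + "A"),
            ("7mer-m8", core7),
            ("7mer-A1", core6 + "A"),
            ("6mer", core6),
            ("6mer-m8", revcomp(g[2:8])),
            ("6mer-A1", revcomp(g[1:6]) + "A"),
        ]
        if not self.config.include_offset_6mers:
            self._canonical_patterns = [
                (c, p) for c, p in self._canonical_patterns
                if c not in ("6mer-m8", "6mer-A1")
            ]
        p0 = self.config.min_3p_start
        self._g3rc = revcomp(g[p0 - 1 :])  # index j pairs guide position L - j
        self._seed8rc = revcomp(g[:8])     # index j pairs guide position 8 - j
        k = self.config.min_threep_len
        self._k = k
        self._kmer_pos: dict[str, list[int]] = defaultdict(list)
        for j in range(len(self._g3rc) - k + 1):
            self._kmer_pos[self._g3rc[j : j + k]].append(j)

    # ---- 3' matches ------------------------------------------------------

    def threep_matches(
        self, read: str, min_len: int | None = None
    ) -> list[tuple[ThreePrimeSegment, tuple[int, int]]]:
        """Maximal 3'-region complementary runs, as (segment, 1-based span)."""
        k = self._k if min_len is None else min_len
        if k < 4:
            raise ValueError("min_len must be >= 4")
        g3rc = self._g3rc
        if k == self._k:
            seeds = self._kmer_seeds(read)
        else:  # non-default length: fall back to the generic scan
            seeds = [(i, j) for i, j, L in _maximal_common_runs(read, g3rc, k)]
        L = self.guide.length
        found: dict[tuple[int, int], tuple[int, int, int]] = {}
        for i, j in seeds:
            # extend to the maximal run containing this seed match
            i0, j0 = i, j
            while i0 > 0 and j0 > 0 and read[i0 - 1] == g3rc[j0 - 1]:
                i0 -= 1
                j0 -= 1
            i1, j1 = i, j
            n, m = len(read), len(g3rc)
            while i1 + 1 < n and j1 + 1 < m and read[i1 + 1] == g3rc[j1 + 1]:
                i1 += 1
                j1 += 1
            length = i1 - i0 + 1
            if length >= k:
                found[(i0 - j0, i0)] = (i0, j0, length)
        out = []
        for i0, j0, length in found.values():
            ts = L - j0 - length + 1
            te = L - j0
            out.append(
                (ThreePrimeSegment(ts, te), (i0 + 1, i0 + length))
            )
        # keep a non-redundant set: longest first, drop runs overlapping an
        # already-kept run on the read (ties break left-most)
        out.sort(key=lambda x: (-(x[1][1] - x[1][0]), x[1][0], x[0].start))
        kept: list[tuple[ThreePrimeSegment, tuple[int, int]]] = []
        for seg, span in out:
            if all(span[1] < s[0] or span[0] > s[1] for _, s in kept):
                kept.append((seg, span))
        kept.sort(key=lambda x: x[1][0])
        return kept

    def _kmer_seeds(self, read: str) -> list[tuple[int, int]]:
        seeds = []
        k = self._k
        for kmer, positions in self._kmer_pos.items():
            start = read.find(kmer)
            while start != -1:
                for j in positions:
                    seeds.append((start, j))
                start = read.find(kmer, start + 1)
        return seeds

    # ---- seed runs -------------------------------------------------------

    def seed_runs(
        self, read: str, region_start: int, min_run: int
    ) -> list[tuple[SeedSegment, tuple[int, int]]]:
        """Maximal seed-region (g1-8) runs within read[region_start:] (0-based).

        Returns (segment, 1-based read span) with spans in full-read
        coordinates.
        """
        region = read[region_start:]
        out = []
        for ri, j0, length in _maximal_common_runs(region, self._seed8rc, min_run):
            se = 8 - j0
            ss = se - length + 1
            start = region_start + ri + 1
            out.append((SeedSegment(ss, se), (start, start + length - 1)))
        return out

    # ---- canonical -------------------------------------------------------

    def canonical(self, read: str) -> Optional[SiteDescriptor]:
        """Highest-ranked canonical site in the read, or None."""
        for category, pattern in self._canonical_patterns:
            i = read.find(pattern)
            if i != -1:
                return SiteDescriptor(
                    category=category,
                    seed=_CANONICAL_SEEDS[category],
                    target_span=(i + 1, i + len(pattern)),
                )
        return None

    def canonical_all(self, read: str) -> list[SiteDescriptor]:
        """Every canonical occurrence, resolved per position by rank.

        A window is reported once, under its strongest class; used by the
        UTR survey, which annotates every site rather than one per read.
        """
        claimed: list[tuple[int, int]] = []
        out = []
        for category, pattern in self._canonical_patterns:
            i = read.find(pattern)
            while i != -1:
                span = (i + 1, i + len(pattern))
                core = (span[0], span[1])
                if not any(s <= core[1] and core[0] <= e for s, e in claimed):
                    out.append(
                        SiteDescriptor(
                            category=category,
                            seed=_CANONICAL_SEEDS[category],
                            target_span=span,
                        )
                    )
                    claimed.append(core)
                i = read.find(pattern, i + 1)
        out.sort(key=lambda d: d.target_span)
        return out

    # ---- full assignment -------------------------------------------------

    def assign(self, read: str) -> SiteDescriptor:
        """Single best site for a read (bind-n-seq read assignment)."""
        cfg = self.config
        lo, hi = cfg.offset_window
        candidates: list[tuple[tuple, SiteDescriptor]] = []
        for seg, span in self.threep_matches(read):
            best_seed = self._best_seed(read, seg, span)
            if best_seed is not None:
                seed, sspan, offset = best_seed
                desc = SiteDescriptor(
                    category="compound",
                    threep=seg,
                    seed=seed,
                    offset=offset,
                    target_span=(span[0], sspan[1]),
                )
                # compound beats 3'-only beats canonical; among compounds the
                # longer 3' register wins, then longer seed, then left-most
                key = (0, -seg.length, -seed.length, span[0])
            else:
                desc = SiteDescriptor(
                    category="3p_only", threep=seg, target_span=span
                )
                key = (1, -seg.length, 0, span[0])
            candidates.append((key, desc))
        canon = self.canonical(read)
        if canon is not None:
            rank = CANONICAL_RANKING.index(canon.category)
            candidates.append(((2, rank, 0, canon.target_span[0]), canon))
        if not candidates:
            return NO_SITE
        candidates.sort(key=lambda x: x[0])
        best_key, best = candidates[0]
        # two distinct sites tied at the head of the precedence order
        if len(candidates) > 1 and candidates[1][0][:3] == best_key[:3] \
                and candidates[1][1].name != best.name:
            best = replace(best, ambiguous=True)
        return best

    def _best_seed(self, read, seg, span):
        """Best downstream seed run for one 3' match, or None."""
        cfg = self.config
        lo, hi = cfg.offset_window
        min_run = cfg.max_seed_run_for_3p_only + 1
        if cfg.microseed_range is not None:
            min_run = min(min_run, cfg.microseed_range[0])
        hits = []
        for seed, sspan in self.seed_runs(read, span[1], min_run):
            bridge = sspan[0] - span[1] - 1
            if bridge < 0:
                continue
            offset = compute_offset(seed.end, seg.start, bridge)
            if lo <= offset <= hi:
                hits.append((seed, sspan, offset))
        if not hits:
            return None
        # longest run, then smallest |offset|, then left-most on the read,
        # then the run ending nearest guide position 8
        hits.sort(key=lambda h: (-h[0].length, abs(h[2]), h[1][0], -h[0].end))
        return hits[0]


def classify_canonical(window: str, guide: MirnaGuide) -> SiteDescriptor:
    """Highest-ranked canonical site class present in a target window."""
    window = normalize_rna(window)
    desc = GuideMatcher(guide).canonical(window)
    return desc if desc is not None else NO_SITE


def find_threep_matches(
    read: str, guide: MirnaGuide, min_len: int, min_3p_start: int = 9
) -> list[tuple[ThreePrimeSegment, tuple[int, int]]]:
    """All maximal 3'-region complementary runs of length >= min_len."""
    read = normalize_rna(read)
    cfg = ClassifyConfig(min_3p_start=min_3p_start, min_threep_len=min_len)
    return GuideMatcher(guide, cfg).threep_matches(read)


def assign_site(
    read: str,
    guide: MirnaGuide,
    config: ClassifyConfig | GuideMatcher | None = None,
) -> SiteDescriptor:
    """Assign exactly one site descriptor to a read.

    Accepts a prebuilt :class:`GuideMatcher` to amortize table construction
    over large read pools.
    """
    read = normalize_rna(read)
    if isinstance(config, GuideMatcher):
        return config.assign(read)
    return GuideMatcher(guide, config).assign(read)


# ---- serialization -------------------------------------------------------

_THREEP_RE = re.compile(r"^m(\d+)_(\d+)$")
_COMPOUND_RE = re.compile(r"^m(\d+)_(\d+)\|([+-]\d+)\|m(\d+)_(\d+)$")
_CANONICAL_NAMES = frozenset(CANONICAL_RANKING) | {"none"}


def format_site_name(site: SiteDescriptor) -> str:
    if site.category == "compound" or (
        site.category == "3p_microseed" and site.seed is not None
    ):
        return (
            f"{site.threep.name}|{site.offset:+d}|m{site.seed.start}_{site.seed.end}"
        )
    if site.category in ("3p_only", "3p_microseed"):
        return site.threep.name
    return site.category


def parse_site_name(name: str) -> SiteDescriptor:
    """Inverse of :func:`format_site_name`; positions only, no target span."""
    name = name.strip()
    if name in _CANONICAL_NAMES:
        if name == "none":
            return NO_SITE
        return SiteDescriptor(category=name, seed=_CANONICAL_SEEDS[name])
    m = _THREEP_RE.match(name)
    if m:
        return SiteDescriptor(
            category="3p_only",
            threep=ThreePrimeSegment(int(m.group(1)), int(m.group(2))),
        )
    m = _COMPOUND_RE.match(name)
    if m:
        return SiteDescriptor(
            category="compound",
            threep=ThreePrimeSegment(int(m.group(1)), int(m.group(2))),
            offset=int(m.group(3)),
            seed=SeedSegment(int(m.group(4)), int(m.group(5))),
        )
    token = name.split("|")[0] if "|" in name else name
    raise ValueError(f"malformed site name {name!r}: cannot parse token {token!r}")


# ---- target-sequence synthesis -------------------------------------------


def site_sequence(guide: MirnaGuide, site: SiteDescriptor | str) -> str:
    """Build the target subsequence realizing a site for this guide.

    Canonical classes map to their defining pattern; ``mX_Y`` to the reverse
    complement of guide positions X..Y; compound sites to
    revcomp(3' segment) + bridge + revcomp(seed segment), with the bridge
    filled with bases copied from the guide itself (a base never Watson-Crick
    pairs with an identical base) so the filler cannot extend either segment.
    """
    if isinstance(site, str):
        site = parse_site_name(site)
    if site.category in _CANONICAL_NAMES and site.category != "none":
        matcher = GuideMatcher(guide)
        return dict(matcher._canonical_patterns)[site.category]
    if site.category == "none":
        raise ValueError("cannot synthesize a sequence for the no-site class")
    threep_seq = revcomp(guide.segment(site.threep.start, site.threep.end))
    if site.category == "3p_only" or site.seed is None:
        return threep_seq
    bridge_len = site.offset + (site.threep.start - site.seed.end)
    if bridge_len < 0:
        raise ValueError(
            f"offset {site.offset} implies a negative bridge for {site.name}"
        )
    bridge = _fill_bridge(guide, site.threep.start, site.seed.end, bridge_len)
    seed_seq = revcomp(guide.segment(site.seed.start, site.seed.end))
    if site.seed.a1:
        seed_seq += "A"
    return threep_seq + bridge + seed_seq


def _fill_bridge(guide: MirnaGuide, threep_start: int, seed_end: int, n: int) -> str:
    """Deterministic non-pairing filler between a 3' segment and a seed match.

    Each base is chosen so the bridge neither extends the flanking segments
    (no pair to guide positions threep_start-1 or seed_end+1 at the junctions)
    nor seeds a >=2-nt complementary run against the guide seed region.
    """
    g = guide.sequence
    comp = dict(zip("ACGU", "UGCA"))
    # guide seed positions paired by each base
    paired_by = {
        c: {p for p in range(1, 9) if comp[c] == g[p - 1]} for c in "ACGU"
    }
    out = []
    prev_paired: set[int] = set()
    for i in range(n):
        forbidden = {p - 1 for p in prev_paired if p > 1}
        for c in "AGCU":
            if i == 0 and comp[c] == g[threep_start - 2]:
                continue
            if i == n - 1 and seed_end < 8 and comp[c] == g[seed_end]:
                continue
            if paired_by[c] & forbidden:
                continue
            break
        out.append(c)
        prev_paired = paired_by[c]
    return "".join(out)
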