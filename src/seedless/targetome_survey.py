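"""Endogenous 3'-UTR survey of canonical and 3'-region target sites.

Scans 3'-UTR sequences (sense strand only) for each miRNA's sites using the
same grammar as bind-n-seq read assignment, under the survey rules:

* canonical sites: 6mer, 7mer-A1, 7mer-m8, 8mer (offset 6mers excluded as
  only marginally effective); supplementary 3' pairing is recorded as a
  boolean, not a separate class;
* 3'-only sites: >= 10 nt of contiguous 3' complementarity with less than
  3 nt of contiguous seed matching at an offset in [-4, +6];
* 3'+microseed sites: >= 10 nt of contiguous 3' complementarity plus a
  3-5-nt contiguous seed run at an offset in [-4, +6].

Because a k-nt site occurs by chance every 4^k nucleotides, longer site
classes are correspondingly rarer; ``chance_ratio`` gives the expected
relative frequency (e.g. 4^6 / 4^10 = 1/256 for 6mer versus 10-nt sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .site_grammar import (
    ClassifyConfig,
    GuideMatcher,
    MirnaGuide,
    SiteDescriptor,
    normalize_rna,
)

__all__ = [
    "UtrRecord",
    "SiteAnnotation",
    "SurveySummary",
    "scan_utr",
    "scan_many",
    "chance_ratio",
    "summarize",
    "SURVEY_CATEGORIES",
]

SURVEY_CATEGORIES = ("6mer", "7mer-A1", "7mer-m8", "8mer", "3p_only", "3p_microseed")

# annotation priority within an overlapping cluster: compound rules first,
# then canonical by rank
_PRIORITY = {
    "3p_microseed": 0,
    "3p_only": 1,
    "8mer": 2,
    "7mer-m8": 3,
    "7mer-A1": 4,
    "6mer": 5,
}


@dataclass(frozen=True)
class UtrRecord:
    """One 3'-UTR sequence (DNA accepted, normalized to RNA)."""

    transcript_id: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if not self.sequence:
            raise ValueError("empty UTR sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """A located site in one UTR for one miRNA."""

    mirna: str
    utr_id: str
    start: int   # 1-based inclusive
    end: int
    category: str
    supplementary_3p: bool = False
    ambiguous: bool = False


def scan_utr(
    utr: UtrRecord,
    guide: MirnaGuide,
    rules: ClassifyConfig | None = None,
    matcher: GuideMatcher | None = None,
) -> list[SiteAnnotation]:
    """Every non-overlapping site of one miRNA in one UTR, left-most first.

    Overlap resolution is greedy: overlapping candidate clusters are
    resolved by category priority (3'-region classes, then canonical rank),
    then left-most, then longest; losing candidates that still do not
    overlap a kept site are retained, and sites whose identity was
    contested are marked ambiguous rather than dropped.
    """
    rules = rules or ClassifyConfig.survey()
    if matcher is None:
        matcher = GuideMatcher(guide, rules)
    seq = utr.sequence
    candidates: list[tuple[tuple, SiteAnnotation]] = []

    threep_spans = matcher.threep_matches(seq)
    for desc in matcher.canonical_all(seq):
        a, b = desc.target_span
        supp = _has_supplementary(threep_spans, a, rules)
        candidates.append(
            (
                (_PRIORITY[desc.category], a, -(b - a)),
                SiteAnnotation(
                    guide.name, utr.transcript_id, a, b, desc.category,
                    supplementary_3p=supp,
                ),
            )
        )
    lo, hi = rules.offset_window
    ms_lo, ms_hi = rules.microseed_range or (3, 5)
    for seg, span in threep_spans:
        best = matcher._best_seed(seq, seg, span)
        if best is None:
            run_len = 0
        else:
            run_len = best[0].length
        if run_len > rules.max_seed_run_for_3p_only and run_len <= ms_hi:
            ann = SiteAnnotation(
                guide.name, utr.transcript_id, span[0], best[1][1], "3p_microseed"
            )
            candidates.append(((_PRIORITY["3p_microseed"], span[0], -seg.length), ann))
        elif run_len <= rules.max_seed_run_for_3p_only:
            ann = SiteAnnotation(
                guide.name, utr.transcript_id, span[0], span[1], "3p_only"
            )
            candidates.append(((_PRIORITY["3p_only"], span[0], -seg.length), ann))
        # runs longer than the microseed range are canonical-with-
        # supplementary territory, already annotated by the canonical scan

    candidates.sort(key=lambda c: c[0])
    kept: list[SiteAnnotation] = []
    contested: set[int] = set()
    for _, ann in candidates:
        clash = [
            i
            for i, k in enumerate(kept)
            if not (ann.end < k.start or ann.start > k.end)
        ]
        if not clash:
            kept.append(ann)
        else:
            contested.update(clash)
    out = [
        replace(a, ambiguous=True) if i in contested else a
        for i, a in enumerate(kept)
    ]
    out.sort(key=lambda a: a.start)
    return out


def _has_supplementary(threep_spans, canonical_start, rules) -> bool:
    """Any qualifying 3' run upstream of a canonical site within the
    offset window?"""
    lo, hi = rules.offset_window
    for seg, (a, b) in threep_spans:
        if b < canonical_start:
            bridge = canonical_start - b - 1
            offset = bridge - (seg.start - 8)
            if lo <= offset <= hi + 8:
                return True
    return False


def scan_many(
    utrs: Iterable[UtrRecord],
    guides: Sequence[MirnaGuide],
    rules: ClassifyConfig | None = None,
) -> list[SiteAnnotation]:
    """Scan every UTR against every guide."""
    rules = rules or ClassifyConfig.survey()
    matchers = [(g, GuideMatcher(g, rules)) for g in guides]
    out = []
    for utr in utrs:
        for g, m in matchers:
            out.extend(scan_utr(utr, g, rules, matcher=m))
    return out


def chance_ratio(k_short: int, k_long: int) -> float:
    """Expected relative frequency of a k_long-nt site versus a k_short-nt
    site in random sequence: 4^k_short / 4^k_long."""
    if k_short < 1 or k_long < 1:
        raise ValueError("site lengths must be >= 1")
    return float(4.0 ** k_short / 4.0 ** k_long)


@dataclass
class SurveySummary:
    """Per-miRNA category counts and cross-miRNA medians/ranges."""

    per_mirna: pd.DataFrame
    across: pd.DataFrame

    def proportion(self, mirna: str, category: str) -> float:
        row = self.per_mirna.loc[mirna]
        total = row[list(SURVEY_CATEGORIES)].sum()
        return float(row[category] / total) if total else float("nan")


def summarize(
    annotations: Sequence[SiteAnnotation], mirnas: Sequence[str]
) -> SurveySummary:
    """Tabulate counts per category per miRNA plus summary statistics.

    ``canonical_proportion`` is the fraction of assignable sites that are
    canonical (6mer/7mer-A1/7mer-m8/8mer).
    """
    if not mirnas:
        raise ValueError("need at least one miRNA")
    df = pd.DataFrame(
        [
            {"mirna": a.mirna, "category": a.category}
            for a in annotations
        ]
    )
    per = pd.DataFrame(0, index=list(mirnas), columns=list(SURVEY_CATEGORIES))
    if len(df):
        counts = df.groupby(["mirna", "category"]).size().unstack(fill_value=0)
        per.update(counts)
    per = per.astype(int)
    canonical = per[["6mer", "7mer-A1", "7mer-m8", "8mer"]].sum(axis=1)
    noncanonical = per[["3p_only", "3p_microseed"]].sum(axis=1)
    total = canonical + noncanonical
    with np.errstate(invalid="ignore"):
        per["canonical_proportion"] = np.where(
            total > 0, canonical / total, np.nan
        )
    across = pd.DataFrame(
        {
            "median": per[list(SURVEY_CATEGORIES)].median(),
            "min": per[list(SURVEY_CATEGORIES)].min(),
            "max": per[list(SURVEY_CATEGORIES)].max(),
        }
    )
    return SurveySummary(per, across)
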