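"""Site taxonomy, complementarity search, and offset arithmetic."""

import pytest
from hypothesis import given, settings, strategies as st

from seedless.site_grammar import (
    CANONICAL_RANKING,
    ClassifyConfig,
    GuideMatcher,
    MirnaGuide,
    SiteDescriptor,
    assign_site,
    classify_canonical,
    compute_offset,
    find_threep_matches,
    format_site_name,
    parse_site_name,
    revcomp,
    site_sequence,
)

from conftest import random_reads

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def pairs(g, t):
    return (g, t) in WC


def embed(seq, name, guide):
    """Pad a synthesized site with bases that cannot extend its segments.

    A base identical to the adjacent guide base can never Watson-Crick pair
    with it, so padding with the guide's own bases is extension-proof.
    """
    d = parse_site_name(name)
    if d.threep is not None:
        left_gpos = d.threep.end + 1
    else:
        left_gpos = d.seed.end + 1
    left = guide.base(left_gpos) if left_gpos <= guide.length else "A"
    seed = d.seed
    if seed is None or seed.a1 or seed.start == 1:
        right = "C" if guide.base(1) != "G" else "A"
    else:
        right = guide.base(seed.start - 1)
    return left + seq + right


# ---------------------------------------------------------------- offsets


class TestComputeOffset:
    @pytest.mark.parametrize(
        "seed_end,threep_start,bridge,expected",
        [(7, 13, 8, 2), (7, 13, 6, 0), (7, 9, 5, 3)],
    )
    def test_worked_examples(self, seed_end, threep_start, bridge, expected):
        assert compute_offset(seed_end, threep_start, bridge) == expected

    def test_rejects_overlapping_segments(self):
        with pytest.raises(ValueError):
            compute_offset(8, 8, 3)
        with pytest.raises(ValueError):
            compute_offset(8, 7, 3)

    @given(
        seed_end=st.integers(1, 8),
        threep_start=st.integers(9, 24),
        bridge=st.integers(0, 30),
        k=st.integers(1, 10),
    )
    def test_linear_in_bridge_length(self, seed_end, threep_start, bridge, k):
        base = compute_offset(seed_end, threep_start, bridge)
        assert compute_offset(seed_end, threep_start, bridge + k) == base + k


# ---------------------------------------------------- canonical classes


class TestClassifyCanonical:
    def test_8mer(self, let7a):
        assert classify_canonical("GGCUACCUCAGG", let7a).category == "8mer"

    def test_7mer_m8_when_no_trailing_a(self, let7a):
        assert classify_canonical("GGCUACCUCGGG", let7a).category == "7mer-m8"

    def test_no_site_on_poly_a(self, let7a):
        assert classify_canonical("A" * 12, let7a).category == "none"

    def test_all_classes_round_trip_their_pattern(self, mir155):
        # each canonical class's defining sequence classifies as itself
        for cls in CANONICAL_RANKING:
            window = embed(site_sequence(mir155, cls), cls, mir155)
            assert classify_canonical(window, mir155).category == cls

    def test_invalid_alphabet_rejected(self, let7a):
        with pytest.raises(ValueError):
            classify_canonical("ACGX", let7a)


# ------------------------------------------------------------ 3' matches


class TestFindThreepMatches:
    def test_programmed_register_recovered(self, let7a):
        read = "GGGGG" + revcomp(let7a.segment(11, 18)) + "GGGGG"
        [(seg, span)] = find_threep_matches(read, let7a, 8)
        assert (seg.start, seg.end) == (11, 18)
        assert span == (6, 13)

    def test_no_match_below_min_len(self, let7a):
        assert find_threep_matches("A" * 40, let7a, 8) == []

    def test_maximal_not_subregisters(self, let7a):
        read = "CCAAG" + revcomp(let7a.segment(11, 22)) + "CCAAG"
        segs = find_threep_matches(read, let7a, 8)
        assert [(s.start, s.end) for s, _ in segs] == [(11, 22)]

    def test_reported_spans_are_watson_crick_and_maximal(self, let7a, rng):
        cfg = ClassifyConfig(min_threep_len=5)
        matcher = GuideMatcher(let7a, cfg)
        g = let7a.sequence
        checked = 0
        for read in random_reads(rng, 3000):
            for seg, (a, b) in matcher.threep_matches(read):
                tgt = read[a - 1 : b]
                # antiparallel: target 5' end pairs guide segment 3' end
                for off, t in enumerate(tgt):
                    assert pairs(g[seg.end - 1 - off], t)
                # maximality within the allowed guide region
                if seg.end < let7a.length and a > 1:
                    assert not pairs(g[seg.end], read[a - 2])
                if seg.start > cfg.min_3p_start and b < len(read):
                    assert not pairs(g[seg.start - 2], read[b])
                checked += 1
        assert checked > 50

    def test_returned_segments_disjoint_on_read(self, let7a, rng):
        matcher = GuideMatcher(let7a, ClassifyConfig(min_threep_len=4))
        for read in random_reads(rng, 2000):
            spans = [s for _, s in matcher.threep_matches(read)]
            spans.sort()
            for (a0, b0), (a1, b1) in zip(spans, spans[1:]):
                assert b0 < a1


# ------------------------------------------------------- read assignment


def oracle_assign(read, guide, cfg):
    """Brute-force single-site assignment: test every window against every
    site definition, then apply the same precedence order."""
    g = guide.sequence
    L = guide.length

    def run_at(i, gpos_hi):
        # maximal complementary run with read[i] pairing guide position
        # gpos_hi, extending with antiparallel geometry
        n = 0
        while i + n < len(read) and gpos_hi - n >= 1 and pairs(
            g[gpos_hi - n - 1], read[i + n]
        ):
            n += 1
        return n

    # all maximal 3' runs
    threep = []
    for i in range(len(read)):
        for te in range(L, cfg.min_3p_start - 1, -1):
            n = run_at(i, te)
            ts = te - n + 1
            if ts < cfg.min_3p_start:
                n = te - cfg.min_3p_start + 1
                ts = cfg.min_3p_start
            if n >= cfg.min_threep_len:
                left_ext = i > 0 and te < L and pairs(g[te], read[i - 1])
                right_ext = (
                    i + n < len(read)
                    and ts > cfg.min_3p_start
                    and pairs(g[ts - 2], read[i + n])
                )
                if not left_ext and not right_ext:
                    threep.append((ts, te, i + 1, i + n))
    # dedupe/non-overlap like the implementation: longest, then left-most
    threep = sorted(set(threep), key=lambda x: (-(x[3] - x[2]), x[2], x[0]))
    kept = []
    for t in threep:
        if all(t[3] < k[2] or t[2] > k[3] for k in kept):
            kept.append(t)

    candidates = []
    for ts, te, a, b in kept:
        seeds = []
        for i in range(b, len(read)):
            for se in range(8, 0, -1):
                n = run_at(i, se)
                ss = se - n + 1
                if ss < 1:
                    n, ss = se, 1
                if n > cfg.max_seed_run_for_3p_only:
                    # a nucleotide inside the 3' duplex cannot extend the
                    # seed run, so runs abutting the segment are maximal
                    lext = i > b and se < 8 and pairs(g[se], read[i - 1])
                    rext = i + n < len(read) and ss > 1 and pairs(
                        g[ss - 2], read[i + n]
                    )
                    if lext or rext:
                        continue
                    off = (i - b) - (ts - se)
                    if cfg.offset_window[0] <= off <= cfg.offset_window[1]:
                        seeds.append((ss, se, off, i + 1))
        seeds = sorted(
            set(seeds), key=lambda s: (-(s[1] - s[0]), abs(s[2]), s[3], -s[1])
        )
        if seeds:
            ss, se, off, _ = seeds[0]
            candidates.append(
                ((0, -(te - ts + 1), -(se - ss + 1), a), f"m{ts}_{te}|{off:+d}|m{ss}_{se}")
            )
        else:
            candidates.append(((1, -(te - ts + 1), 0, a), f"m{ts}_{te}"))

    matcher = GuideMatcher(guide, cfg)
    canon = matcher.canonical(read)
    if canon is not None:
        candidates.append(
            ((2, CANONICAL_RANKING.index(canon.category), 0, canon.target_span[0]),
             canon.category)
        )
    if not candidates:
        return "none"
    candidates.sort(key=lambda c: c[0])
    return candidates[0][1]


class TestAssignSite:
    def test_compound_worked_example(self, let7a):
        threep = revcomp(let7a.segment(11, 18))       # AUACAACC
        bridge = "GUAGGU"                             # 6 nt, non-pairing
        seed = revcomp(let7a.segment(2, 7))           # UACCUC
        read = "CCAAG" + threep + bridge + seed + "GAGCC"
        assert assign_site(read, let7a).name == "m11_18|+2|m2_7"

    def test_polyu_flanked_8mer(self, let7a):
        read = "U" * 10 + "CUACCUCA" + "U" * 10
        assert assign_site(read, let7a).name == "8mer"

    def test_featureless_read_is_none(self, let7a):
        assert assign_site("A" * 40, let7a).name == "none"

    def test_agrees_with_brute_force_oracle(self, let7a, rng):
        cfg = ClassifyConfig(min_threep_len=5)
        matcher = GuideMatcher(let7a, cfg)
        reads = random_reads(rng, 4000)
        # bias half the reads toward sites so non-trivial classes are hit
        threep = revcomp(let7a.segment(12, 19))
        for i in range(0, len(reads), 2):
            r = reads[i]
            reads[i] = r[:10] + threep + r[18:]
        mismatches = [
            (r, matcher.assign(r).name, oracle_assign(r, let7a, cfg))
            for r in reads
            if matcher.assign(r).name != oracle_assign(r, let7a, cfg)
        ]
        assert mismatches == []

    def test_every_read_gets_exactly_one_category(self, mir155, rng):
        matcher = GuideMatcher(mir155, ClassifyConfig())
        cats = {"8mer", "7mer-m8", "7mer-A1", "6mer", "6mer-m8", "6mer-A1",
                "3p_only", "compound", "none"}
        for read in random_reads(rng, 500):
            assert matcher.assign(read).category in cats


# --------------------------------------------------------- serialization


class TestSiteNames:
    def test_paper_naming_convention(self):
        d = parse_site_name("m13_20|+2|m2_7")
        assert (d.threep.start, d.threep.end) == (13, 20)
        assert d.offset == 2
        assert (d.seed.start, d.seed.end) == (2, 7)

    def test_canonical_keyword(self):
        d = parse_site_name("8mer")
        assert d.category == "8mer" and d.threep is None and d.offset is None

    @pytest.mark.parametrize(
        "name", ["m9_19|+3|m2_5", "m13_22|-1|m2_8", "m11_23", "7mer-m8", "none"]
    )
    def test_round_trip(self, name):
        assert format_site_name(parse_site_name(name)) == name

    @pytest.mark.parametrize("bad", ["m13-20", "m13_20|2|m2_7", "9mer", "m_3"])
    def test_malformed_names_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_site_name(bad)


class TestSiteSequence:
    @pytest.mark.parametrize(
        "name", ["m13_20|+2|m2_7", "m13_22|+0|m2_5", "m11_23", "8mer", "6mer"]
    )
    def test_synthesized_sites_classify_as_themselves(self, mir155, name):
        cfg = ClassifyConfig()
        seq = site_sequence(mir155, name)
        read = embed(seq, name, mir155)
        got = assign_site(read, mir155, cfg)
        want = parse_site_name(name)
        if want.category in CANONICAL_RANKING:
            assert got.category == want.category
        else:
            assert got.name == name

    def test_negative_bridge_rejected(self, mir155):
        with pytest.raises(ValueError):
            site_sequence(mir155, "m9_20|-4|m2_7")
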