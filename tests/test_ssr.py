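import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markerkit.model import SsrPrimerParams, Transcript
from markerkit.primers import PrimerRejection, gc_percent
from markerkit.ssr import (
    DEFAULT_THRESHOLDS,
    canonical_class,
    design_primers,
    detect_ssrs,
    group_compound,
    is_primitive,
    melting_temperature,
    summarize_ssrs,
    SsrLocus,
)


def T(seq, tid="t1"):
    return Transcript(tid, seq)


# ---------------------------------------------------------------------------
# detection

def test_detect_simple_di_repeat():
    loci = detect_ssrs(T("TT" + "AG" * 6 + "TT"))
    assert len(loci) == 1
    l = loci[0]
    assert (l.motif, l.n_repeats, l.start, l.end) == ("AG", 6, 3, 14)


def test_below_threshold_not_reported():
    assert detect_ssrs(T("CCTT" + "AG" * 5 + "TTCC")) == []
    assert len(detect_ssrs(T("CCTT" + "AAG" * 5 + "TTCC"))) == 1  # tri threshold is 5


def test_repeat_reported_at_smallest_primitive_unit():
    loci = detect_ssrs(T("ATATATATATAT"))
    assert len(loci) == 1
    assert loci[0].motif == "AT" and loci[0].n_repeats == 6


def test_partial_trailing_unit_is_truncated():
    loci = detect_ssrs(T("CC" + "AAG" * 5 + "AA" + "CCCC"))
    assert len(loci) == 1
    assert loci[0].n_repeats == 5 and loci[0].end == 2 + 15


def test_detection_independent_of_transcript_order(small_panel):
    ts = small_panel.transcripts[:10]
    fwd = [l for t in ts for l in detect_ssrs(t)]
    rev = [l for t in reversed(ts) for l in detect_ssrs(t)]
    key = lambda l: (l.transcript_id, l.start)
    assert sorted(map(key, fwd)) == sorted(map(key, rev))


def _regex_oracle(seq, thresholds=DEFAULT_THRESHOLDS):
    """Independent SSR finder: per-unit-length regex with primitivity filter."""
    candidates = []
    for u, k in thresholds.items():
        pat = re.compile(rf"(?=((\w{{{u}}})\2{{{k - 1},}}))")
        for m in pat.finditer(seq):
            start = m.start()
            motif = m.group(2)
            if not is_primitive(motif) or "N" in motif:
                continue
            # keep only left-maximal runs: the period must break just before
            if start >= 1 and seq[start - 1] == seq[start - 1 + u]:
                continue
            run = len(m.group(1)) // u
            candidates.append((start + 1, start + run * u, motif, run, u))
    # smallest-unit-first containment suppression
    out = []
    for s, e, motif, run, u in sorted(candidates, key=lambda c: (c[4], c[0])):
        if any(os <= s and e <= oe for os, oe, _, _, ou in out if ou < u):
            continue
        out.append((s, e, motif, run, u))
    return {(s, e, motif, run) for s, e, motif, run, _ in out}


@settings(derandomize=True, max_examples=30)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_detector_matches_regex_oracle_on_random_sequences(seed):
    rng = np.random.default_rng(seed)
    # AT-rich alphabet raises the accidental-repeat rate
    seq = "".join(rng.choice(list("AACGTT"), size=3000))
    got = {
        (l.start, l.end, l.motif, l.n_repeats) for l in detect_ssrs(T(seq))
    }
    assert got == _regex_oracle(seq)


# ---------------------------------------------------------------------------
# canonicalization

@pytest.mark.parametrize(
    "motif,cls",
    [("GA", "AG/CT"), ("TTC", "AAG/CTT"), ("AT", "AT/TA"), ("CG", "CG/GC")],
)
def test_canonical_class_examples(motif, cls):
    assert canonical_class(motif) == cls


def test_canonical_class_rejects_non_primitive():
    with pytest.raises(ValueError):
        canonical_class("ATAT")


def test_canonical_class_rotation_and_rc_invariance():
    from markerkit.iupac import reverse_complement

    for motif in ("AG", "AAG", "ACGT", "AATGC"):
        base = canonical_class(motif)
        for i in range(len(motif)):
            rot = motif[i:] + motif[:i]
            assert canonical_class(rot) == base
            assert canonical_class(reverse_complement(rot)) == base


def test_reachable_class_counts():
    """4 dinucleotide and 10 trinucleotide canonical classes exist."""
    from itertools import product

    def classes(u):
        out = set()
        for tup in product("ACGT", repeat=u):
            m = "".join(tup)
            if is_primitive(m):
                out.add(canonical_class(m))
        return out

    assert len(classes(2)) == 4
    assert len(classes(3)) == 10


# ---------------------------------------------------------------------------
# compound grouping and summary

def mk(start, end, motif, n, tid="t1"):
    return SsrLocus(tid, start, end, motif, n)


def test_group_compound_gap_rule():
    a = mk(3, 14, "AG", 6)         # ends 14
    b = mk(18, 32, "AAG", 5)       # gap 3 -> compound
    got = group_compound([a, b], max_gap=100)
    assert got[0].compound_group == got[1].compound_group is not None
    far = group_compound([mk(3, 14, "AG", 6), mk(165, 179, "AAG", 5)], max_gap=100)
    assert all(l.compound_group is None for l in far)
    single = group_compound([mk(3, 14, "AG", 6)])
    assert single[0].compound_group is None


def test_group_compound_respects_transcript_split():
    a = mk(3, 14, "AG", 6, tid="t1")
    b = mk(20, 34, "AAG", 5, tid="t2")
    got = group_compound([a, b])
    assert all(l.compound_group is None for l in got)


def test_summarize_planted_truth(small_panel):
    loci = [l for t in small_panel.transcripts for l in detect_ssrs(t)]
    loci = group_compound(loci)
    summary = summarize_ssrs(loci, small_panel.transcripts)
    truth = small_panel.truth_ssrs
    assert summary.n_ssrs == len(truth)
    from collections import Counter

    assert summary.by_unit_length == dict(Counter(len(l.motif) for l in truth))
    hosts = Counter(l.transcript_id for l in truth)
    assert summary.n_ssr_containing == len(hosts)
    assert summary.n_multi_ssr == sum(1 for c in hosts.values() if c > 1)


def test_summarize_empty():
    s = summarize_ssrs([], [T("ACGTACG")])
    assert s.n_ssrs == 0 and s.by_unit_length == {} and s.n_compound == 0


# ---------------------------------------------------------------------------
# primers

def test_melting_temperature_formula():
    assert melting_temperature("GC" * 5 + "AT" * 5) == pytest.approx(51.78)
    assert melting_temperature("G" * 14 + "ATATAT") == pytest.approx(59.98)
    with pytest.raises(ValueError):
        melting_temperature("ACGTACGTACGTA")  # 13-mer


def test_design_primers_on_planted_locus():
    rng = np.random.default_rng(3)
    flank1 = "".join(rng.choice(list("ACGT"), size=150))
    flank2 = "".join(rng.choice(list("ACGT"), size=150))
    seq = flank1 + "AG" * 8 + flank2
    t = T(seq)
    target = (151, 166)
    p = design_primers(t, target)
    assert not isinstance(p, PrimerRejection)
    assert 100 <= p.product_size <= 280
    assert p.forward_start + len(p.forward_seq) - 1 < target[0]
    assert p.reverse_end - len(p.reverse_seq) + 1 > target[1]
    params = SsrPrimerParams()
    for primer in (p.forward_seq, p.reverse_seq):
        assert params.min_length <= len(primer) <= params.max_length
        assert params.min_gc <= gc_percent(primer) <= params.max_gc
        assert params.min_tm <= melting_temperature(primer) <= params.max_tm


def test_design_primers_no_upstream_space():
    seq = "AG" * 10 + "".join(np.random.default_rng(0).choice(list("ACGT"), size=300))
    p = design_primers(T(seq), (1, 20))
    assert isinstance(p, PrimerRejection)
    assert p.constraint == "SPACE"


def test_design_primers_at_flanks_fail_gc():
    seq = "AT" * 100 + "AAG" * 6 + "TA" * 100
    p = design_primers(T(seq), (201, 218))
    assert isinstance(p, PrimerRejection)
    assert p.constraint == "GC"
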