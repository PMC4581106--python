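import pytest
from Bio.Data.IUPACData import ambiguous_dna_values
from hypothesis import given, settings
from hypothesis import strategies as st

from markerkit.caps import (
    CapsMarker,
    CapsParams,
    CapsRejection,
    design_caps_marker,
    differential_enzymes,
    digest_fragments,
    project_to_genome,
    scan_sites,
)
from markerkit.io import AlignmentBlock
from markerkit.iupac import reverse_complement
from markerkit.model import Enzyme, Transcript, VariantSite

ECORI = Enzyme("EcoRI", "GAATTC", 1)


def vs(tid, pos, ref, alt):
    return VariantSite(transcript_id=tid, pos=pos, ref=ref, alts=(alt,))


def test_scan_sites_examples(enzyme_map):
    assert scan_sites("TTGAATTCAA", ECORI) == [3]
    assert scan_sites("GAGCTC", enzyme_map["SacI"]) == [1]
    assert scan_sites("GAGCTC", enzyme_map["AluI"]) == [2]  # nested recognition
    assert scan_sites("AAAA", ECORI) == []


def test_scan_sites_overlapping_matches():
    taq = Enzyme("TaqI", "TCGA", 1)
    assert scan_sites("TCGATCGA", taq) == [1, 5]
    # overlapping degenerate hits are all reported
    dde = Enzyme("DdeI", "CTNAG", 1)
    assert scan_sites("CTCAGCTGAG", dde) == [1, 6]


def test_scan_sites_never_matches_masked_bases():
    assert scan_sites("GANTTC", ECORI) == []


def test_differential_enzymes_planted_site():
    t = Transcript("t1", "TTTT" + "GAATTC" + "TTTT")
    site = vs("t1", 7, "A", "G")  # breaks GAATTC -> GAGTTC
    diags = differential_enzymes(site, t, [ECORI])
    assert [(e.name, a) for e, a in diags] == [("EcoRI", "REF")]


def test_differential_requires_match_to_cover_the_snp(enzyme_map):
    # GAGCT[C/A]: SacI's site covers the SNP, AluI's nested AGCT does not
    t = Transcript("t1", "TTTTGAGCTCTTTT")
    site = vs("t1", 10, "C", "A")
    diags = differential_enzymes(
        site, t, [enzyme_map["SacI"], enzyme_map["AluI"]]
    )
    assert [(e.name, a) for e, a in diags] == [("SacI", "REF")]


def test_differential_no_enzyme_context(enzymes):
    t = Transcript("t1", "A" * 30)
    assert differential_enzymes(vs("t1", 15, "A", "T"), t, enzymes) == []


def test_differential_swapping_alleles_swaps_labels(enzymes):
    t_ref = Transcript("t1", "TTTT" + "GAATTC" + "TTTT")
    t_alt = Transcript("t1", "TTTT" + "GAGTTC" + "TTTT")
    d_ref = differential_enzymes(vs("t1", 7, "A", "G"), t_ref, enzymes)
    d_alt = differential_enzymes(vs("t1", 7, "G", "A"), t_alt, enzymes)
    flipped = {(e.name, {"REF": "ALT", "ALT": "REF"}[a]) for e, a in d_alt}
    assert {(e.name, a) for e, a in d_ref} == flipped


def _oracle_differential(site, t, enzymes, flank=10):
    """Exhaustive window x enzyme x allele scan using Biopython's code table."""
    lo = max(0, site.pos - 1 - flank)
    hi = min(len(t), site.pos + flank)
    out = []
    for e in enzymes:
        hits = {}
        for allele_name, allele in (("REF", site.ref), ("ALT", site.alts[0])):
            window = (
                t.sequence[lo : site.pos - 1] + allele + t.sequence[site.pos : hi]
            )
            snp_idx = site.pos - 1 - lo
            found = False
            for start in range(len(window) - len(e.recognition) + 1):
                if not start <= snp_idx <= start + len(e.recognition) - 1:
                    continue
                if all(
                    b in ambiguous_dna_values[p]
                    for p, b in zip(e.recognition, window[start:])
                ):
                    found = True
                    break
            hits[allele_name] = found
        if hits["REF"] != hits["ALT"]:
            out.append((e.name, "REF" if hits["REF"] else "ALT"))
    return out


@settings(derandomize=True, max_examples=40)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_differential_matches_exhaustive_oracle(enzymes, seed):
    """The diagnostic-enzyme caller agrees with a brute-force scanner."""
    import numpy as np

    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
    t = Transcript("t1", seq)
    pos = int(rng.integers(12, 390))
    ref = seq[pos - 1]
    alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
    site = vs("t1", pos, ref, alt)
    got = [(e.name, a) for e, a in differential_enzymes(site, t, enzymes)]
    assert got == _oracle_differential(site, t, enzymes)


def test_digest_fragments_examples(enzyme_map):
    amp = "A" * 99 + "GAATTC" + "A" * 195  # site starts at 100, cut offset 1
    assert digest_fragments(amp, ECORI) == (100, 200)
    assert digest_fragments("A" * 300, ECORI) == (300,)
    two = "T" * 50 + "AGCT" + "T" * 50 + "AGCT" + "T" * 50
    frags = digest_fragments(two, enzyme_map["AluI"])
    assert len(frags) == 3 and sum(frags) == len(two)


def test_design_caps_marker_planted(enzymes):
    import numpy as np

    rng = np.random.default_rng(5)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=600))
    pos = 300
    seq = seq[: pos - 4] + "GAATTC" + seq[pos + 2 :]
    t = Transcript("t1", seq)
    site = vs("t1", pos, seq[pos - 1], "G" if seq[pos - 1] != "G" else "C")
    m = design_caps_marker(site, t, enzymes)
    assert isinstance(m, CapsMarker)
    assert 200 <= m.amplicon_length <= 400
    assert m.amplicon_start <= pos <= m.amplicon_end
    for ladders in m.fragments.values():
        assert sum(ladders["REF"]) == m.amplicon_length
        assert sum(ladders["ALT"]) == m.amplicon_length
        assert ladders["REF"] != ladders["ALT"]


def test_design_caps_marker_rejections(enzymes):
    # no diagnostic enzyme anywhere near the SNP
    t = Transcript("t1", "A" * 600)
    r = design_caps_marker(vs("t1", 300, "A", "T"), t, enzymes)
    assert isinstance(r, CapsRejection) and r.reason == "NO_ENZYME"
    # diagnostic enzyme but no room for a 200 bp amplicon
    short = Transcript("t1", "TT" + "GAATTC" + "T" * 92)
    r = design_caps_marker(vs("t1", 4, "A", "G"), short, enzymes)
    assert isinstance(r, CapsRejection) and r.reason == "NO_AMPLICON"


def test_scorability_screen():
    from markerkit.caps import _ladders_scorable

    assert _ladders_scorable((100, 200), (300,), 20)
    assert not _ladders_scorable((100, 200), (100, 200), 20)
    assert not _ladders_scorable((150, 150), (149, 151), 20)


def test_palindromic_set_reverse_strand_adds_no_sites(enzymes, small_panel):
    """Scanning the reverse complement finds the same site set (palindromes)."""
    t = small_panel.transcripts[0]
    n = len(t)
    for e in enzymes:
        fwd = set(scan_sites(t.sequence, e))
        rc = scan_sites(reverse_complement(t.sequence), e)
        back = {n - (p + len(e.recognition) - 1) + 1 for p in rc}
        assert fwd == back


BLOCK = AlignmentBlock("t1", 101, 200, "scaf1", 5001, 5100, "+")
BLOCK_MINUS = AlignmentBlock("t1", 101, 200, "scaf1", 5001, 5100, "-")


def test_project_to_genome():
    assert project_to_genome(vs("t1", 150, "A", "G"), [BLOCK]) == ("scaf1", 5050, "+")
    assert project_to_genome(vs("t1", 150, "A", "G"), [BLOCK_MINUS]) == (
        "scaf1", 5051, "-",
    )
    with pytest.raises(LookupError, match="UNMAPPED"):
        project_to_genome(vs("t1", 250, "A", "G"), [BLOCK])
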