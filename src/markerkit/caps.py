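"""CAPS (cleaved amplified polymorphic sequence) marker prediction.

A SNP is a CAPS candidate when some restriction enzyme's recognition site
*overlapping the SNP position* exists for exactly one of the two alleles:
PCR around the SNP followed by digestion then yields allele-specific
fragment patterns on a gel.  This module finds such diagnostic enzymes,
places a single 200-400 bp amplicon with one primer pair around the SNP,
and predicts the digestion fragment ladder of each allele - the ladder
check is what makes a marker scorable in practice, since two alleles whose
fragments differ by only a few bases cannot be separated on agarose.

SNP coordinates can also be projected from transcript space onto genome
scaffolds through gapless alignment blocks, strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io import AlignmentBlock
from .iupac import matches_at
from .model import Enzyme, PrimerPair, SsrPrimerParams, Transcript, VariantSite
from .primers import PrimerRejection, design_primer_pair


@dataclass
class CapsParams:
    min_amplicon: int = 200
    max_amplicon: int = 400
    flank: int = 10  # allele-window half-width; exceeds every bundled site length
    scorability_min_diff: int = 0  # 0 = no fragment-size screening
    primer: SsrPrimerParams = field(default_factory=lambda: SsrPrimerParams(
        min_amplicon=200, max_amplicon=400
    ))


@dataclass
class CapsMarker:
    site: VariantSite
    diagnostic_enzymes: list[tuple[Enzyme, str]]  # allele_cut in {"REF", "ALT"}
    amplicon_start: int
    amplicon_end: int
    primer_pair: PrimerPair
    fragments: dict[str, dict[str, tuple[int, ...]]]  # enzyme -> allele -> ladder
    genome_projection: Optional[tuple[str, int, str]] = None

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_end - self.amplicon_start + 1


@dataclass
class CapsRejection:
    site: VariantSite
    reason: str  # NO_ENZYME / NO_AMPLICON / NOT_SCORABLE


def scan_sites(seq: str, e: Enzyme) -> list[int]:
    """1-based start positions of every (possibly overlapping) match."""
    pattern = e.recognition
    return [
        i + 1 for i in range(len(seq) - len(pattern) + 1) if matches_at(seq, pattern, i)
    ]


def _allele_window(t: Transcript, site: VariantSite, allele: str, flank: int) -> tuple[str, int]:
    """Sequence window of +/- flank around the SNP carrying ``allele``.

    Returns (window, offset) where offset is the 0-based index of the SNP
    within the window; windows truncate at transcript ends.
    """
    lo = max(0, site.pos - 1 - flank)
    hi = min(len(t), site.pos + flank)
    window = t.sequence[lo : site.pos - 1] + allele + t.sequence[site.pos : hi]
    return window, site.pos - 1 - lo


def differential_enzymes(
    site: VariantSite,
    t: Transcript,
    enzymes: Sequence[Enzyme],
    flank: int = 10,
) -> list[tuple[Enzyme, str]]:
    """Enzymes whose site covering the SNP exists in exactly one allele.

    ``allele_cut`` names the allele whose sequence carries the recognition
    site ("REF" or "ALT").  Only biallelic sites are eligible.
    """
    if not site.biallelic:
        raise ValueError(f"{site.transcript_id}:{site.pos}: CAPS requires a biallelic site")
    if t.sequence[site.pos - 1] != site.ref:
        raise ValueError(
            f"{site.transcript_id}:{site.pos}: reference allele {site.ref} "
            f"disagrees with transcript base {t.sequence[site.pos - 1]}"
        )
    out = []
    ref_win, offset = _allele_window(t, site, site.ref, flank)
    alt_win, _ = _allele_window(t, site, site.alts[0], flank)
    for e in enzymes:
        def covers(window: str) -> bool:
            return any(
                p - 1 <= offset <= p - 2 + len(e)
                for p in scan_sites(window, e)
            )
        in_ref, in_alt = covers(ref_win), covers(alt_win)
        if in_ref != in_alt:
            out.append((e, "REF" if in_ref else "ALT"))
    return out


def digest_fragments(amplicon_seq: str, e: Enzyme) -> tuple[int, ...]:
    """Sorted fragment lengths after a complete digest of the amplicon.

    Cut positions are ``match_start - 1 + cut_offset`` bases from the
    amplicon start; cuts at the very ends produce no fragment.  With no
    match the amplicon stays whole.
    """
    n = len(amplicon_seq)
    cuts = sorted(
        {
            p - 1 + e.cut_offset
            for p in scan_sites(amplicon_seq, e)
            if 0 < p - 1 + e.cut_offset < n
        }
    )
    edges = [0] + cuts + [n]
    return tuple(sorted(b - a for a, b in zip(edges, edges[1:])))


def design_caps_marker(
    site: VariantSite,
    t: Transcript,
    enzymes: Sequence[Enzyme],
    params: CapsParams | None = None,
) -> CapsMarker | CapsRejection:
    """Full CAPS design for one SNP: enzymes, amplicon, primers, ladders.

    The amplicon centers the SNP as nearly as primer feasibility allows,
    breaking ties toward smaller amplicons.  With ``scorability_min_diff``
    > 0, a marker is kept only if for some diagnostic enzyme the two
    allele ladders differ by at least that many bases in some fragment.
    """
    params = params or CapsParams()
    diagnostics = differential_enzymes(site, t, enzymes, flank=params.flank)
    if not diagnostics:
        return CapsRejection(site=site, reason="NO_ENZYME")
    primer_params = SsrPrimerParams(
        min_amplicon=params.min_amplicon,
        max_amplicon=params.max_amplicon,
        min_tm=params.primer.min_tm,
        max_tm=params.primer.max_tm,
        min_length=params.primer.min_length,
        max_length=params.primer.max_length,
        min_gc=params.primer.min_gc,
        max_gc=params.primer.max_gc,
    )
    pair = design_primer_pair(
        t.sequence, site.pos, site.pos, params=primer_params, centered_first=True
    )
    if isinstance(pair, PrimerRejection):
        return CapsRejection(site=site, reason="NO_AMPLICON")
    amp_start, amp_end = pair.forward_start, pair.reverse_end
    snp_idx = site.pos - amp_start  # 0-based within amplicon
    amp_ref = t.sequence[amp_start - 1 : amp_end]
    amp_alt = amp_ref[:snp_idx] + site.alts[0] + amp_ref[snp_idx + 1 :]
    fragments: dict[str, dict[str, tuple[int, ...]]] = {}
    scorable = params.scorability_min_diff <= 0
    for e, _allele in diagnostics:
        ladders = {"REF": digest_fragments(amp_ref, e), "ALT": digest_fragments(amp_alt, e)}
        fragments[e.name] = ladders
        if not scorable and _ladders_scorable(
            ladders["REF"], ladders["ALT"], params.scorability_min_diff
        ):
            scorable = True
    if not scorable:
        return CapsRejection(site=site, reason="NOT_SCORABLE")
    return CapsMarker(
        site=site,
        diagnostic_enzymes=diagnostics,
        amplicon_start=amp_start,
        amplicon_end=amp_end,
        primer_pair=pair,
        fragments=fragments,
    )


def _ladders_scorable(a: tuple[int, ...], b: tuple[int, ...], min_diff: int) -> bool:
    """Do two fragment ladders differ by >= min_diff bp in some fragment?

    Compared greedily after removing fragments shared between the ladders;
    the remaining fragments of one allele must each be resolvable from
    every remaining fragment of the other.
    """
    if a == b:
        return False
    rest_a = list(a)
    rest_b = list(b)
    for x in list(rest_a):
        if x in rest_b:
            rest_a.remove(x)
            rest_b.remove(x)
    return any(
        abs(x - y) >= min_diff for x in (rest_a or rest_b) for y in (rest_b or rest_a)
    )


def project_to_genome(
    site: VariantSite, blocks: Sequence[AlignmentBlock]
) -> tuple[str, int, str]:
    """Map a transcript position to (scaffold, genome position, strand).

    Affine within a gapless block; on the minus strand the position is
    counted back from the block's genome end.  A position in no block
    raises ``UNMAPPED``.
    """
    for b in blocks:
        if b.transcript_id == site.transcript_id and b.t_start <= site.pos <= b.t_end:
            off = site.pos - b.t_start
            if b.strand == "+":
                return b.scaffold, b.g_start + off, "+"
            return b.scaffold, b.g_end - off, "-"
    raise LookupError(f"UNMAPPED: {site.transcript_id}:{site.pos} not covered by any block")


def write_caps_table(results, path, blocks: Optional[dict[str, list[AlignmentBlock]]] = None) -> None:
    """One row per (locus, enzyme); rejections carry the reason instead."""
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tpos\tref\talt\tenzyme\tallele_cut\tamplicon_start\t"
            "amplicon_end\tfwd_primer\trev_primer\tref_fragments\talt_fragments\t"
            "scaffold\tgenome_pos\tstrand\tstatus\n"
        )
        for r in results:
            s = r.site
            base = f"{s.transcript_id}\t{s.pos}\t{s.ref}\t{','.join(s.alts)}"
            if isinstance(r, CapsRejection):
                fh.write(base + "\t." * 10 + f"\t.\t{r.reason}\n")
                continue
            proj = (".", ".", ".")
            if blocks is not None:
                try:
                    proj = tuple(map(str, project_to_genome(s, blocks.get(s.transcript_id, []))))
                except LookupError:
                    proj = (".", "UNMAPPED", ".")
            for e, allele_cut in r.diagnostic_enzymes:
                lad = r.fragments[e.name]
                fh.write(
                    base
                    + f"\t{e.name}\t{allele_cut}\t{r.amplicon_start}\t{r.amplicon_end}"
                    + f"\t{r.primer_pair.forward_seq}\t{r.primer_pair.reverse_seq}"
                    + "\t" + ",".join(map(str, lad["REF"]))
                    + "\t" + ",".join(map(str, lad["ALT"]))
                    + f"\t{proj[0]}\t{proj[1]}\t{proj[2]}\tOK\n"
                )
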