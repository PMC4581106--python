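"""Microsatellite (SSR) detection, motif canonicalization and primer design.

Detection follows the MISA convention: maximal perfect tandem repeats of
primitive 2-6 bp units, with minimum repeat numbers of 6 for di- and 5 for
tri-/tetra-/penta-/hexanucleotide motifs (mononucleotide runs are not
considered).  A repeat region is reported exactly once, at its smallest
primitive unit, so (AT)x6 is never also reported as (ATAT)x3.

Motifs are grouped into canonical classes invariant under rotation and
reverse complementation: the class representative is the lexicographic
minimum over all rotations of the motif and of its reverse complement, and
the class label is ``min/revcomp(min)`` (e.g. GA, AG, TC and CT all belong
to class AG/CT).  There are exactly 4 reachable dinucleotide classes and 10
trinucleotide classes.

Two SSRs on one transcript separated by at most ``max_gap`` bases form a
compound SSR.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .iupac import reverse_complement
from .model import PrimerPair, SsrPrimerParams, Transcript
from .primers import PrimerRejection, design_primer_pair, gc_percent, melting_temperature

__all__ = [
    "SsrLocus",
    "DEFAULT_THRESHOLDS",
    "detect_ssrs",
    "canonical_class",
    "group_compound",
    "summarize_ssrs",
    "SsrSummary",
    "design_primers",
    "melting_temperature",
    "gc_percent",
    "is_primitive",
    "write_ssr_table",
]

#: Minimum repeat numbers per unit length (MISA-style criteria).
DEFAULT_THRESHOLDS: dict[int, int] = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass
class SsrLocus:
    transcript_id: str
    start: int  # 1-based inclusive
    end: int
    motif: str  # unit as it appears in the sequence
    n_repeats: int
    compound_group: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif) * self.n_repeats:
            raise ValueError(
                f"{self.transcript_id}:{self.start}-{self.end}: span does not "
                f"equal {len(self.motif)} x {self.n_repeats}"
            )

    @property
    def unit_length(self) -> int:
        return len(self.motif)

    @property
    def canonical_class(self) -> str:
        return canonical_class(self.motif)


def is_primitive(motif: str) -> bool:
    """True iff the motif is not a whole-number repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_class(motif: str) -> str:
    """Canonical class label, invariant under rotation and reverse complement."""
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rotations = {motif[i:] + motif[:i] for i in range(len(motif))}
    rc = reverse_complement(motif)
    rotations |= {rc[i:] + rc[:i] for i in range(len(rc))}
    rep = min(rotations)
    mate = reverse_complement(rep)
    if mate == rep:
        # palindromic representative (e.g. AT): label with the complementary
        # strand read in the same orientation instead, as the survey tables do
        mate = rep[::-1]
    return f"{rep}/{mate}"


def detect_ssrs(
    t: Transcript, thresholds: Optional[dict[int, int]] = None
) -> list[SsrLocus]:
    """All maximal primitive tandem repeats meeting the repeat thresholds.

    Repeats are scanned per unit length in increasing order; a candidate
    wholly contained in a locus already reported at a smaller unit is
    suppressed, and non-primitive units are skipped (their region is the
    smaller unit's run).  Output is sorted by start position.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    seq = t.sequence
    n = len(seq)
    accepted: list[SsrLocus] = []
    for u in sorted(thresholds):
        min_rep = thresholds[u]
        i = 0
        while i + u < n:
            if seq[i] != seq[i + u] or seq[i] == "N":
                i += 1
                continue
            # extend the run of period-u matches starting at i
            j = i
            while j + u < n and seq[j] == seq[j + u] and seq[j] != "N":
                j += 1
            run_len = (j - i) + u  # total bases with period u
            n_rep = run_len // u
            motif = seq[i : i + u]
            if n_rep >= min_rep and is_primitive(motif):
                start = i + 1
                end = i + u * n_rep
                contained = any(
                    loc.start <= start and end <= loc.end
                    for loc in accepted
                    if loc.unit_length < u
                )
                if not contained:
                    accepted.append(
                        SsrLocus(
                            transcript_id=t.id,
                            start=start,
                            end=end,
                            motif=motif,
                            n_repeats=n_rep,
                        )
                    )
            i = j + 1  # first position whose period-u match broke
        # dedupe within unit length cannot occur: runs are maximal and disjoint
    accepted.sort(key=lambda loc: (loc.start, loc.unit_length))
    return accepted


def group_compound(loci: Sequence[SsrLocus], max_gap: int = 100) -> list[SsrLocus]:
    """Assign compound-group ids to runs of nearby loci on one transcript.

    Consecutive loci (sorted by start) on the same transcript whose gap
    (next.start - prev.end - 1) is at most ``max_gap`` share a group id;
    singletons keep ``compound_group=None``.  Returns new locus records.
    """
    out = [
        SsrLocus(l.transcript_id, l.start, l.end, l.motif, l.n_repeats)
        for l in sorted(loci, key=lambda l: (l.transcript_id, l.start))
    ]
    group_id = 0
    current: list[SsrLocus] = []

    def flush():
        nonlocal group_id
        if len(current) > 1:
            group_id += 1
            for member in current:
                member.compound_group = group_id
        current.clear()

    for loc in out:
        if current and (
            loc.transcript_id != current[-1].transcript_id
            or loc.start - current[-1].end - 1 > max_gap
        ):
            flush()
        current.append(loc)
    flush()
    return out


@dataclass
class SsrSummary:
    n_sequences: int
    total_bp: int
    n_ssrs: int
    n_ssr_containing: int
    n_multi_ssr: int
    n_compound: int
    by_unit_length: dict[int, int]
    motif_matrix: dict[str, Counter]  # canonical class -> repeat-count histogram


def summarize_ssrs(
    loci: Sequence[SsrLocus], transcripts: Iterable[Transcript]
) -> SsrSummary:
    transcripts = list(transcripts)
    per_transcript = Counter(l.transcript_id for l in loci)
    matrix: dict[str, Counter] = {}
    for l in loci:
        matrix.setdefault(l.canonical_class, Counter())[l.n_repeats] += 1
    return SsrSummary(
        n_sequences=len(transcripts),
        total_bp=sum(len(t) for t in transcripts),
        n_ssrs=len(loci),
        n_ssr_containing=len(per_transcript),
        n_multi_ssr=sum(1 for c in per_transcript.values() if c > 1),
        n_compound=sum(1 for l in loci if l.compound_group is not None),
        by_unit_length=dict(Counter(l.unit_length for l in loci)),
        motif_matrix=matrix,
    )


def design_primers(
    t: Transcript,
    target: tuple[int, int],
    params: SsrPrimerParams | None = None,
) -> PrimerPair | PrimerRejection:
    """Primer pair bracketing a target interval (smallest-product ranking)."""
    return design_primer_pair(
        t.sequence, target[0], target[1], params=params, centered_first=False
    )


def write_ssr_table(
    loci: Sequence[SsrLocus],
    path,
    primers: Optional[dict[int, PrimerPair | PrimerRejection]] = None,
) -> None:
    """MISA-style TSV, optionally with primer columns (keyed by locus index)."""
    with open(path, "w") as fh:
        cols = [
            "ID", "SSR_nr", "type", "SSR", "class", "size", "start", "end", "compound",
        ]
        if primers is not None:
            cols += ["fwd_primer", "rev_primer", "product_size"]
        fh.write("\t".join(cols) + "\n")
        counters: Counter = Counter()
        for i, l in enumerate(loci):
            counters[l.transcript_id] += 1
            row = [
                l.transcript_id,
                str(counters[l.transcript_id]),
                f"p{l.unit_length}",
                f"({l.motif}){l.n_repeats}",
                l.canonical_class,
                str(l.end - l.start + 1),
                str(l.start),
                str(l.end),
                "." if l.compound_group is None else f"c{l.compound_group}",
            ]
            if primers is not None:
                p = primers.get(i)
                if isinstance(p, PrimerPair):
                    row += [p.forward_seq, p.reverse_seq, str(p.product_size)]
                else:
                    why = p.constraint if isinstance(p, PrimerRejection) else "."
                    row += [f"NO_PRIMER:{why}" if why else ".", ".", "."]
            fh.write("\t".join(row) + "\n")
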