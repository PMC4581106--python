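"""Domain types shared across the marker-discovery pipeline.

All coordinates are 1-based inclusive, matching VCF and the tabular reports;
any half-open arithmetic is internal to individual algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .iupac import IUPAC_CODES


@dataclass
class Transcript:
    """A unigene: the coordinate frame for variants, markers and repeats.

    ``orf_start``/``orf_end`` delimit the CDS (1-based inclusive); positions
    before the ORF are 5'UTR, after it 3'UTR.  ``boundary_positions`` are
    transcript coordinates of exon-exon junctions predicted from a
    transcript-to-genome alignment.
    """

    id: str
    sequence: str
    orf_start: Optional[int] = None
    orf_end: Optional[int] = None
    boundary_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = next((i for i, c in enumerate(self.sequence) if c not in IUPAC_CODES), None)
        if bad is not None:
            raise ValueError(
                f"transcript {self.id}: non-IUPAC character "
                f"{self.sequence[bad]!r} at position {bad + 1}"
            )
        if (self.orf_start is None) != (self.orf_end is None):
            raise ValueError(f"transcript {self.id}: partial ORF annotation")
        if self.orf_start is not None:
            if not 1 <= self.orf_start <= self.orf_end <= len(self.sequence):
                raise ValueError(
                    f"transcript {self.id}: ORF {self.orf_start}-{self.orf_end} "
                    f"outside sequence of length {len(self.sequence)}"
                )
        if self.boundary_positions:
            bp = self.boundary_positions
            if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
                raise ValueError(f"transcript {self.id}: boundary positions not strictly increasing")
            if bp[0] < 1 or bp[-1] > len(self.sequence):
                raise ValueError(f"transcript {self.id}: boundary position outside sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_orf(self) -> bool:
        return self.orf_start is not None


@dataclass
class SampleCall:
    """Per-sample genotype at one site: GT allele indices, depth, allele depths."""

    gt: Optional[tuple[int, int]]
    dp: Optional[int] = None
    ad: Optional[tuple[int, ...]] = None

    @property
    def is_missing(self) -> bool:
        return self.gt is None

    @property
    def is_het(self) -> bool:
        return self.gt is not None and self.gt[0] != self.gt[1]


@dataclass
class VariantSite:
    """One SNP locus with its site-level annotations and per-sample calls.

    Site annotations follow the upstream caller's conventions: ``qual`` is
    the Phred-scaled site quality, ``fs`` the Phred-scaled strand-bias
    Fisher p-value, ``qd`` quality-by-depth, ``mq0_fraction`` the share of
    zero-mapping-quality reads.  Absent annotations are ``None`` (treated as
    passing by the filters), never coerced to zero.
    """

    transcript_id: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: Optional[float] = None
    fs: Optional[float] = None
    qd: Optional[float] = None
    mq0_fraction: Optional[float] = None
    total_depth: Optional[int] = None
    samples: dict[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alts = tuple(self.alts)
        if self.ref not in "ACGT" or len(self.ref) != 1:
            raise ValueError(f"{self.transcript_id}:{self.pos}: invalid ref allele {self.ref!r}")
        if not self.alts:
            raise ValueError(f"{self.transcript_id}:{self.pos}: no alt allele")
        for a in self.alts:
            if a not in "ACGT" or len(a) != 1:
                raise ValueError(f"{self.transcript_id}:{self.pos}: invalid alt allele {a!r}")
        if self.ref in self.alts:
            raise ValueError(f"{self.transcript_id}:{self.pos}: ref allele listed among alts")

    @property
    def biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts


@dataclass
class Enzyme:
    """A restriction enzyme: IUPAC recognition site plus top-strand cut offset.

    ``cut_offset`` counts bases from the start of the recognition site to the
    cut on the top strand, so EcoRI G^AATTC has offset 1 and blunt SmaI
    CCC^GGG offset 3.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        self.recognition = self.recognition.upper()
        if len(self.recognition) < 4:
            raise ValueError(f"enzyme {self.name}: recognition site shorter than 4 bp")
        bad = next((c for c in self.recognition if c not in IUPAC_CODES), None)
        if bad is not None:
            raise ValueError(f"enzyme {self.name}: invalid IUPAC letter {bad!r}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(f"enzyme {self.name}: cut offset {self.cut_offset} out of range")

    def __len__(self) -> int:
        return len(self.recognition)


@dataclass
class FilterConfig:
    """Thresholds of the two-round SNP hard-filtering pipeline.

    Round 1 (site annotations): clusters of >=``cluster_size`` SNPs spanning
    <=``cluster_window_bp``; MQ0 fraction, strand bias FS, pooled
    minor-allele read-count frequency, QD, QUAL, total depth.
    Round 2 (transcript context and genotypes): transcript-edge and
    exon-junction exclusion zones, a minimum number of deeply covered
    genotypes, and exclusion of sites heterozygous in the reference sample.
    """

    cluster_size: int = 3
    cluster_window_bp: int = 100
    max_mq0_fraction: float = 0.10
    max_fs: float = 60.0
    min_maf: float = 0.01
    min_qual: float = 11.0
    min_total_depth: int = 11
    min_qd: float = 2.0
    edge_exclusion_bp: int = 30
    boundary_exclusion_bp: int = 30
    min_deep_genotypes: int = 2
    deep_genotype_dp: int = 10
    reference_sample: str = "axillaris"

    def __post_init__(self) -> None:
        numeric = {
            k: v for k, v in self.__dict__.items() if isinstance(v, (int, float))
        }
        neg = [k for k, v in numeric.items() if v < 0]
        if neg:
            raise ValueError(f"negative filter thresholds: {neg}")


@dataclass
class SsrPrimerParams:
    """Constraint ranges for SSR-flanking PCR primer design."""

    min_amplicon: int = 100
    max_amplicon: int = 280
    min_tm: float = 55.0
    max_tm: float = 65.0
    min_length: int = 18
    max_length: int = 28
    min_gc: float = 45.0
    max_gc: float = 55.0

    def __post_init__(self) -> None:
        for lo, hi in (
            (self.min_amplicon, self.max_amplicon),
            (self.min_tm, self.max_tm),
            (self.min_length, self.max_length),
            (self.min_gc, self.max_gc),
        ):
            if lo > hi:
                raise ValueError(f"primer parameter range inverted: {lo} > {hi}")


@dataclass
class PrimerPair:
    """A concrete primer pair on a transcript (1-based inclusive coords)."""

    forward_seq: str
    forward_start: int
    reverse_seq: str
    reverse_end: int  # 3'-most transcript coordinate of the reverse-primer window

    @property
    def product_size(self) -> int:
        return self.reverse_end - self.forward_start + 1
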