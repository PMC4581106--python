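"""Per-site SNP classification.

Covers the descriptive layers computed for each called SNP: which transcript
region it falls in (5'UTR / CDS / 3'UTR relative to the predicted ORF), its
substitution class and transition/transversion status, per-sample zygosity,
pairwise polymorphism status between two samples, the pooled minor-allele
read-count frequency, and IUPAC masking of variant positions (used before
primer design so primers never sit on a polymorphic base).
"""

from __future__ import annotations

from collections import Counter
from enum import Enum
from typing import Optional

from .iupac import code_for
from .model import SampleCall, Transcript, VariantSite


class Region(str, Enum):
    FIVE_UTR = "FIVE_UTR"
    CDS = "CDS"
    THREE_UTR = "THREE_UTR"
    UNKNOWN = "UNKNOWN"


class Zygosity(str, Enum):
    HOM_REF = "HOM_REF"
    HOM_ALT = "HOM_ALT"
    HET = "HET"
    MISSING = "MISSING"


class PairStatus(str, Enum):
    MONOMORPHIC = "MONOMORPHIC"
    POLY_HOM = "POLY_HOM"
    POLY_OTHER = "POLY_OTHER"
    INSUFFICIENT_DEPTH = "INSUFFICIENT_DEPTH"


#: The six unordered substitution classes; A/G and C/T are the transitions.
SUBSTITUTION_CLASSES = ("A/G", "C/T", "A/C", "A/T", "C/G", "G/T")
TRANSITIONS = frozenset({"A/G", "C/T"})


def classify_region(site: VariantSite, t: Transcript) -> Region:
    """5'UTR / CDS / 3'UTR by position relative to the ORF (inclusive ends)."""
    if not 1 <= site.pos <= len(t):
        raise ValueError(
            f"position {site.pos} outside transcript {t.id} (length {len(t)})"
        )
    if not t.has_orf:
        return Region.UNKNOWN
    if site.pos < t.orf_start:
        return Region.FIVE_UTR
    if site.pos <= t.orf_end:
        return Region.CDS
    return Region.THREE_UTR


def classify_substitution(ref: str, alt: str) -> tuple[str, bool]:
    """Unordered substitution class and whether it is a transition."""
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"alleles must be concrete bases, got {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref})")
    cls = "/".join(sorted((ref, alt)))
    return cls, cls in TRANSITIONS


def zygosity_of(call: SampleCall, n_alleles: Optional[int] = None) -> Zygosity:
    if call.gt is None:
        return Zygosity.MISSING
    a, b = call.gt
    if n_alleles is not None and (a >= n_alleles or b >= n_alleles):
        raise ValueError(f"allele index out of range in genotype {call.gt}")
    if a != b:
        return Zygosity.HET
    return Zygosity.HOM_REF if a == 0 else Zygosity.HOM_ALT


def pair_status(
    site: VariantSite, a: str, b: str, min_dp: int = 10
) -> PairStatus:
    """Polymorphism status of one site between two samples.

    A comparison needs both genotypes called with depth strictly greater
    than ``min_dp``; otherwise INSUFFICIENT_DEPTH.  Genotypes are compared
    as allele multisets, so phase and index order are irrelevant.
    """
    for name in (a, b):
        if name not in site.samples:
            raise KeyError(f"unknown sample name {name!r}")
    ca, cb = site.samples[a], site.samples[b]
    if ca.gt is None or cb.gt is None:
        return PairStatus.INSUFFICIENT_DEPTH
    if ca.dp is None or cb.dp is None or ca.dp <= min_dp or cb.dp <= min_dp:
        return PairStatus.INSUFFICIENT_DEPTH
    if sorted(ca.gt) == sorted(cb.gt):
        return PairStatus.MONOMORPHIC
    if ca.gt[0] == ca.gt[1] and cb.gt[0] == cb.gt[1]:
        return PairStatus.POLY_HOM
    return PairStatus.POLY_OTHER


def minor_allele_rc_freq(site: VariantSite) -> float:
    """Pooled minor-allele read-count frequency.

    Allele depths (AD) are summed over all samples; the result is the count
    of the least common *observed* allele divided by the pooled total.
    Alleles with zero pooled reads are ignored; if only one allele was
    observed at all there is no minor-allele evidence and the frequency is
    0.0.  Low values flag calls supported by very few reads, the main
    false-positive signature when the sample panel is too small for a
    genotype-based minor allele frequency to be meaningful.
    """
    n_alleles = len(site.alleles)
    pooled = [0] * n_alleles
    for call in site.samples.values():
        if call.ad:
            for i, c in enumerate(call.ad[:n_alleles]):
                pooled[i] += c
    total = sum(pooled)
    if total == 0:
        raise ValueError(
            f"{site.transcript_id}:{site.pos}: no allele-count evidence"
        )
    observed = [c for c in pooled if c > 0]
    if len(observed) < 2:
        return 0.0
    return min(observed) / total


def mask_variants(t: Transcript, sites: list[VariantSite]) -> str:
    """Replace each variant position with the IUPAC code for {ref} ∪ alts."""
    seq = list(t.sequence)
    for s in sites:
        if s.transcript_id != t.id:
            raise ValueError(f"site {s.transcript_id}:{s.pos} is not on transcript {t.id}")
        base = seq[s.pos - 1]
        if base != s.ref:
            raise ValueError(
                f"{t.id}:{s.pos}: reference allele {s.ref} disagrees with "
                f"transcript base {base}"
            )
        seq[s.pos - 1] = code_for({s.ref, *s.alts})
    return "".join(seq)


class SnpClassification:
    """Full classification record for one site on its transcript."""

    __slots__ = ("site", "region", "substitution_class", "is_transition", "zygosity", "marcf")

    def __init__(self, site: VariantSite, t: Transcript):
        self.site = site
        self.region = classify_region(site, t)
        if site.biallelic:
            self.substitution_class, self.is_transition = classify_substitution(
                site.ref, site.alts[0]
            )
        else:
            self.substitution_class, self.is_transition = None, None
        self.zygosity = {
            name: zygosity_of(call, n_alleles=len(site.alleles))
            for name, call in site.samples.items()
        }
        try:
            self.marcf = minor_allele_rc_freq(site)
        except ValueError:
            self.marcf = None

    @property
    def biallelic(self) -> bool:
        return self.site.biallelic


def classify_sites(
    sites: list[VariantSite], transcripts: dict[str, Transcript]
) -> list[SnpClassification]:
    out = []
    for s in sites:
        t = transcripts.get(s.transcript_id)
        if t is None:
            raise KeyError(f"unknown transcript id {s.transcript_id}")
        out.append(SnpClassification(s, t))
    return out


def write_classification_table(classifications, path) -> None:
    sample_names: list[str] = []
    for c in classifications:
        sample_names = list(c.zygosity)
        break
    with open(path, "w") as fh:
        header = ["transcript_id", "pos", "region", "substitution_class", "is_transition"]
        header += [f"zygosity_{n}" for n in sample_names] + ["marcf"]
        fh.write("\t".join(header) + "\n")
        for c in classifications:
            row = [
                c.site.transcript_id,
                str(c.site.pos),
                c.region.value,
                c.substitution_class or ".",
                "." if c.is_transition is None else str(c.is_transition).lower(),
            ]
            row += [c.zygosity[n].value for n in sample_names]
            row.append("." if c.marcf is None else f"{c.marcf:.4f}")
            fh.write("\t".join(row) + "\n")


def region_counts(classifications) -> Counter:
    return Counter(c.region for c in classifications)
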