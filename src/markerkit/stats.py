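"""Summary statistics over transcripts, SNP classifications and SSR loci.

Reproduces the descriptive tables of a transcriptome marker survey: bp-per-
SNP frequency, transition/transversion tables stratified by region,
per-unigene SNP count distributions, three-way pairwise polymorphism Venn
counts, assembly metrics (N50, size bins) and kb-per-SSR frequency.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .classify import (
    PairStatus,
    Region,
    SnpClassification,
    SUBSTITUTION_CLASSES,
    TRANSITIONS,
)
from .model import Transcript, VariantSite


def _round_half_up(x: float, digits: int = 0) -> float:
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def snp_frequency(total_bp: int, n_snps: int) -> int:
    """bp per SNP: total reference length divided by SNP count, nearest int."""
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    return int(_round_half_up(total_bp / n_snps))


def ssr_frequency(total_bp: int, n_ssrs: int) -> float:
    """kb per SSR, to one decimal."""
    if n_ssrs <= 0:
        raise ValueError("n_ssrs must be positive")
    return _round_half_up(total_bp / n_ssrs / 1000, 1)


# ---------------------------------------------------------------------------
# Ts/Tv

@dataclass
class TsTvStratum:
    counts: dict[str, int]
    percentages: dict[str, float]
    n: int
    tstv: Optional[float]  # None when there are no transversions


@dataclass
class TsTvTable:
    strata: dict[str, TsTvStratum]  # keys: ALL, CDS, FIVE_UTR, THREE_UTR


def _tstv_stratum(classes: list[str]) -> TsTvStratum:
    counts = Counter(classes)
    n = len(classes)
    percentages = {
        c: (_round_half_up(100 * counts.get(c, 0) / n, 1) if n else 0.0)
        for c in SUBSTITUTION_CLASSES
    }
    ts = sum(counts.get(c, 0) for c in TRANSITIONS)
    tv = n - ts
    tstv = _round_half_up(ts / tv, 1) if tv else None
    return TsTvStratum(
        counts={c: counts.get(c, 0) for c in SUBSTITUTION_CLASSES},
        percentages=percentages,
        n=n,
        tstv=tstv,
    )


def tstv_summary(classifications: Sequence[SnpClassification]) -> TsTvTable:
    """Substitution-class table and Ts/Tv per stratum, biallelic sites only."""
    if not classifications:
        raise ValueError("no classifications given")
    biallelic = [c for c in classifications if c.biallelic]
    strata = {"ALL": _tstv_stratum([c.substitution_class for c in biallelic])}
    for region, key in (
        (Region.CDS, "CDS"),
        (Region.FIVE_UTR, "FIVE_UTR"),
        (Region.THREE_UTR, "THREE_UTR"),
    ):
        strata[key] = _tstv_stratum(
            [c.substitution_class for c in biallelic if c.region == region]
        )
    return TsTvTable(strata=strata)


def tstv_from_counts(ts: int, tv: int) -> Optional[float]:
    return _round_half_up(ts / tv, 1) if tv else None


# ---------------------------------------------------------------------------
# Per-unigene SNP distribution

@dataclass
class UnigeneSnpDistribution:
    per_transcript: dict[str, int]        # SNP-containing transcripts only
    histogram: dict[str, int]             # bins "1".."9" and ">=10"
    n_snp_containing: int
    mean_per_transcript: float            # denominator: ALL transcripts
    frac_ge10: float                      # of SNP-containing transcripts


def unigene_distribution(
    sites: Sequence[VariantSite], transcripts: dict[str, Transcript]
) -> UnigeneSnpDistribution:
    counts = Counter(s.transcript_id for s in sites)
    bins: Counter = Counter()
    for c in counts.values():
        bins[">=10" if c >= 10 else str(c)] += 1
    n_containing = len(counts)
    n_all = len(transcripts)
    mean = _round_half_up(len(sites) / n_all, 1) if n_all else 0.0
    frac = (
        _round_half_up(100 * bins.get(">=10", 0) / n_containing, 1)
        if n_containing
        else 0.0
    )
    return UnigeneSnpDistribution(
        per_transcript=dict(counts),
        histogram=dict(bins),
        n_snp_containing=n_containing,
        mean_per_transcript=mean,
        frac_ge10=frac,
    )


# ---------------------------------------------------------------------------
# Three-way Venn of pairwise polymorphism

#: Region keys of a three-set Venn over the pairwise comparisons (AB, AC, BC).
VENN_REGIONS = ("AB_only", "AC_only", "BC_only", "AB_AC", "AB_BC", "AC_BC", "ALL3")


def venn_counts(pair_polymorphic: Iterable[tuple[bool, bool, bool]]) -> dict[str, int]:
    """7-region Venn counts from per-site (AB, AC, BC) polymorphism flags.

    Each site contributes to exactly one region, or to none when it is
    polymorphic in no comparison.
    """
    regions = Counter()
    for ab, ac, bc in pair_polymorphic:
        key = {
            (True, False, False): "AB_only",
            (False, True, False): "AC_only",
            (False, False, True): "BC_only",
            (True, True, False): "AB_AC",
            (True, False, True): "AB_BC",
            (False, True, True): "AC_BC",
            (True, True, True): "ALL3",
        }.get((ab, ac, bc))
        if key:
            regions[key] += 1
    return {r: regions.get(r, 0) for r in VENN_REGIONS}


def pairwise_polymorphism_flags(
    sites: Sequence[VariantSite],
    pairs: Sequence[tuple[str, str]],
    min_dp: int = 10,
    homozygous_only: bool = False,
) -> list[tuple[bool, bool, bool]]:
    """Per-site polymorphism flags for three sample pairs.

    ``homozygous_only`` restricts to fixed differences (both samples
    homozygous for different alleles); otherwise any polymorphic comparison
    counts, including those involving heterozygotes.
    """
    from .classify import pair_status  # local import avoids cycle at module load

    if len(pairs) != 3:
        raise ValueError("exactly three sample pairs required")
    wanted = (
        {PairStatus.POLY_HOM}
        if homozygous_only
        else {PairStatus.POLY_HOM, PairStatus.POLY_OTHER}
    )
    flags = []
    for s in sites:
        flags.append(
            tuple(pair_status(s, a, b, min_dp=min_dp) in wanted for a, b in pairs)
        )
    return flags


# ---------------------------------------------------------------------------
# Assembly metrics

@dataclass
class AssemblyMetrics:
    n_transcripts: int
    total_bp: int
    mean_length: float
    n50: int
    size_bins: dict[str, int]  # "500-1000", "1001-1500", ... last bin open


def assembly_metrics(
    transcripts: Iterable[Transcript], bin_width: int = 500, first_edge: int = 500
) -> AssemblyMetrics:
    """N50, mean length, total bp and a size-bin histogram.

    N50 is the largest observed length L such that transcripts of length
    >= L hold at least half the total bases (descending-cumulative rule).
    """
    lengths = sorted((len(t) for t in transcripts), reverse=True)
    if not lengths:
        raise ValueError("no transcripts")
    total = sum(lengths)
    cum = 0
    n50 = lengths[-1]
    for length in lengths:
        cum += length
        if cum >= total / 2:
            n50 = length
            break
    bins: Counter = Counter()
    for length in lengths:
        if length < first_edge:
            bins[f"<{first_edge}"] += 1
        else:
            # bin 0 covers [first_edge, first_edge+width]; bin k>0 covers
            # (first_edge+k*width, first_edge+(k+1)*width]
            k = max(0, (length - first_edge - 1) // bin_width)
            lo = first_edge + k * bin_width + (0 if k == 0 else 1)
            hi = first_edge + (k + 1) * bin_width
            bins[f"{lo}-{hi}"] += 1
    return AssemblyMetrics(
        n_transcripts=len(lengths),
        total_bp=total,
        mean_length=_round_half_up(total / len(lengths), 1),
        n50=n50,
        size_bins=dict(bins),
    )
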