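"""Two-round hard filtering of transcriptome SNP calls.

Round 1 screens site-level annotations from the upstream caller: SNP
clusters (>= 3 calls spanning <= 100 bp), excess zero-mapping-quality reads,
strand bias (FS), pooled minor-allele read-count frequency, quality-by-depth,
site quality and total depth.  Round 2 applies transcript-context rules:
exclusion zones at transcript edges and around exon-exon junctions, a
minimum number of deeply covered genotypes, and removal of sites called
heterozygous in the reference sample (whose accession the reference
transcriptome was assembled from, so a heterozygous call there signals a
collapsed paralog or mapping artifact rather than an inter-species SNP).

A missing annotation passes its filter: the thresholds presume the caller
emitted the annotation, and absence is not evidence of failure.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .classify import minor_allele_rc_freq
from .model import FilterConfig, Transcript, VariantSite

#: All failure codes a verdict may carry.
REASON_CODES = (
    "CLUSTER",
    "MQ0",
    "STRAND_BIAS",
    "LOW_MAF",
    "LOW_QD",
    "LOW_QUAL",
    "LOW_DEPTH",
    "EDGE",
    "BOUNDARY",
    "INSUFFICIENT_DEEP_GENOTYPES",
    "REF_HET",
)

ROUND1_REASONS = frozenset(
    {"CLUSTER", "MQ0", "STRAND_BIAS", "LOW_MAF", "LOW_QD", "LOW_QUAL", "LOW_DEPTH"}
)
ROUND2_REASONS = frozenset({"EDGE", "BOUNDARY", "INSUFFICIENT_DEEP_GENOTYPES", "REF_HET"})


@dataclass
class FilterVerdict:
    site: VariantSite
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.reasons

    def add(self, reason: str) -> None:
        if reason not in REASON_CODES:
            raise ValueError(f"unknown filter reason {reason!r}")
        if reason not in self.reasons:
            self.reasons.append(reason)


def _check_sorted(sites: Sequence[VariantSite]) -> None:
    keys = [(s.transcript_id, s.pos) for s in sites]
    if keys != sorted(keys):
        raise ValueError("sites must be sorted by (transcript_id, pos)")


def remove_clusters(
    sites: Sequence[VariantSite], size: int = 3, window_bp: int = 100
) -> set[int]:
    """Indices of sites belonging to a cluster of >= ``size`` SNPs within ``window_bp``.

    A site fails iff it is a member of at least one group of ``size``
    consecutive sites on the same transcript whose inclusive span
    (max pos - min pos + 1) is <= ``window_bp``.
    """
    _check_sorted(sites)
    failing: set[int] = set()
    # group indices by transcript, order preserved
    by_transcript: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        by_transcript.setdefault(s.transcript_id, []).append(i)
    for idxs in by_transcript.values():
        for w in range(len(idxs) - size + 1):
            window = idxs[w : w + size]
            span = sites[window[-1]].pos - sites[window[0]].pos + 1
            if span <= window_bp:
                failing.update(window)
    return failing


def filter_round1(
    sites: Sequence[VariantSite], cfg: FilterConfig | None = None
) -> list[FilterVerdict]:
    """Annotation-level filters; one verdict per input site, in input order."""
    cfg = cfg or FilterConfig()
    _check_sorted(sites)
    verdicts = [FilterVerdict(site=s) for s in sites]
    for v in verdicts:
        s = v.site
        if s.mq0_fraction is not None and s.mq0_fraction > cfg.max_mq0_fraction:
            v.add("MQ0")
        if s.fs is not None and s.fs > cfg.max_fs:
            v.add("STRAND_BIAS")
        if any(c.ad for c in s.samples.values()):
            if minor_allele_rc_freq(s) < cfg.min_maf:
                v.add("LOW_MAF")
        if s.qd is not None and s.qd < cfg.min_qd:
            v.add("LOW_QD")
        if s.qual is not None and s.qual < cfg.min_qual:
            v.add("LOW_QUAL")
        if s.total_depth is not None and s.total_depth < cfg.min_total_depth:
            v.add("LOW_DEPTH")
    # cluster rule over the survivors of the threshold filters
    survivors = [i for i, v in enumerate(verdicts) if v.passed]
    sub = [sites[i] for i in survivors]
    for j in remove_clusters(sub, cfg.cluster_size, cfg.cluster_window_bp):
        verdicts[survivors[j]].add("CLUSTER")
    return verdicts


def filter_round2(
    sites: Sequence[VariantSite],
    transcripts: dict[str, Transcript],
    cfg: FilterConfig | None = None,
) -> list[FilterVerdict]:
    """Transcript-context and genotype-support filters."""
    cfg = cfg or FilterConfig()
    verdicts = [FilterVerdict(site=s) for s in sites]
    for v in verdicts:
        s = v.site
        t = transcripts.get(s.transcript_id)
        if t is None:
            raise KeyError(f"unknown transcript id {s.transcript_id}")
        if s.pos <= cfg.edge_exclusion_bp or s.pos > len(t) - cfg.edge_exclusion_bp:
            v.add("EDGE")
        if any(abs(s.pos - b) <= cfg.boundary_exclusion_bp for b in t.boundary_positions):
            v.add("BOUNDARY")
        deep = sum(
            1
            for c in s.samples.values()
            if c.dp is not None and c.dp > cfg.deep_genotype_dp
        )
        if deep < cfg.min_deep_genotypes:
            v.add("INSUFFICIENT_DEEP_GENOTYPES")
        ref_call = s.samples.get(cfg.reference_sample)
        if ref_call is not None and ref_call.is_het:
            v.add("REF_HET")
    return verdicts


@dataclass
class FilterReport:
    """Per-reason failure counts plus pass/fail totals for one pipeline run."""

    n_input: int
    n_passed: int
    reason_counts: Counter

    def to_rows(self) -> list[tuple[str, int]]:
        rows = [("INPUT", self.n_input), ("PASSED", self.n_passed)]
        rows += [(r, self.reason_counts.get(r, 0)) for r in REASON_CODES]
        return rows


def run_filter_pipeline(
    sites: Sequence[VariantSite],
    transcripts: dict[str, Transcript] | Iterable[Transcript],
    cfg: FilterConfig | None = None,
) -> tuple[list[VariantSite], list[FilterVerdict], FilterReport]:
    """Both filter rounds; returns (passing sites, all verdicts, report).

    Reasons from both rounds are accumulated on each verdict rather than
    short-circuited, so the report is complete.  The pipeline is idempotent:
    re-running on the passing set removes nothing.
    """
    cfg = cfg or FilterConfig()
    if not isinstance(transcripts, dict):
        transcripts = {t.id: t for t in transcripts}
    verdicts = filter_round1(sites, cfg)
    for v1, v2 in zip(verdicts, filter_round2(sites, transcripts, cfg)):
        for r in v2.reasons:
            v1.add(r)
    passing = [v.site for v in verdicts if v.passed]
    report = FilterReport(
        n_input=len(verdicts),
        n_passed=len(passing),
        reason_counts=Counter(r for v in verdicts for r in v.reasons),
    )
    return passing, verdicts, report


def write_verdict_report(verdicts: Sequence[FilterVerdict], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tpos\tref\talt\tfilter\n")
        for v in verdicts:
            s = v.site
            status = "PASS" if v.passed else ";".join(v.reasons)
            fh.write(f"{s.transcript_id}\t{s.pos}\t{s.ref}\t{','.join(s.alts)}\t{status}\n")
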