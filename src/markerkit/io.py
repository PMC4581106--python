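"""Readers and writers for the pipeline's file formats.

FASTA (transcripts) goes through Biopython, VCF input through cyvcf2.  The
small tab-separated side tables (ORF coordinates, exon-junction positions,
restriction enzymes, genome-alignment blocks) are plain TSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .iupac import is_valid_iupac
from .model import Enzyme, SampleCall, Transcript, VariantSite

#: The 20 bundled restriction enzymes, by name.
DEFAULT_ENZYME_NAMES = (
    "AluI", "ApaI", "BamHI", "BbrPI", "BfrI", "ClaI", "DdeI", "DpnII",
    "DraI", "EcoRI", "HaeIII", "HincII", "HinfI", "HpaI", "PvuII", "RsaI",
    "SacI", "Sau3AI", "SmaI", "TaqI",
)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[Transcript]:
    """Load a transcriptome FASTA into :class:`Transcript` records.

    Sequences are upper-cased; record order is preserved.  Duplicate ids,
    empty files and non-IUPAC characters are hard errors.
    """
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        transcripts.append(Transcript(id=rec.id, sequence=str(rec.seq)))
    if not transcripts:
        raise ValueError(f"no FASTA records in {path}")
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# VCF

def _opt(value):
    return None if value is None else float(value)


def read_vcf(path, snps_only: bool = True) -> tuple[list[VariantSite], int]:
    """Read multi-sample variant calls.

    Returns ``(sites, n_skipped)`` where ``n_skipped`` counts records dropped
    because an allele is longer than one base (indels / MNPs) when
    ``snps_only`` is set.  Missing INFO annotations are stored as ``None``,
    never as zero.  The MQ0 fraction is taken from ``MQ0F`` when present,
    else derived as ``MQ0/DP`` when both are present, else left absent.
    """
    vcf = VCF(str(path))
    sample_names = list(vcf.samples)
    sites: list[VariantSite] = []
    skipped = 0
    for n_rec, rec in enumerate(vcf, start=1):
        try:
            alts = tuple(rec.ALT)
            if len(rec.REF) != 1 or any(len(a) != 1 for a in alts):
                if snps_only:
                    skipped += 1
                    continue
            mq0f = _opt(rec.INFO.get("MQ0F"))
            if mq0f is None:
                mq0 = rec.INFO.get("MQ0")
                dp_info = rec.INFO.get("DP")
                if mq0 is not None and dp_info:
                    mq0f = float(mq0) / float(dp_info)
            try:
                dp_arr = rec.format("DP")
            except KeyError:
                dp_arr = None
            try:
                ad_arr = rec.format("AD")
            except KeyError:
                ad_arr = None
            samples: dict[str, SampleCall] = {}
            for i, name in enumerate(sample_names):
                g = rec.genotypes[i]
                gt = None
                if len(g) >= 3 and g[0] >= 0 and g[1] >= 0:
                    gt = (g[0], g[1])
                dp = None
                if dp_arr is not None and dp_arr[i][0] >= 0:
                    dp = int(dp_arr[i][0])
                ad = None
                if ad_arr is not None and ad_arr[i][0] >= 0:
                    ad = tuple(int(x) for x in ad_arr[i])
                samples[name] = SampleCall(gt=gt, dp=dp, ad=ad)
            dp_site = rec.INFO.get("DP")
            sites.append(
                VariantSite(
                    transcript_id=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alts=alts,
                    qual=_opt(rec.QUAL),
                    fs=_opt(rec.INFO.get("FS")),
                    qd=_opt(rec.INFO.get("QD")),
                    mq0_fraction=mq0f,
                    total_depth=None if dp_site is None else int(dp_site),
                    samples=samples,
                )
            )
        except Exception as exc:  # noqa: BLE001 - annotate record number
            raise ValueError(f"malformed VCF record {n_rec} in {path}: {exc}") from exc
    return sites, skipped


def write_vcf(
    sites: Iterable[VariantSite],
    path,
    sample_names: Optional[list[str]] = None,
    transcripts: Optional[Iterable[Transcript]] = None,
    filters: Optional[dict[int, str]] = None,
) -> None:
    """Serialize sites to a VCF v4.2 text file.

    ``filters`` maps a site's index in ``sites`` to a FILTER string
    (``PASS`` or semicolon-joined reason codes); unlisted sites get ``.``.
    """
    sites = list(sites)
    if sample_names is None:
        sample_names = list(sites[0].samples) if sites else []
    lines = ["##fileformat=VCFv4.2"]
    if transcripts is not None:
        for t in transcripts:
            lines.append(f"##contig=<ID={t.id},length={len(t)}>")
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand-bias Fisher p-value">',
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=MQ0F,Number=1,Type=Float,Description="Fraction of zero-MQ reads">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names),
    ]
    for i, s in enumerate(sites):
        info = []
        if s.total_depth is not None:
            info.append(f"DP={s.total_depth}")
        if s.fs is not None:
            info.append(f"FS={s.fs:g}")
        if s.qd is not None:
            info.append(f"QD={s.qd:g}")
        if s.mq0_fraction is not None:
            info.append(f"MQ0F={s.mq0_fraction:g}")
        cols = [
            s.transcript_id,
            str(s.pos),
            ".",
            s.ref,
            ",".join(s.alts),
            "." if s.qual is None else f"{s.qual:g}",
            (filters or {}).get(i, "."),
            ";".join(info) or ".",
            "GT:DP:AD",
        ]
        for name in sample_names:
            call = s.samples.get(name)
            if call is None or call.gt is None:
                gt = "./."
            else:
                gt = f"{call.gt[0]}/{call.gt[1]}"
            dp = "." if call is None or call.dp is None else str(call.dp)
            ad = "." if call is None or call.ad is None else ",".join(map(str, call.ad))
            cols.append(f"{gt}:{dp}:{ad}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Side tables

def read_orf_table(path) -> dict[str, tuple[int, int]]:
    """TSV of transcript_id, orf_start, orf_end (1-based inclusive)."""
    orfs: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            tid, start, end = row[0], int(row[1]), int(row[2])
            orfs[tid] = (start, end)
    return orfs


def read_boundary_file(path) -> dict[str, list[int]]:
    """TSV of transcript_id, boundary_pos: exon-junction transcript positions."""
    bounds: dict[str, list[int]] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            bounds.setdefault(row[0], []).append(int(row[1]))
    for v in bounds.values():
        v.sort()
    return bounds


def annotate_transcripts(
    transcripts: list[Transcript],
    orfs: Optional[dict[str, tuple[int, int]]] = None,
    boundaries: Optional[dict[str, list[int]]] = None,
) -> list[Transcript]:
    """Attach ORF and exon-junction annotations, returning new records."""
    out = []
    for t in transcripts:
        orf = (orfs or {}).get(t.id)
        out.append(
            Transcript(
                id=t.id,
                sequence=t.sequence,
                orf_start=orf[0] if orf else None,
                orf_end=orf[1] if orf else None,
                boundary_positions=(boundaries or {}).get(t.id, []),
            )
        )
    return out


@dataclass
class AlignmentBlock:
    """One gapless transcript-to-genome alignment block (all coords 1-based)."""

    transcript_id: str
    t_start: int
    t_end: int
    scaffold: str
    g_start: int
    g_end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.t_end - self.t_start != self.g_end - self.g_start:
            raise ValueError(
                f"block {self.transcript_id}:{self.t_start}-{self.t_end}: "
                "transcript and genome spans differ in length"
            )


def read_alignment_blocks(path) -> dict[str, list[AlignmentBlock]]:
    """TSV: transcript_id, t_start, t_end, scaffold, g_start, g_end, strand."""
    blocks: dict[str, list[AlignmentBlock]] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            b = AlignmentBlock(
                row[0], int(row[1]), int(row[2]), row[3], int(row[4]), int(row[5]), row[6]
            )
            blocks.setdefault(b.transcript_id, []).append(b)
    return blocks


# ---------------------------------------------------------------------------
# Enzyme table

def load_enzyme_table(path=None) -> list[Enzyme]:
    """Load a TSV enzyme table (name, recognition, cut_offset).

    With no path, the bundled table of 20 commonly used enzymes is returned.
    """
    if path is None:
        source = resources.files("markerkit").joinpath("data/enzymes.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    enzymes = []
    for row in csv.reader(text.splitlines(), delimiter="\t"):
        if not row or row[0].startswith("#"):
            continue
        name, recognition, cut = row[0], row[1], int(row[2])
        if not is_valid_iupac(recognition.upper()):
            raise ValueError(f"enzyme {name}: invalid IUPAC recognition {recognition!r}")
        enzymes.append(Enzyme(name=name, recognition=recognition, cut_offset=cut))
    return enzymes
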