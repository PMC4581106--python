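"""Deterministic synthetic transcriptome + variant-panel generator.

Emulates the statistical structure of a three-sample transcriptome variant
survey so that every pipeline stage is testable without external data:

* transcripts with ORF annotations (5'UTR / CDS / 3'UTR partition), a
  subset carrying exon-junction positions and a subset lacking an ORF;
* SNPs placed per region at configurable densities, substitution classes
  drawn to hit a target Ts/Tv in expectation, per-sample zygosity mixes,
  and a read-depth / allele-count model;
* planted SSR loci whose flanks are scrubbed of accidental repeats, so the
  detector must recover exactly the planted coordinates;
* planted CAPS contexts carrying a restriction site in exactly one allele;
* planted filter violations, one transcript per violation event, each
  failing the filter pipeline for exactly the reasons in the truth table.

Every random draw comes from named child streams of the master seed, so
adding a feature family never perturbs the draws of another, and a fixed
seed reproduces the panel byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .caps import differential_enzymes
from .iupac import IUPAC_CODES
from .classify import classify_substitution
from .io import load_enzyme_table, write_fasta, write_vcf
from .model import Enzyme, SampleCall, Transcript, VariantSite
from .ssr import DEFAULT_THRESHOLDS, SsrLocus, canonical_class, detect_ssrs

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}

#: Default planted SSR motifs x repeat counts (50 loci: 20 di, 15 tri,
#: 5 tetra, 5 penta, 5 hexa), spanning several canonical classes.
DEFAULT_PLANTED_SSRS: tuple[tuple[str, int], ...] = (
    tuple(("AG", 6 + i % 5) for i in range(8))
    + tuple(("AC", 6 + i % 4) for i in range(6))
    + tuple(("AT", 6 + i % 3) for i in range(6))
    + tuple(("AAG", 5 + i % 4) for i in range(6))
    + tuple(("ATC", 5 + i % 3) for i in range(5))
    + tuple(("AAC", 5 + i % 3) for i in range(4))
    + tuple(("AAAG", 5 + i % 2) for i in range(5))
    + tuple(("AAAAG", 5) for _ in range(5))
    + tuple(("AAGGCC", 5) for _ in range(5))
)

_VIOLATION_REASONS = (
    "CLUSTER", "MQ0", "STRAND_BIAS", "LOW_MAF", "LOW_QD", "LOW_QUAL",
    "LOW_DEPTH", "EDGE", "BOUNDARY", "INSUFFICIENT_DEEP_GENOTYPES", "REF_HET",
)


@dataclass
class SimSpec:
    """Study conditions of one synthetic panel."""

    seed: int = 1
    n_transcripts: int = 200
    min_length: int = 2000
    max_length: int = 4000
    gc_content: float = 0.5
    orf_fraction: float = 0.6          # of transcript length
    five_utr_share: float = 0.33       # of the non-ORF remainder
    no_orf_fraction: float = 0.05      # transcripts lacking ORF annotation
    boundary_fraction: float = 0.3     # transcripts with exon junctions
    snp_density_per_kb: dict = field(
        default_factory=lambda: {"FIVE_UTR": 7.8, "CDS": 10.4, "THREE_UTR": 8.6}
    )
    target_tstv: float = 1.7
    sample_names: tuple[str, ...] = ("axillaris", "exserta", "integrifolia")
    # (p_hom_ref, p_hom_alt, p_het) for each non-reference sample
    zygosity_mix: dict = field(
        default_factory=lambda: {
            "exserta": (0.30, 0.65, 0.05),
            "integrifolia": (0.20, 0.30, 0.50),
        }
    )
    mean_depth: float = 100.0
    planted_ssrs: tuple[tuple[str, int], ...] = DEFAULT_PLANTED_SSRS
    planted_caps: Optional[tuple[str, ...]] = None  # enzyme names; None = all 20
    planted_violations: dict = field(
        default_factory=lambda: {r: 1 for r in _VIOLATION_REASONS}
    )

    def __post_init__(self) -> None:
        for name, mix in self.zygosity_mix.items():
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"zygosity mix for {name} does not sum to 1")
        if any(d < 0 for d in self.snp_density_per_kb.values()):
            raise ValueError("negative SNP density")


@dataclass
class TruthSnp:
    transcript_id: str
    pos: int
    ref: str
    alt: str
    region: str
    substitution_class: str
    is_transition: bool
    kind: str                      # NORMAL / CAPS / VIOLATION
    reasons: tuple[str, ...] = ()  # expected filter-failure reasons


@dataclass
class TruthCaps:
    transcript_id: str
    pos: int
    enzyme: str
    allele_cut: str


@dataclass
class SimResult:
    spec: SimSpec
    transcripts: list[Transcript]
    sites: list[VariantSite]       # sorted by (transcript_id, pos)
    truth_snps: list[TruthSnp]
    truth_ssrs: list[SsrLocus]
    truth_caps: list[TruthCaps]

    @property
    def transcript_index(self) -> dict[str, Transcript]:
        return {t.id: t for t in self.transcripts}


# ---------------------------------------------------------------------------
# SSR planting

def plant_ssr(
    sequence: str,
    motif: str,
    n_repeats: int,
    at: int,
    thresholds: Optional[dict[int, int]] = None,
    assert_detectable: bool = True,
) -> tuple[str, tuple[int, int]]:
    """Overwrite ``sequence`` at 1-based ``at`` with ``motif`` x ``n_repeats``.

    The bases immediately flanking the insertion are adjusted to break the
    repeat period, so a detector finds the locus at exactly the returned
    (start, end) coordinates.  Length is preserved.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    u = len(motif)
    if assert_detectable and n_repeats < thresholds.get(u, 10**9):
        raise ValueError(
            f"({motif}){n_repeats} is below the detection threshold for unit length {u}"
        )
    span = u * n_repeats
    if at < 2 or at + span > len(sequence):  # keep one flanking base on each side
        raise ValueError(f"SSR ({motif}){n_repeats} at {at} does not fit with flanks")
    seq = list(sequence)
    seq[at - 1 : at - 1 + span] = motif * n_repeats
    # break the period on both sides: position before the run must differ
    # from the base one unit into the run; position after it from one unit back
    before = at - 2
    if seq[before] == seq[before + u]:
        seq[before] = next(b for b in _BASES if b != seq[before + u])
    after = at - 1 + span
    if seq[after] == seq[after - u]:
        seq[after] = next(b for b in _BASES if b != seq[after - u])
    return "".join(seq), (at, at + span - 1)


def _scrub_accidental_repeats(
    seq: str,
    tid: str,
    planted: list[tuple[int, int, str, int]],
    rng: np.random.Generator,
    max_iter: int = 60,
) -> str:
    """Randomize bases of any detected repeat not matching a planted locus.

    ``planted`` rows are (start, end, motif, n_repeats).  Bases inside
    planted spans are never touched.
    """
    planted_set = {p for p in planted}
    spans = [(s, e) for s, e, _, _ in planted]
    for _ in range(max_iter):
        t = Transcript(id=tid, sequence=seq)
        found = {
            (l.start, l.end, l.motif, l.n_repeats) for l in detect_ssrs(t)
        }
        extras = found - planted_set
        missing = planted_set - found
        if not extras and not missing:
            return seq
        chars = list(seq)
        dirty = extras | {
            # a missing planted locus means something merged into/over it:
            # rewrite its immediate flanks
            (max(1, s - 3), min(len(seq), e + 3), m, n)
            for s, e, m, n in missing
        }
        for s, e, _, _ in sorted(dirty):
            for i in range(s - 1, e):
                if any(ps - 1 <= i <= pe - 1 for ps, pe in spans):
                    continue
                chars[i] = _BASES[rng.integers(4)]
        # re-plant any missing locus verbatim (its span bases are canonical)
        seq = "".join(chars)
        for s, e, m, n in sorted(missing):
            seq, _coords = plant_ssr(seq, m, n, s)
    raise RuntimeError(f"could not scrub accidental repeats on {tid}")


# ---------------------------------------------------------------------------
# main generator

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(_BASES))[rng.choice(4, size=n, p=p)])


def _draw_alt(ref: str, rng: np.random.Generator, p_transition: float) -> str:
    if rng.random() < p_transition:
        return _TRANSITION[ref]
    return _TRANSVERSIONS[ref][rng.integers(2)]


def _clean_annotations(rng: np.random.Generator) -> dict:
    return {
        "qual": float(np.round(rng.uniform(50, 2000), 2)),
        "fs": float(np.round(rng.uniform(0, 10), 3)),
        "qd": float(np.round(rng.uniform(5, 30), 2)),
        "mq0_fraction": 0.0,
    }


def _genotype_calls(
    spec: SimSpec,
    ref_idx: int,
    rng: np.random.Generator,
    force: Optional[dict[str, tuple[int, int]]] = None,
) -> dict[str, SampleCall]:
    """Draw per-sample genotypes/depths/allele counts for a biallelic site.

    The reference sample is homozygous-reference unless overridden via
    ``force``; at least one other sample carries the alternate allele.
    """
    force = force or {}
    ref_sample = spec.sample_names[0]
    for _ in range(100):
        gts: dict[str, tuple[int, int]] = {}
        for name in spec.sample_names:
            if name in force:
                gts[name] = force[name]
            elif name == ref_sample:
                gts[name] = (0, 0)
            else:
                p_rr, p_aa, p_het = spec.zygosity_mix[name]
                u = rng.random()
                gts[name] = (0, 0) if u < p_rr else (1, 1) if u < p_rr + p_aa else (0, 1)
        if any(1 in g for g in gts.values()):
            break
    calls = {}
    for name in spec.sample_names:
        dp = max(12, int(rng.poisson(spec.mean_depth)))
        g = gts[name]
        if g == (0, 0):
            ad = (dp, 0)
        elif g == (1, 1):
            ad = (0, dp)
        else:
            a = int(rng.binomial(dp, 0.5))
            a = min(max(a, 2), dp - 2)  # keep both alleles visibly supported
            ad = (dp - a, a)
        calls[name] = SampleCall(gt=g, dp=dp, ad=ad)
    return calls


def _region_of(pos: int, t: Transcript) -> str:
    if not t.has_orf:
        return "UNKNOWN"
    if pos < t.orf_start:
        return "FIVE_UTR"
    if pos <= t.orf_end:
        return "CDS"
    return "THREE_UTR"


def _lattice_positions(
    lo: int, hi: int, count: int, rng: np.random.Generator, min_gap: int = 51
) -> list[int]:
    """Jittered even placement of ``count`` positions in [lo, hi], gaps >= min_gap."""
    width = hi - lo
    if width <= 0 or count <= 0:
        return []
    count = min(count, max(0, width // min_gap))
    if count == 0:
        return []
    step = width / count
    out = []
    for i in range(count):
        jitter_halfwidth = max(0.0, (step - min_gap) / 2)
        j = rng.uniform(-jitter_halfwidth, jitter_halfwidth)
        pos = int(round(lo + (i + 0.5) * step + j))
        out.append(min(hi, max(lo, pos)))
    return sorted(set(out))


def generate(spec: SimSpec) -> SimResult:
    """Build the full synthetic panel described by ``spec``."""
    n_violation_events = sum(spec.planted_violations.values())
    if spec.n_transcripts < n_violation_events + 20:
        raise ValueError("too few transcripts for the planted features")
    if spec.min_length < 400:
        raise ValueError("transcripts shorter than 400 bp cannot host markers")
    for motif, n_rep in spec.planted_ssrs:
        if len(motif) * n_rep + 200 > spec.min_length:
            raise ValueError(f"planted SSR ({motif}){n_rep} cannot fit any transcript")

    enzymes = {e.name: e for e in load_enzyme_table()}
    caps_names = spec.planted_caps or tuple(sorted(enzymes))
    for name in caps_names:
        if name not in enzymes:
            raise ValueError(f"unknown enzyme {name!r} in planted CAPS list")

    master = np.random.SeedSequence(spec.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("sequence", "ssr", "caps", "snp", "depth", "violation"),
            master.spawn(6),
        )
    }

    rng_seq = streams["sequence"]
    width = len(str(spec.n_transcripts))
    transcripts: list[Transcript] = []
    lengths = rng_seq.integers(spec.min_length, spec.max_length + 1, size=spec.n_transcripts)
    no_orf = rng_seq.random(spec.n_transcripts) < spec.no_orf_fraction
    has_boundary = rng_seq.random(spec.n_transcripts) < spec.boundary_fraction
    raw: list[dict] = []
    for i in range(spec.n_transcripts):
        L = int(lengths[i])
        seq = _random_seq(rng_seq, L, spec.gc_content)
        orf = None
        if not no_orf[i]:
            orf_len = int(round(spec.orf_fraction * L))
            five = int(round(spec.five_utr_share * (L - orf_len)))
            orf = (five + 1, five + orf_len)
        bounds: list[int] = []
        if has_boundary[i]:
            n_b = int(rng_seq.integers(1, 3))
            bounds = sorted(
                {int(rng_seq.integers(200, L - 200)) for _ in range(n_b)}
            )
        raw.append(
            {"id": f"t{i + 1:0{width}d}", "seq": seq, "orf": orf, "bounds": bounds}
        )

    # --- violation transcripts: the first n_violation_events, one event each
    violation_plan: list[tuple[str, int]] = []  # (reason, transcript index)
    idx = 0
    for reason in _VIOLATION_REASONS:
        for _ in range(spec.planted_violations.get(reason, 0)):
            violation_plan.append((reason, idx))
            idx += 1
    normal_indices = list(range(idx, spec.n_transcripts))
    # BOUNDARY events need a junction on their transcript
    for reason, i in violation_plan:
        if reason == "BOUNDARY" and not raw[i]["bounds"]:
            raw[i]["bounds"] = [len(raw[i]["seq"]) // 2]

    # --- plant SSRs on normal transcripts (some get two; a few pairs compound)
    rng_ssr = streams["ssr"]
    truth_ssrs: list[SsrLocus] = []
    planted_by_t: dict[int, list[tuple[int, int, str, int]]] = {}
    ssr_hosts: list[int] = []
    k = 0
    ssr_list = list(spec.planted_ssrs)
    while k < len(ssr_list):
        # every 5th host receives two loci (exercises multi-SSR / compound stats)
        host = normal_indices[len(ssr_hosts) % len(normal_indices)]
        ssr_hosts.append(host)
        two = (len(ssr_hosts) % 5 == 0) and k + 1 < len(ssr_list)
        seq = raw[host]["seq"]
        entries = ssr_list[k : k + (2 if two else 1)]
        k += len(entries)
        cursor = 220
        for j, (motif, n_rep) in enumerate(entries):
            span = len(motif) * n_rep
            hi = len(seq) - span - 220
            if j == 0 and hi > cursor:
                at = int(rng_ssr.integers(cursor, hi))
            else:
                at = cursor  # second locus lands 29 bp after the first: compound
            seq, (s, e) = plant_ssr(seq, motif, n_rep, at)
            planted_by_t.setdefault(host, []).append((s, e, motif, n_rep))
            truth_ssrs.append(
                SsrLocus(raw[host]["id"], s, e, motif, n_rep)
            )
            cursor = e + 30  # second locus lands close: compound-eligible
        raw[host]["seq"] = seq

    # scrub accidental repeats everywhere (violation transcripts included,
    # so SSR totals over the panel equal the planted truth exactly)
    for i in range(spec.n_transcripts):
        raw[i]["seq"] = _scrub_accidental_repeats(
            raw[i]["seq"], raw[i]["id"], planted_by_t.get(i, []), rng_ssr
        )

    # --- plant CAPS contexts on normal transcripts without SSRs
    rng_caps = streams["caps"]
    caps_hosts = [i for i in normal_indices if i not in planted_by_t]
    if len(caps_hosts) < len(caps_names):
        raise ValueError("not enough SSR-free transcripts for planted CAPS contexts")
    truth_caps: list[TruthCaps] = []
    caps_sites: list[tuple[int, int, str, str]] = []  # (t_index, pos, ref, alt)
    for enzyme_name, host in zip(caps_names, caps_hosts):
        e = enzymes[enzyme_name]
        placed = False
        for _attempt in range(200):
            seq = raw[host]["seq"]
            L = len(seq)
            site_start = int(rng_caps.integers(250, L - 250 - len(e)))
            # resolve any degenerate recognition letter to a random member base
            concrete = "".join(
                sorted(IUPAC_CODES[p])[rng_caps.integers(len(IUPAC_CODES[p]))]
                for p in e.recognition
            )
            offset = int(rng_caps.integers(len(e)))
            snp_pos = site_start + offset  # 1-based transcript position
            ref_base = concrete[offset]
            allowed = [
                b for b in _BASES
                if b != ref_base and b not in IUPAC_CODES[e.recognition[offset]]
            ]
            if not allowed:
                continue  # degenerate letter admits every base; pick a new offset
            alt_base = allowed[int(rng_caps.integers(len(allowed)))]
            candidate = seq[: site_start - 1] + concrete + seq[site_start - 1 + len(e) :]
            t = Transcript(id=raw[host]["id"], sequence=candidate, orf_start=None)
            vs = VariantSite(
                transcript_id=t.id, pos=snp_pos, ref=ref_base, alts=(alt_base,)
            )
            diags = differential_enzymes(vs, t, [e])
            if (e, "REF") not in [(d[0], d[1]) for d in diags]:
                continue
            # the context must not disturb SSR truth on this transcript
            if detect_ssrs(t):
                continue
            raw[host]["seq"] = candidate
            truth_caps.append(TruthCaps(t.id, snp_pos, e.name, "REF"))
            caps_sites.append((host, snp_pos, ref_base, alt_base))
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place CAPS context for {enzyme_name}")

    # --- freeze transcripts
    for r in raw:
        orf = r["orf"]
        transcripts.append(
            Transcript(
                id=r["id"],
                sequence=r["seq"],
                orf_start=orf[0] if orf else None,
                orf_end=orf[1] if orf else None,
                boundary_positions=r["bounds"],
            )
        )
    t_by_index = transcripts

    # --- SNPs
    rng_snp = streams["snp"]
    rng_depth = streams["depth"]
    p_transition = spec.target_tstv / (1 + spec.target_tstv)
    sites: list[VariantSite] = []
    truth_snps: list[TruthSnp] = []

    def add_site(
        t: Transcript,
        pos: int,
        kind: str,
        reasons: tuple[str, ...] = (),
        ref: Optional[str] = None,
        alt: Optional[str] = None,
        calls: Optional[dict[str, SampleCall]] = None,
        ann_override: Optional[dict] = None,
        total_depth: Optional[int] = None,
    ) -> VariantSite:
        ref = ref or t.sequence[pos - 1]
        if ref == "N":
            raise ValueError("SNP on an N base")
        alt = alt or _draw_alt(ref, rng_snp, p_transition)
        calls = calls or _genotype_calls(spec, 0, rng_depth)
        ann = _clean_annotations(rng_depth)
        if ann_override:
            ann.update(ann_override)
        site = VariantSite(
            transcript_id=t.id,
            pos=pos,
            ref=ref,
            alts=(alt,),
            qual=ann["qual"],
            fs=ann["fs"],
            qd=ann["qd"],
            mq0_fraction=ann["mq0_fraction"],
            total_depth=(
                total_depth
                if total_depth is not None
                else sum(c.dp for c in calls.values())
            ),
            samples=calls,
        )
        sites.append(site)
        cls, is_ts = classify_substitution(ref, alt)
        truth_snps.append(
            TruthSnp(
                transcript_id=t.id,
                pos=pos,
                ref=ref,
                alt=alt,
                region=_region_of(pos, t),
                substitution_class=cls,
                is_transition=is_ts,
                kind=kind,
                reasons=reasons,
            )
        )
        return site

    # planted CAPS SNPs (clean: they must pass filtering)
    caps_positions: dict[int, list[int]] = {}
    for host, pos, ref_base, alt_base in caps_sites:
        add_site(t_by_index[host], pos, "CAPS", ref=ref_base, alt=alt_base)
        caps_positions.setdefault(host, []).append(pos)

    # bulk SNPs on normal transcripts
    for i in normal_indices:
        t = t_by_index[i]
        L = len(t)
        exp = sum(
            spec.snp_density_per_kb.get(region, 0.0) * _region_len(t, region) / 1000
            for region in ("FIVE_UTR", "CDS", "THREE_UTR", "UNKNOWN")
        )
        count = int(rng_snp.poisson(exp))
        taken = sorted(caps_positions.get(i, []))
        positions = _lattice_positions(31, L - 30, count, rng_snp)
        for pos in positions:
            if any(abs(pos - b) <= 31 for b in t.boundary_positions):
                continue
            if any(abs(pos - q) <= 50 for q in taken):
                continue
            if t.sequence[pos - 1] == "N":
                continue
            add_site(t, pos, "NORMAL")
            taken.append(pos)

    # --- planted filter violations, one dedicated transcript per event
    rng_v = streams["violation"]
    ref_sample = spec.sample_names[0]
    for reason, i in violation_plan:
        t = t_by_index[i]
        L = len(t)
        mid = L // 2
        if reason == "CLUSTER":
            for pos in (mid, mid + 40, mid + 80):
                add_site(t, pos, "VIOLATION", reasons=("CLUSTER",))
        elif reason == "MQ0":
            add_site(t, mid, "VIOLATION", reasons=("MQ0",), ann_override={"mq0_fraction": 0.25})
        elif reason == "STRAND_BIAS":
            add_site(t, mid, "VIOLATION", reasons=("STRAND_BIAS",), ann_override={"fs": 75.0})
        elif reason == "LOW_MAF":
            calls = {}
            for j, name in enumerate(spec.sample_names):
                dp = max(12, int(rng_v.poisson(spec.mean_depth)))
                ad = (dp - 1, 1) if j == len(spec.sample_names) - 1 else (dp, 0)
                calls[name] = SampleCall(gt=(0, 0), dp=dp, ad=ad)
            add_site(t, mid, "VIOLATION", reasons=("LOW_MAF",), calls=calls)
        elif reason == "LOW_QD":
            add_site(t, mid, "VIOLATION", reasons=("LOW_QD",), ann_override={"qd": 1.0})
        elif reason == "LOW_QUAL":
            add_site(t, mid, "VIOLATION", reasons=("LOW_QUAL",), ann_override={"qual": 8.0})
        elif reason == "LOW_DEPTH":
            # a consistent VCF cannot have DP < 11 while two samples exceed 10,
            # so this plant necessarily also lacks deep genotypes
            calls = {
                name: SampleCall(gt=(0, 1) if j > 0 else (0, 0), dp=d, ad=(d - d // 2, d // 2))
                for j, (name, d) in enumerate(zip(spec.sample_names, (4, 3, 3)))
            }
            add_site(
                t, mid, "VIOLATION",
                reasons=("LOW_DEPTH", "INSUFFICIENT_DEEP_GENOTYPES"),
                calls=calls, total_depth=10,
            )
        elif reason == "EDGE":
            add_site(t, 15, "VIOLATION", reasons=("EDGE",))
        elif reason == "BOUNDARY":
            b = t.boundary_positions[0]
            add_site(t, b + 10, "VIOLATION", reasons=("BOUNDARY",))
        elif reason == "INSUFFICIENT_DEEP_GENOTYPES":
            calls = {}
            for name, d in zip(spec.sample_names, (50, 9, 8)):
                gt = (0, 0) if name == ref_sample else (1, 1)
                ad = (d, 0) if gt == (0, 0) else (0, d)
                calls[name] = SampleCall(gt=gt, dp=d, ad=ad)
            add_site(
                t, mid, "VIOLATION",
                reasons=("INSUFFICIENT_DEEP_GENOTYPES",), calls=calls,
            )
        elif reason == "REF_HET":
            force = {ref_sample: (0, 1)}
            calls = _genotype_calls(spec, 0, rng_v, force=force)
            add_site(t, mid, "VIOLATION", reasons=("REF_HET",), calls=calls)

    order = sorted(range(len(sites)), key=lambda j: (sites[j].transcript_id, sites[j].pos))
    sites = [sites[j] for j in order]
    truth_snps = [truth_snps[j] for j in order]
    truth_ssrs.sort(key=lambda l: (l.transcript_id, l.start))
    truth_caps.sort(key=lambda c: (c.transcript_id, c.pos))
    return SimResult(
        spec=spec,
        transcripts=transcripts,
        sites=sites,
        truth_snps=truth_snps,
        truth_ssrs=truth_ssrs,
        truth_caps=truth_caps,
    )


def _region_len(t: Transcript, region: str) -> int:
    if not t.has_orf:
        return len(t) if region == "UNKNOWN" else 0
    if region == "FIVE_UTR":
        return t.orf_start - 1
    if region == "CDS":
        return t.orf_end - t.orf_start + 1
    if region == "THREE_UTR":
        return len(t) - t.orf_end
    return 0


# ---------------------------------------------------------------------------
# serialization

def write_panel(result: SimResult, out_dir) -> dict[str, Path]:
    """Write FASTA / ORF table / boundary file / VCF / truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "transcripts.fasta",
        "orf": out / "orf.tsv",
        "boundaries": out / "boundaries.tsv",
        "vcf": out / "snps.vcf",
        "truth_snps": out / "truth_snps.tsv",
        "truth_ssrs": out / "truth_ssrs.tsv",
        "truth_caps": out / "truth_caps.tsv",
    }
    write_fasta(result.transcripts, paths["fasta"])
    with open(paths["orf"], "w") as fh:
        for t in result.transcripts:
            if t.has_orf:
                fh.write(f"{t.id}\t{t.orf_start}\t{t.orf_end}\n")
    with open(paths["boundaries"], "w") as fh:
        for t in result.transcripts:
            for b in t.boundary_positions:
                fh.write(f"{t.id}\t{b}\n")
    write_vcf(
        result.sites,
        paths["vcf"],
        sample_names=list(result.spec.sample_names),
        transcripts=result.transcripts,
    )
    with open(paths["truth_snps"], "w") as fh:
        fh.write(
            "transcript_id\tpos\tref\talt\tregion\tsubstitution_class\t"
            "is_transition\tkind\treasons\n"
        )
        for s in result.truth_snps:
            fh.write(
                f"{s.transcript_id}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.region}\t"
                f"{s.substitution_class}\t{str(s.is_transition).lower()}\t"
                f"{s.kind}\t{','.join(s.reasons) or '.'}\n"
            )
    with open(paths["truth_ssrs"], "w") as fh:
        fh.write("transcript_id\tstart\tend\tmotif\tn_repeats\tcanonical_class\n")
        for l in result.truth_ssrs:
            fh.write(
                f"{l.transcript_id}\t{l.start}\t{l.end}\t{l.motif}\t"
                f"{l.n_repeats}\t{canonical_class(l.motif)}\n"
            )
    with open(paths["truth_caps"], "w") as fh:
        fh.write("transcript_id\tpos\tenzyme\tallele_cut\n")
        for c in result.truth_caps:
            fh.write(f"{c.transcript_id}\t{c.pos}\t{c.enzyme}\t{c.allele_cut}\n")
    return paths
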