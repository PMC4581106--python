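# Methods

## Scope and data model

`markerkit` implements the computation that sits *after* assembly and
variant calling in a transcriptome marker survey: hard-filtering multi-sample
SNP calls against a unigene reference, classifying and summarizing the
surviving sites, and converting them into CAPS and SSR markers.  Read QC,
assembly, read mapping and the variant caller itself are upstream concerns;
their outputs (FASTA, annotated VCF, ORF table, exon-junction table,
transcript-to-genome alignment blocks) are this package's input contract.

All coordinates are 1-based inclusive, matching VCF; internal half-open
arithmetic never leaks into reports.  A site's annotations (QUAL, FS, QD,
MQ0 fraction, DP) are stored as absent when the caller did not emit them,
and an absent annotation passes its filter: a missing value is not evidence
of a defect.  The MQ0 fraction is read from `MQ0F`, else derived as
`MQ0/DP` when both are present, else treated as absent.

## Two-round SNP filtering

Round 1 (site annotations), with defaults:

| rule | threshold | failure code |
|---|---|---|
| ≥3 SNPs spanning ≤100 bp (inclusive span) | 3 / 100 bp | `CLUSTER` |
| zero-mapping-quality read fraction | > 0.10 | `MQ0` |
| strand-bias FS (Phred-scaled Fisher p) | > 60 | `STRAND_BIAS` |
| pooled minor-allele read-count frequency | < 0.01 | `LOW_MAF` |
| quality by depth | < 2.0 | `LOW_QD` |
| site quality | < 11 | `LOW_QUAL` |
| total depth | < 11 | `LOW_DEPTH` |

Round 2 (transcript context): first/last 30 bp of the transcript (`EDGE`),
±30 bp around any exon-exon junction (`BOUNDARY`), fewer than 2 samples
with depth strictly > 10 (`INSUFFICIENT_DEEP_GENOTYPES`), and a
heterozygous call in the reference sample (`REF_HET`) — the reference
accession is the one the transcriptome was assembled from, so heterozygosity
there flags collapsed paralogs or mapping artifacts.

Design choices where the procedure was genuinely open:

* **Cluster semantics.**  "Three SNPs within 100 bp" is implemented as the
  standard cluster filter: every member of any window of 3 consecutive
  same-transcript sites whose inclusive span (max − min + 1) is ≤ 100 bp is
  removed; the tie case span == 100 fails.  Membership in an *arbitrary*
  triple within 100 bp is equivalent to membership in a consecutive one,
  which the brute-force oracle test exploits.
* **Cluster evaluation order.**  The cluster rule is evaluated over the
  survivors of the other round-1 threshold filters; reasons from both
  rounds are accumulated rather than short-circuited, so the verdict report
  is complete and the pipeline is idempotent (re-running on the passing set
  removes nothing).
* **Minor allele frequency.**  With only three samples a genotype-based MAF
  is quantized to multiples of 1/6 and a 1 % threshold would be vacuous, so
  the filter uses the *pooled read-count* minor-allele frequency: allele
  depths are summed over samples and the least common observed allele's
  share is taken.  With a single observed allele the frequency is defined
  as 0 (no minor-allele evidence).
* **Depth rule.**  "Greater than 10" is strict (> 10, not ≥ 10).

## Classification and summaries

Region is 5′UTR (pos < ORF start), CDS (inclusive ORF span), 3′UTR
(pos > ORF end), or UNKNOWN when the transcript has no ORF annotation.
Substitution classes are unordered pairs; A/G and C/T are the transitions,
and Ts/Tv is their count ratio over the four transversion classes, reported
to one decimal and computed over biallelic sites only.  Pairwise
polymorphism between two samples requires both genotypes called at depth
> 10 (`INSUFFICIENT_DEPTH` otherwise), distinguishes fixed homozygous
differences (`POLY_HOM`) from comparisons involving a heterozygote
(`POLY_OTHER`), and feeds the 7-region three-way Venn.  SNP frequency is
total reference bp divided by SNP count (nearest integer, "1 SNP per N
bp"); the mean SNPs-per-transcript denominator is *all* transcripts, not
only SNP-containing ones.  N50 follows the descending-cumulative rule (the
largest observed length L such that transcripts ≥ L hold at least half the
total bases).  Percentages use half-up rounding to one decimal.

## CAPS prediction

An enzyme is diagnostic for a biallelic SNP when some recognition-site
match *covering the SNP position* exists in exactly one of the two allele
windows (±10 bp flank, truncated at transcript ends; the flank exceeds the
longest bundled recognition site).  Requiring the match to cover the SNP is
the standard CAPS definition — site-count differences elsewhere in the
amplicon would be co-segregating accidents, not allele reads.  Matching is
IUPAC-aware (HincII GTYRAC, DdeI CTNAG, HinfI GANTC); an `N` in the subject
sequence matches only a literal `N` in a pattern, so masked regions never
produce phantom sites.  All 20 bundled recognition sites are palindromic,
so forward-strand scanning is complete; SacI (GAGCT^C) and AluI (AG^CT)
illustrate nested recognition — every AluI site inside a SacI site is
reported for both enzymes, but only matches covering the SNP make a marker.

The amplicon is placed by a deterministic primer search: the SNP is
centred as nearly as primer feasibility allows, ties broken toward smaller
amplicons (maximizing both cut-fragment sizes), within 200–400 bp.
Digestion ladders are predicted per allele per enzyme; cut positions are
`match_start − 1 + cut_offset`, cuts falling on amplicon ends produce no
fragment, and each ladder sums exactly to the amplicon length.  A
configurable scorability screen (`scorability_min_diff`, default 0 = off)
rejects markers whose two ladders differ by fewer bp than a gel can
resolve; the default reproduces the enzyme-presence-only behaviour, the
screen is the corrective extension.  Transcript coordinates project to
genome scaffolds affinely within gapless alignment blocks, counting from
the block's genome end on the minus strand; positions in no block raise
`UNMAPPED`.

A "marker" is reported per (locus, enzyme) row with a per-locus rollup,
since one locus can be diagnostic for several enzymes.

## SSR detection and primers

Maximal perfect tandem repeats of primitive 2–6 bp units, thresholds
6/5/5/5/5 repeats for di- through hexanucleotides; mononucleotide runs are
out of scope.  A repeat region is reported once, at its smallest primitive
unit ((AT)₆ is never also (ATAT)₃), and a longer-unit repeat wholly
contained in a reported locus is suppressed, matching the non-redundant
reporting convention of microsatellite scanners.  Trailing partial units
are truncated.  Motif classes are canonical under rotation and reverse
complementation; the representative is the lexicographic minimum over both
orbits and the label is `rep/revcomp(rep)` — except when the representative
is its own reverse complement (AT, CG), where the label's second half is
the complementary strand read in the same orientation (AT/TA, CG/GC), as
the survey tables print it.  Two loci on one transcript with an inter-locus
gap ≤ 100 bp (the conventional interruption distance) form a compound SSR.

Primer pairs bracket the target: the forward primer lies entirely upstream,
the reverse primer is the reverse complement of a window entirely
downstream, and both must satisfy length 18–28 nt, GC 45–55 % and Tm
55–65 °C, with the product inside 100–280 bp (SSR) or 200–400 bp (CAPS).
Tm uses the GC-fraction formula `64.9 + 41·(nGC − 16.4)/len` — the
protocols constrain the acceptance window, not the thermodynamic model, and
a parameter-free formula keeps results reproducible.  Note the constraint
set is jointly restrictive: at 50 % GC the formula forces primers of
~21–28 nt.  The search is deterministic (SSR: smallest product, then most
centred, then leftmost; CAPS: most centred first) and a rejection names the
binding constraint (`SPACE`, `GC` or `TM`).

## Synthetic panels

The generator emulates a three-sample variant survey at desk scale.
Defaults: 200 transcripts of 2000–4000 bp (uniform) at 50 % GC; 60 % of
each transcript is ORF with the 5′UTR taking 33 % of the remainder; 5 % of
transcripts lack an ORF (region UNKNOWN) and 30 % carry 1–2 exon
junctions.  Per-region SNP densities (7.8/10.4/8.6 per kb for
5′UTR/CDS/3′UTR) put ~5000 SNPs on the panel; substitution classes are
drawn to a target Ts/Tv of 1.7 in expectation (transition probability
Ts/(1+Ts)).  The reference sample is homozygous-reference; the two other
samples draw genotypes from per-sample zygosity mixes (one mostly
homozygous-alternate with 5 % heterozygotes, one 50 % heterozygous,
emulating a self-incompatible outcrosser), with redraws guaranteeing at
least one alternate-allele carrier.  Depths are Poisson(100); heterozygous
allele depths are Binomial(dp, 0.5) clamped so both alleles stay visibly
supported.

Fifty SSR loci (20 di, 15 tri, 5 each tetra/penta/hexa) and twenty
CAPS contexts (one per bundled enzyme) are planted on disjoint transcripts.
SSR flanks are period-broken at both ends and *all* transcripts are
scrubbed of accidental above-threshold repeats (detected loci outside
planted spans are re-randomized until the detector reports exactly the
planted set), so exact-recovery tests are sound.  Planted CAPS contexts
write a concrete instance of the recognition site into the reference and
pick an alternate base outside the degeneracy set at the SNP offset,
re-verified through the diagnostic caller before acceptance.  Eleven filter
violations (one per reason code) are planted on dedicated transcripts so no
violation contaminates a neighbour; site positions elsewhere keep pairwise
gaps ≥ 51 bp, which provably prevents accidental 3-in-100 clusters.  One
coupling is unavoidable: a site with total depth < 11 cannot have two
samples above depth 10, so the `LOW_DEPTH` plant also carries
`INSUFFICIENT_DEEP_GENOTYPES` in its truth row.

Randomness uses one child stream per feature family (sequence, SSR, CAPS,
SNP, depth, violation) spawned from the master seed, so adding a family
never perturbs another's draws; a fixed seed reproduces all output files
byte-identically, independent of Python hash randomization.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level errors and coverage heterogeneity
along transcripts, misassembly and collapsed paralogs, imperfect or
interrupted repeats, indels and multi-nucleotide variants, linkage between
nearby sites, and realistic codon/GC structure in CDS regions.  Recovery
rates of 100 % on planted truth certify the algorithms' correctness, not
the false-negative rate of the upstream caller on biological data.

## Problem sizes and numerics

The default panel (200 transcripts, ~5000 SNPs, 50 SSRs, 20 CAPS contexts)
is the package's chosen study scale: large enough that the Ts/Tv draw
concentrates within ±0.15 of target and every reason code and motif class
is exercised, small enough to regenerate in seconds.  Survey-scale counts
(tens of millions of bp) enter only through the printed-arithmetic worked
examples, whose inputs are the published totals themselves.  Ratios are
rounded half-up to one decimal at the reporting boundary only; a stratum
with zero transversions reports Ts/Tv as undefined rather than a number.

## Known limitations

No dCAPS (mismatch-primer) design, methylation sensitivity, or
multi-primer-pair ranking; no mononucleotide or approximate SSRs; no
nearest-neighbour Tm or secondary-structure screening; no codon-level
synonymous/non-synonymous annotation; VCF round-tripping preserves the
fields the pipeline consumes (GT/DP/AD, QUAL, FS, QD, MQ0F, DP), not
arbitrary caller annotations.
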