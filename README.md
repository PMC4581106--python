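# markerkit

Post-assembly molecular-marker discovery for non-model plant transcriptomes.

Given a reference transcriptome (one unigene per FASTA record), per-transcript
ORF annotations, and multi-sample SNP calls (VCF with per-sample GT/DP/AD and
site-level QUAL/FS/QD/MQ0 annotations), `markerkit` reproduces the
computational stages that turn raw variant calls into usable markers:

1. **Two-round SNP hard filtering** — round 1 screens caller annotations
   (clusters of ≥3 SNPs within 100 bp, MQ0 fraction > 0.10, strand-bias
   FS > 60, pooled minor-allele read-count frequency < 0.01, QD < 2,
   QUAL < 11, depth < 11); round 2 applies transcript-context rules
   (first/last 30 bp of a transcript, ±30 bp around exon–exon junctions,
   fewer than two genotypes with depth > 10, heterozygous call in the
   reference accession).
2. **SNP classification & statistics** — 5′UTR/CDS/3′UTR region, the six
   substitution classes and the transition/transversion ratio
   Ts/Tv = (A/G + C/T) / (A/C + A/T + C/G + G/T), per-sample zygosity,
   pairwise polymorphism between samples (3-way Venn), minor-allele
   read-count frequency, bp-per-SNP and kb-per-SSR frequencies, per-unigene
   SNP distributions, assembly N50 and size bins, and IUPAC masking of
   variant positions.
3. **CAPS marker prediction** — a SNP becomes a cleaved-amplified-
   polymorphic-sequence marker when a restriction enzyme's recognition site
   *overlapping the SNP* exists for exactly one allele.  A bundled table of
   20 commonly used enzymes (AluI … TaqI) is scanned over both allele
   contexts; one primer pair is placed so the 200–400 bp amplicon centres
   the SNP, and the digestion fragment ladder of each allele is predicted so
   unscorable markers (ladders differing by a few bp) can be screened out.
4. **SSR (microsatellite) detection and primer design** — maximal perfect
   tandem repeats of primitive 2–6 bp units at minimum repeat counts
   6/5/5/5/5 (di → hexa), motif canonicalization into rotation/reverse-
   complement classes (GA, AG, TC, CT → AG/CT), compound-SSR grouping, and
   flanking primers under hard constraints (product 100–280 bp, primer
   18–28 nt, GC 45–55 %, Tm 55–65 °C).
5. **Synthetic panels** — a deterministic generator builds three-sample
   transcriptome variant panels with planted SSR loci, planted
   CAPS-diagnostic contexts, planted filter violations and a target Ts/Tv,
   together with exact truth tables, so the whole pipeline is testable
   without any sequencing data.

## Worked example

Run the full pipeline on a simulated panel (200 transcripts, ~5000 SNPs,
50 SSR loci, 20 CAPS contexts):

```sh
markerkit all --seed 1 --out-dir work
```

which logs, per stage:

```
[simulate] 200 transcripts, 5228 SNPs
[filter] 5215/5228 sites pass
[classify] classified 5215 sites
[stats] N50 3197, 5215 SNPs
[caps] 1167/5215 sites yield CAPS markers
[ssr] 50 SSRs on 42 transcripts
```

Reading the numbers: of 5228 simulated SNP calls, 13 are removed by the
two-round hard filter (each simulated with exactly one class of defect —
strand bias, low quality, transcript-edge position, …).  Of the 5215
passing biallelic SNPs, 1167 sit inside a restriction site present in
exactly one allele and admit a 200–400 bp amplicon, so they can be scored
as CAPS markers; each output row carries the diagnostic enzyme, the primer
pair and both predicted fragment ladders.  The SSR stage recovers all 50
planted microsatellites with exact coordinates and designs flanking primers
for them.  Every stage writes TSV/JSON reports plus a `manifest.json` that
echoes the configuration and input checksums needed to reproduce the run.

The same operations are importable as a library, e.g.:

```python
from markerkit import detect_ssrs, differential_enzymes, load_enzyme_table
```

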