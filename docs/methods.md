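# Methods

## Homology-projected gene calling

A *template* is a reference gene or pseudogene model with one or more CDS
isoforms. Spliced alignment of templates onto a target genome is consumed,
not performed: the pipeline starts from mapped exon chains (0-based
half-open intervals in ascending genomic order, plus strand and a mapping
identity), the point at which the bespoke logic begins. When a template
maps to several loci, the locus with the highest identity wins; exact ties
go to the lexicographically smallest (chromosome, start).

The putative full-length CDS is the concatenation of the mapped exon
substrings, reverse-complemented as a unit on the minus strand. Diagnosis:

- `orf_shift` if the length is not a multiple of 3 (detail = residue mod 3);
- `nonsense` if a stop codon occurs before the final codon (detail = 1-based
  codon ordinal), after recoding TGA at annotated selenocysteine ordinals
  (1-based) to selenocysteine;
- `nonsense` also covers the stop-loss corner case (length divisible by 3,
  no internal stop, final codon not a stop), which the tri-state diagnosis
  has no separate name for; the simulator never emits it;
- `intact` otherwise.

Read support: a loss-of-function mutation counts only when **every** base of
every mapped exon has short-read depth ≥ `min_coverage` (default 10, reads
assumed mapped with no mismatches or gaps; the coverage track is the
caller's responsibility). A chromosome absent from the track reads as depth
zero — absence of evidence is not support. The decision table:

| diagnosis | support        | template   | call                     |
|-----------|----------------|------------|--------------------------|
| intact    | not applicable | gene       | intact_gene              |
| intact    | supported      | pseudogene | gene_from_pseudogene     |
| intact    | unsupported    | pseudogene | pseudogene (stays)       |
| LOF       | supported      | either     | pseudogene               |
| LOF       | unsupported    | gene       | partially_supported_gene |
| LOF       | unsupported    | pseudogene | pseudogene (stays)       |

A pseudogene template is resurrected only when its intact ORF is fully
read-supported; an intact but unsupported projection stays a pseudogene.
Isoforms are diagnosed independently and a template is intact if *any*
isoform reconstructs an intact CDS (the permissive reading; logged).

`frameshift_impact(cds_len, del_start, del_end) = cds_len/3 −
⌈del_start/3⌉ + 1` counts codons from the one containing the first deleted
base through the final codon — the arithmetic behind the mitochondrial ND5
worked example (1,818-bp CDS, 5-bp deletion at 1,552–1,556 → 89 codons).

## Transcript classification

Transcripts overlapping any annotated gene/pseudogene/ncRNA span by ≥ 1 bp
(exon-level, strand-blind by default; both choices configurable) are set
aside. The rest: longest ORF ≥ `min_orf` (300 nt) → coding NAG candidate;
else length > `lncrna_min_len` (1,000 nt) → lncRNA; else unclassified. An
ORF is ATG-initiated, stop-terminated (stop included in its length), on the
sense strand of the (oriented, genome-guided) transcript. "Lacking an ORF"
for lncRNAs is read as "no ORF reaching the coding threshold": a literal
zero-ORF rule would let 9-nt incidental ORFs disqualify real lncRNAs.

## NAG consolidation, triage, clustering

Pairwise identity is `1 − d/max(|a|,|b|)` with `d` the unit-cost edit
distance (edlib): symmetric, 1 iff identical, and deterministic — the
matches-over-columns ratio of a specific optimal alignment is path-dependent
among co-optimal unit-cost alignments, so the edit-distance form is used
everywhere (dedup and the > 98.5 % rule, which is strict: exactly 0.985
does not merge). Deduplication is greedy longest-first: each sequence joins
the first representative it exceeds the threshold with, else founds a
cluster; representatives are therefore the longest members and pairwise
≤ threshold.

Triage by hit taxonomy: any *Gallus gallus* hit outside the reference
assembly tags → gNAG; else any hit → oNAG; else novel. Family size is the
raw hit count (the query itself is not added).

The presence matrix codes intact (including partially supported) → 1,
unmapped → 0, supported loss of function → −1, per NAG per genome.
Two-way clustering uses Ward linkage on Euclidean distances of the
{−1,0,1} vectors (rows and columns independently; both configurable);
deterministic given the input, and a constant matrix is rejected.

## Genomic context statistics

Chromosome classes follow the chicken karyotype: chr1–5 + Z macro,
chr6–13 + W middle, chr14–39 micro, everything else unplaced. Windows tile
each chromosome from 0 in `window` (1 Mbp) steps, last window shorter; a
feature belongs to the window/bin containing its **start** (no double
counting). G/C excludes N from numerator and denominator and is undefined
(not zero) on all-N input. Bin profiles cut each chromosome into 100
equal portions (last absorbs the remainder) and average per-Mbp NAG
density and G/C across chromosomes of a group. Flanks are the two
`flank`-bp intervals left and right of a gene span, clipped to the
chromosome, with no masking of neighbouring genes. Group comparisons use
the Wilcoxon rank-sum test (exact for small tie-free samples, normal
approximation otherwise) by default and Welch's t on request; two
identical constant groups get p = 1 by convention and are flagged. G4
frequency is canonical-motif count (`G{3,}([ACGT]{1,7}G{3,}){3}`,
non-overlapping leftmost-greedy, both strands, N never matches) per kbp;
density per length rather than per-gene counts is what the flank/body
comparisons use.

## Expression

"Expressed anywhere" defaults to any strictly positive value (threshold =
smallest positive float; configurable — presence counts depend on it). Tau
is Σ(1 − x_i/x_max)/(n−1), scale-invariant, undefined for all-zero rows.
RT-qPCR abundance is 2^−(Ct_target − Ct_reference); summaries average
technical replicates within each biological replicate, then biological
replicates, with the SD taken over all individual measurements (the
3 × 5 replicate design).

## Synthetic cohorts

The simulator emulates the study conditions at desk scale. Defaults: four
genomes; per genome one macro (1.2 Mbp, G/C 0.40), one middle (0.7 Mbp,
0.42), one micro (0.4 Mbp, 0.53) chromosome and one unplaced contig
(0.2 Mbp, 0.45) — the class means of the real karyotype; a linear
subtelomeric G/C ramp of amplitude 0.10 over the outer 10 %; 300 templates
(4 % pseudogene models, of which half are planted resurrected) of 110–360
codons in 2–5 exons, a few carrying selenocysteine UGA codons; per genome
and gene-template 10 % planted nonsense and 10 % frameshift mutations, 80 %
of them fully read-supported (depth 30) and the rest given one base at
depth 9; 100 NAGs mixed 60/30/10 gNAG/oNAG/novel, each present (0.7),
pseudogenized (0.1) or absent elsewhere and always present in its home
genome; decoy transcripts (overlapping, ORF-free long, ORF-free short)
exercise the transcript-verdict partition. Bases are independent
Bernoulli draws with position-dependent G/C probability — no dinucleotide
structure, which is sufficient for every statistic the pipeline computes
but means the background G4 rate is lower than in real genomes. Coverage
is emitted directly as depths (no read simulation). NAG chromosome choice
is biased toward high-G/C classes; the window-level generator (Gaussian
G/C, Poisson counts with log-linear G/C dependence) is the instrument for
correlation experiments, and a paired generator plants G4/G·C enrichment
in NAG bodies and flanks (5-kb flanks at test scale) for the direction
comparisons. All randomness flows from the single config seed; equal
configs give byte-identical emitted files.

Passing the planted-truth suites shows the decision logic is exact under
noise-free mappings and idealized coverage; it does not certify behaviour
under alignment error, fragmented assemblies or expression noise, which
the simulator deliberately does not model.

## Numerical and scale choices

Internal coordinates are 0-based half-open everywhere; GFF3 I/O converts
to/from 1-based inclusive at exactly one point per direction. Percentages
in reports use half-up decimal rounding at the printed precision. Test and
acceptance problem sizes (10-Mbp cohorts, 200-window correlations over 100
seeds, 200 genes/group with 5-kb flanks, ≥ 1,000 randomized oracle cases
per primitive) were chosen as the smallest scales at which the planted
effects are unambiguous.

## Known limitations

- The "absent template" threshold (`min_map_identity`) defaults to 0: any
  mapping counts, as the study leaves the cutoff unstated.
- Stop-loss CDSs are folded into the nonsense class (see above).
- The overlap test defaults to exon-level and strand-blind; span-level and
  stranded variants are config switches, not separately validated rules.
- lncRNA calls depend on the adopted "no qualifying ORF" reading.
- Greedy deduplication is order-dependent by design (longest-first,
  deterministic); it can split what single-linkage would merge, never the
  reverse.
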