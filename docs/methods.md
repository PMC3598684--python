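# Methods

## Scope and model

`pistarv` reproduces, as a library, the analysis chain used in de novo
transcriptome studies of phosphate starvation in non-model plants: a
redundant assembler output is reduced to a non-redundant transcript set,
short-read pairs are mapped back to it, expression is quantified as RPKM
from uniquely-aligned reads, differential expression between control and
−P treatments is called with a G-test under Benjamini–Hochberg FDR
control, orthologs in a second species are found by reciprocal best hits,
and promoters are scanned for the P1BS element. The package does not
assemble reads (assembler outputs are consumed, not produced) and does
not run BLAST-scale database searches (12-column hit tables are inputs).

## Synthetic experiment

The generator emulates the study design end to end: two tissues (root,
shoot) × two treatments (control, −P) × three replicates = twelve
libraries of 100-bp paired-end reads. Its defaults are the conditions the
workflow was designed for:

| parameter | default | rationale |
|---|---|---|
| read length | 100 bp | Illumina HiSeq PE reads of the target studies |
| insert length | 260 ± 30 bp (normal, clipped to [read, transcript]) | reported average insert of such libraries |
| transcript lengths | log-normal, ln-mean 6.55, ln-sd 0.7, floor 200 bp | median ≈ 700 bp, typical of plant de novo assemblies |
| transcripts | 2,000 | demo scale: every stage exercised in ~2 min on one CPU |
| library depth | 50,000 pairs | same |
| error rate | 0.005/base substitutions | low-error Illumina regime |
| DE fraction | 10%, fold U(2, 8), half up / half down per tissue | detectable but not dominant signal |
| containment fraction | 30% of transcripts yield a contained fragment (30–90% span) at identity 0.95 | the fragment carries an *exact* number of substitutions so the planted identity is exact |
| isoform fraction | 10% of loci yield 1–3 variants | shared core (≤ 52% of the transcript) plus a unique flank at 80% of the core |
| ortholog fraction | 50%, identity U(65, 95)%, coverage U(65, 100)% | all planted pairs pass the 60/60 filter; tests plant weaker pairs explicitly |
| promoters | 1,000 bp, half carry 1–3 planted GNATATNC octamers | background rejection-sampled motif-free, so truth is exhaustive |

Determinism: one global seed derives a named, independent stream per
purpose (transcriptome, DE labels, each library, contigs, cross-species,
promoters) via CRC-keyed `numpy` generators, so any component can be
regenerated alone and whole runs are byte-identical.

Expression model: per-transcript expected pair count ∝ baseline abundance
(log-normal) × length, multiplied by the true fold under −P, normalized
to the library depth; realized counts are Poisson. Mate 1 is the 5' read
of the fragment, mate 2 the reverse complement of its 3' end (FR
chemistry).

What the generator does *not* emulate — and hence what passing tests do
not show about real data: biological replicate dispersion (counts are
Poisson around a fixed expectation), indel sequencing errors and quality
gradients, adapter contamination, 3' coverage bias, intron/genome
structure (reads are drawn from transcripts only), and homology between
distinct transcripts beyond the planted fragments/isoforms.

### The unique-flank constant

Optimal edit-distance alignment credits ≈ 60% residual identity between
unrelated random DNA. An isoform variant composed of `core + flank` with
flank = 0.8 × core therefore measures ≈ (1 + 0.6·0.8)/1.8 ≈ 0.82 identity
against its source transcript — safely below the 0.90 containment gate —
while a 25% flank would measure ≈ 0.91 and be (correctly) removed as a
containment. The 80% flank keeps the generator's contract that isoform
variants are isoforms, not containments.

## Stage-by-stage numerical choices

**De-redundancy.** Greedy pass in descending length order (ties by input
order, so the first of an exact duplicate pair survives). Candidate pairs
are pre-filtered by shared 15-mers (every position of the shorter probed
against k-mers sampled every ⌊k/2⌋ of retained contigs — a ≥ 90%-identity
containment always retains an exact 15-run long enough to be sampled).
The containment test aligns the shorter into the longer with edlib in
infix mode; identity = matches / alignment columns from the extended
cigar. "Entirely covered" is operationalized as ≥ 90% of the shorter's
length (flag-exposed): when the full-length alignment misses the identity
gate, the test retries with up to (1 − min_cover) of the query trimmed
from the ends. A full dynamic-programming local alignment is used only as
the test oracle on small fixtures — the two routes agree there, and the
edlib route is O(nm/64) instead of O(nm).

**Isoform selection.** Locus labels are read from a `locus=` tag in the
FASTA description; an unlabeled contig is its own locus. Longest wins;
length ties break to the lexicographically smaller id.

**Statistics.** Mean length is rounded to the bp; the median of an even
count is the lower middle; N50 is the length at which the descending
cumulative sum first reaches half the total.

**Assessment.** Coverage is measured on the *reference*: the fraction of
reference bases spanned by the single best contig aligning at ≥ 90%
identity (the union-of-contigs alternative is deliberately out of scope;
measuring contig-side coverage instead is a flag on the CLI). Gates at
coverage ≥ 50% and ≥ 90% are inclusive.

**Mapping.** Exact 21-mer seeds at offsets spaced k apart plus the final
window: with ≤ 2 mismatches per 100-bp mate, at least one of the four
disjoint seeds is error-free (pigeonhole), so the seeding is lossless
within the mismatch budget. Extension is gapless — the generator produces
substitution errors only, and this keeps the mapper verifiable against an
exhaustive all-positions oracle. Concordance requires opposite strands,
FR orientation and an implied insert within mean ± 4 sd (140–380 bp at
defaults). Classification counts minimal-mismatch locations, capped at a
report limit of 2 (unique = 1, multi ≥ 2); the reported location is the
lexicographically smallest (transcript id, start) for determinism.
Mapping is independent of read input order.

**Quantification.** A unique concordant pair contributes 2 reads to C
(config: `--count-unit pairs` counts fragments). Library total N is the
merged treatment's uniquely-aligned read count. The +1 pseudocount is
added to the RPKM itself, not to counts, so unexpressed transcripts
report exactly 1.00; fold changes use the incremented values. Output
tables round RPKM and fold to 2 decimals; internal arithmetic is
unrounded.

**Differential expression.** Plain G-test (no Williams/Yates correction
by default; Williams is a flag for sensitivity analysis). Cells with
O = 0 contribute 0; a table with an all-zero column (both counts zero, or
counts equal to totals) carries no signal and returns G = 0, p = 1.
Transcripts with zero counts in both treatments are excluded from testing
and from m in the BH correction. FDR is controlled per tissue. The test
consumes merged-replicate counts and therefore models technical (Poisson)
variability only — a faithful reproduction of the classical read-count
workflow, not a best-practice endorsement; a dispersion-aware model
(edgeR, DESeq2) is the modern replacement.

*Composition effect.* Because libraries are normalized to fixed depth,
planting 10% DE transcripts shifts every null transcript's *relative*
abundance; at high depth the G-test genuinely detects these shifts, so
the demo's false-discovery-vs-truth metric exceeds the nominal FDR under
planted DE. This is a property of proportion-based testing without
composition correction, shared by the workflow being reproduced. The
calibration claim — false-call fraction within 2% at FDR < 0.01 — holds
on fully-null simulations and is asserted there.

*Which counts are tested.* "G-test of the RPKM-derived read counts" is
ambiguous between raw unique counts and RPKM-rescaled values; raw unique
counts against library totals are tested, since RPKM rescaling would
break the test's distributional basis.

**Orthology.** Top hit per query = minimal e-value, ties to maximal
bitscore then lexicographic subject id. Coverage for the 60/60 filter is
measured on the query (species-A) side — the side is config-exposed, as
conventions differ. Thresholds are inclusive (≥). Non-coding transcripts
flow through the same RBH logic on nucleotide-level hit tables. The ORF
finder is longest-ATG-to-stop over six frames (ties: lowest frame, then
leftmost), a deliberate simplification of Markov-scored ORF callers.

**P1BS.** The octamer pattern G,N,A,T,A,T,N,C is matched with N ∈
{A,C,G,T}; ambiguity codes in the subject never match (avoids spurious
hits in masked regions). The pattern equals its own reverse complement,
so every match is reported once per strand at the same start; overlapping
occurrences are found with a look-ahead scan.

## Problem sizes

The demo default (2,000 transcripts; 12 × 50,000 pairs) exercises every
stage and completes in about two minutes on one CPU. The acceptance
script runs its end-to-end experiment at 1,000 transcripts and 20,000
pairs per library, plus a 10-seed fully-null calibration at 2,000
transcripts, chosen so the whole recomputation stays around a minute.
Statistical checks in the test suite use 20 seeds at 2,000 transcripts
(count-level simulation, which is exact for the DE stage and far cheaper
than re-mapping reads).

## Known limitations

- The mapper is gapless and substitution-only; indel-bearing reads would
  be classified unaligned rather than placed.
- Containment identity from infix alignment can differ marginally from a
  full local-alignment identity when gaps at fragment ends would pay;
  the planted-identity recovery tolerance (1%) absorbs this.
- Merged-count G-testing inherits the composition and overdispersion
  caveats above.
- `go_tally` consumes externally-produced annotation tables; no
  annotation is computed in-package.
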