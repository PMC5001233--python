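# Methods

## The problem

During ER stress the endoribonuclease IRE1α excises a short segment — 26 nt
in the canonical case of *Xbp1* mRNA — from its target transcripts in the
cytosol, outside the spliceosome. Reads that straddle such an excision point
fail contiguous alignment and are discarded by conventional mappers, and
splice-aware tools tuned to canonical introns rank these short events poorly.
`splicerescue` recovers them from the unmapped fraction and contrasts a
splicing-competent case sample (Het) against a splicing-deficient control
(KO), in which any genuine excision must be absent.

## Pipeline model

1. **Expanded genome.** From a UCSC knownGene-format table, one flank record
   is built per adjacent exon pair: the terminal `L − 4` bases of the
   upstream exon concatenated with the initial `L − 4` bases of the
   downstream exon, where `L` is the read length (truncated to the exon when
   an exon is shorter; extending into the intron would create chimeric
   flanks). Flanks are merged with the genome so that reads spanning an
   *annotated* junction with at least 5 bases on each side align in pass 1
   and never reach the split stage. `L − 4` guarantees each side of a
   junction-spanning read overlaps its flank by at least 4 bases.
   Junctions shared by overlapping isoforms are emitted once, keyed by
   (chrom, leftEnd, rightStart); flank ids encode those coordinates so the
   known/novel annotation needs no side table.

2. **Pass 1.** Whole reads against the expanded genome. Reads with more
   equally good placements than `max_good_alignments` are suppressed — they
   are mapped, only ambiguously, so they are not splicing candidates and are
   not forwarded to splitting. Unmapped reads go on.

3. **Split.** Each unmapped read of length `L` is decomposed at every offset
   in `[MS, L − MS]` — `max(0, L − 2·MS + 1)` split pairs, each half at least
   the minimum split size MS.

4. **Pass 2.** All halves against the *plain* genome (flank records would
   corrupt the genomic gap arithmetic). Half query ids follow
   `<readId>/<offset>/<L|R>` so origin and offset stay recoverable.

5. **Matched pairs.** For each read and offset, every (left, right)
   placement combination is tested: same chromosome, same strand, colinear
   in read orientation, and gap `rightStart − leftEnd` within
   `[minCD, MD]` inclusive. Grouping by origin read makes this quadratic
   only in the placements of one read, not in the whole half pool; a
   brute-force all-pairs scan is kept in the test suite as the oracle. On
   the reverse strand the read-order upstream half is the one with the
   larger genomic coordinate and coordinates are reported in genomic
   orientation, which keeps the case/control comparison strand-agnostic.

6. **Clustering.** Matched pairs cluster within (chrom, strand, gap length)
   by single linkage on leftEnd with tolerance BB; equal spliced length is
   required, so bounding leftEnd also bounds rightStart. The reported
   coordinates are the modal (leftEnd, rightStart) of the cluster, ties
   broken toward the smallest leftEnd (determinism across platforms).
   Support counts *distinct origin reads*: a read contributing several
   offsets or placements counts once, so one multi-split read cannot inflate
   a junction.

7. **Filter, annotate, rank.** Junctions below `min_support` distinct reads
   are dropped; a junction is *known* if an annotated junction of the same
   length lies within BB on the same chromosome, else *novel*; ranking is by
   descending support, ties by coordinate.

8. **Comparison.** A case junction is unique if the control has no junction
   of the same length within BB on the same chromosome (the *filtered*
   control set is used; see limitations). BB is reused as the comparison
   tolerance rather than introducing a fourth spatial parameter. The
   side-by-side report pairs each case junction with its closest admissible
   control match.

## Parameters

| name | meaning | default | rationale |
|---|---|---|---|
| `min_split_size` (MS) | smallest half, bp | 8 | below ~8 bp halves map everywhere; typical usable range is 8 up to L/3 |
| `max_distance` (MD) | largest gap, bp | 40,000 | of the order of a gene length, assuming both halves fall in one gene |
| `min_distance` (minCD) | smallest gap, bp, inclusive | 2 | a 2 bp excision is the smallest reportable region |
| `boundary_buffer` (BB) | positional tolerance, bp | 5 | small slack for alignment jitter; values beyond ~5 blur distinct loci |
| `min_support` | distinct reads per junction | 2 | one read is never evidence |
| `max_good_alignments` | placements before suppression | 8 | multi-mapping cap for both passes |

Raising MS strictly shrinks the admissible split set, so the junction count
is non-increasing in MS; the matched-pair set is non-decreasing in MD; and
single-linkage clusters at smaller BB refine those at larger BB. These
monotonicity facts are property-tested.

## Parameter-response linear model

Junction counts over a grid of (MS, MD, BB) are summarised by ordinary least
squares with identity link:

    count = β0 + β1·MS + β2·MD + β3·BB

No interactions and no count link are used — the response is smooth and
nearly linear over practical grids, and the model's purpose is interpolation
("how many junctions would setting X report"), not inference. Predictions
are clipped at zero for reporting. Grid orchestration reuses work: pass 1 is
parameter-free, and halves split at the smallest MS of the grid serve every
larger MS by filtering on half length. Fitting requires ≥ 4 runs and a
full-rank design; a constant predictor is reported by name. β1 ≤ 0 is
expected on any pipeline-derived grid (the monotonicity above).

## Synthetic data

The generator emulates the study design at desk scale: two 10 kb
chromosomes; a three-exon "housekeeping" gene on chr1 (exercising the flank
reference — its mature-mRNA reads must be absorbed in pass 1); a 1.2 kb
single-exon target gene on the last chromosome from which a 26 nt segment is
excised in the Het transcripts only. Reads are 33 bp, error-free, constant
quality Phred 40 (Phred+33), sampled uniformly at 20× per transcript; Het
draws from both the unspliced and the excised target transcript, KO from the
unspliced one only.

Two constructions make the ground truth deterministic rather than merely
probable:

* the genome is rejection-sampled until no read-length k-mer repeats on
  either strand, so every genomic read has a unique placement;
* the excision boundary is placed where the innermost bases on the two sides
  differ, blocking the coordinate ambiguity that terminal micro-homology
  causes at real splice junctions — recovered coordinates are therefore
  exact, not ±1 (the coordinate-convention acid test);
* the Het spliced pool always contains `min_support + 2` anchor reads
  spanning the excision at evenly spaced offsets with ≥ MS bases on each
  side, so the support promise holds for every seed; an error names the
  minimum coverage when the requested coverage cannot host the anchors.

What the fixture does **not** emulate: sequencing errors (the matching stage
is exact-alignment-based, so errors would test the aligner, not the
algorithm; an optional uniform substitution rate exists but defaults to 0),
expression-level variation, fragment-size models, paired-end inserts, and
repeat-rich genomes. Passing tests therefore demonstrate the correctness of
the algorithmic chain, not robustness to noisy real data — short spurious
half placements do occur (8 bp halves hit random loci) and are visible as
low-support junk calls that the support filter removes, which is the same
mechanism that operates at full scale.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere, including BED output;
  spliced length is exactly `rightStart − leftEnd`.
* Both comparison bounds are inclusive (`minCD ≤ gap ≤ MD`).
* Empty inputs propagate as empty outputs (no junctions, empty BED);
  zero-variance responses in the model yield zero slopes, and R² is defined
  as 1 when the residuals are exactly zero.
* Ambiguous quality encodings (all bytes in 59–74 with none above 74) are
  treated as Phred+33 with a warning; unequal read lengths across input
  files abort the run before any alignment.
* Replicates are junction-called per file and unioned by exact coordinates,
  with read ids namespaced per replicate so summed support remains a
  distinct-read count; per-replicate support appears in the detail file.
* Paired-end mates are pooled as independent single-end reads (mate-suffixed
  ids); no mate-aware constraint is applied.
* Per-chromosome chunking of the pass-2 alignments is exact, not an
  approximation: matched pairs never span chromosomes, so junction calling
  is separable and chunked output is byte-identical.
* Intermediate files are deleted on a fixed schedule (pass-1 alignments
  after unmapped extraction, unmapped and half files after the stage that
  consumes them) unless `--keep-intermediates`; deletion never touches final
  outputs and is logged path by path.

## Problem sizes

The default fixture runs the entire comparative pipeline — two samples,
~3,300 reads, two alignment passes, matching, clustering, comparison — in
about one second on one CPU, and the acceptance script regenerates
everything from its seed at each invocation. Property-based checks use pools
of 1,000 random half alignments across 20 seeds against the quadratic
brute-force oracle.

## Known limitations

* The built-in aligner is exact-match; mismatch tolerance is available only
  through an external bowtie-1-compatible aligner, whose mismatch policy is
  left at that aligner's defaults.
* Strict absence in the control is judged against the control's *filtered*
  junction set; a control junction with support below `min_support` does not
  veto a case junction. Reconcilers comparing against other implementations
  should check which convention those use.
* Support counts distinct reads, not matched pairs; implementations that
  count pairs will report larger numbers at the same loci.
* Junctions between non-adjacent exons are not placed in the flank
  reference; exon-skipping reads of annotated genes therefore surface as
  novel junctions rather than being absorbed in pass 1.
* No probabilistic scoring, fusion/trans-splicing, or multi-way (> 2 sample)
  designs.
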