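# Methods

This note records the models behind each pipeline stage, the parameters
that matter, the design choices made where the design was genuinely open,
and what the synthetic-data generator does and does not emulate.

## Coordinates, sequences, formats

All intervals are 0-based half-open on a named chromosome with a mandatory
strand; GTF/GFF3 readers convert from the 1-based inclusive convention at
the boundary, so `end - start` is a length everywhere. Unstranded features
(`.`) are rejected rather than guessed, because strand drives positional
classification. Sequences are stored in the DNA alphabet (`U` → `T` on
input, restored on FASTA output for RNA-flagged records) so that mimicry
and pairing operations work over a single comparison alphabet. Transcript
length always means the spliced (exonic) length.

The GTF reader accepts the gffcompare/StringTie dialect and takes the
attribute key that carries the class code as a parameter
(`class_code` by default), since assembler versions disagree on it.

## Identification cascade

Four gates, each a pure predicate over one transcript, so membership in
the output is independent of gate order (only the attrition log depends on
it):

| gate | rule | default | notes |
|---|---|---|---|
| class code | code ∈ allowed set | `{i,x,u,o,e}` | reference matches (`=`) and other codes removed |
| length | spliced length ≥ `min_length` | 201 nt | "longer than 200 nt" |
| exons | exon count ≥ `min_exons` | 2 | single-exon transcripts removed; 2-exon transcripts retained |
| expression | max-over-samples FPKM ≥ `min_fpkm` | 0.1 | inclusive boundary |

The expression gate aggregates by the **maximum** across samples: a
transcript convincingly expressed in any one condition passes. Mean- or
per-sample aggregation would silently drop condition-specific lncRNAs,
which are exactly the interesting ones in a stress design.

Coding potential uses the intersection rule: a candidate is a lncRNA only
if *every* configured predictor calls it non-coding. Predictors implement
a two-line interface (`(transcript_id, sequence) → CodingVerdict`), so
external tools can be slotted in by writing their verdicts into the same
structure. Two predictors are built in:

* **Longest ORF** — longest ATG→stop span over the three forward frames of
  the spliced transcript, stop codon included; an ATG-initiated frame
  reaching the sequence end counts its complete codons. Coding iff
  ≥ `min_orf_nt` = 300 nt (the conventional 100-codon lncRNA cutoff).
* **Hexamer log-odds** — mean over sliding hexamers of
  log(P_coding/P_noncoding), pseudocount-smoothed tables trained from
  example coding and non-coding sequences; coding iff the mean exceeds 0.
  Windows containing `N` are skipped.

The default predictor set is the ORF rule alone: the hexamer score needs
labelled training sequences, which a de-novo identification run does not
have. Where labels exist (the synthetic bench; a user with a curated
training set) the hexamer predictor is enabled explicitly, and the test
suite requires it to separate generator-planted coding from non-coding
sequences with AUC > 0.9.

## Positional classification

Precedence, first match wins:

1. **sense** — ≥ 1 nt exonic overlap with a same-strand gene exon;
2. **antisense** — any overlap with an opposite-strand gene's genomic span;
3. **intronic** — span wholly inside one intron of a same-strand gene;
4. **lincRNA** — none of the above.

Exonic same-strand overlap is the strongest structural evidence, hence its
priority; antisense is judged on spans (mirroring the `x` class-code
semantics) while sense is judged on exons (mirroring `o`/`e`). The
supporting gene is the one with maximal overlap, ties broken by the
lexicographically smaller gene id — this makes classification invariant to
gene input order. Genes are indexed per chromosome with an interval tree;
the test suite checks exact agreement with an index-free all-pairs
re-statement of the rules.

When class codes are present they are trusted; the computed classification
is cross-checked against them and disagreements are *reported*, not
resolved, since the code-emitting tool's dialect is outside our control.

## Differential expression

The DE stage re-specifies the classic count-based NB workflow rather than
wrapping a package, so every number it produces is reproducible from this
note:

1. **Size factors** s_j: median over transcripts of c_ij / geomean_i,
   restricted to transcripts with strictly positive geometric mean,
   rescaled to geometric mean 1. Failing that restriction (no transcript
   expressed in all samples) is an error suggesting the pseudo-reference
   fallback rather than a silent guess.
2. **Fold change**: log2FC = log₂((q̄_B + ε)/(q̄_A + ε)) on normalised
   counts q = c/s, with pseudo-mean ε = 1 bounding the fold change when a
   group is all zero.
3. **Dispersion**: per transcript, the method-of-moments estimate
   α_i = (v_i/κ − μ̂_i)/μ̂_i² from the pooled within-group variance v_i,
   then the cohort **median** of the α_i shared across all transcripts,
   floored at 10⁻⁸. κ = median(χ²_df)/df (df = n − 2 groups) corrects the
   small-sample skew of the variance estimate: at df = 4 the sample
   variance's median is ≈ 0.84 of the truth, and since the pooling step is
   itself a median, omitting κ biases the shared dispersion low and makes
   the test anti-conservative (null p < 0.05 fraction ≈ 0.08 instead of
   0.05). With κ the measured null fraction is 0.048–0.060 across seeds.
   Sharing one dispersion across transcripts is the right bias/variance
   trade at 2–3 replicates per group, and matches the generator's model of
   a common α; with strongly transcript-specific dispersions it will be
   mis-calibrated (see Limitations).
4. **Wald test**: z = log2FC / SE with
   SE² = [(μ̂_A + αμ̂_A²)/(n_A (μ̂_A+ε)²) + (μ̂_B + αμ̂_B²)/(n_B (μ̂_B+ε)²)] / ln²2
   (delta method under Var = μ + αμ²), two-sided p from the standard
   normal. Transcripts with zero total count get p = 1.
5. **BH adjustment**: step-up with monotonicity enforcement, implemented
   directly (and cross-checked against statsmodels in the tests).
6. **Call**: DE iff FDR < 0.01 (strict; the boundary is configurable to
   inclusive) and |log2FC| ≥ 2.

The test is symmetric (swapping groups flips the fold-change sign and
preserves p) and calibrated by construction against the generator's null.

## Cis / trans targets and target mimics

*Cis*: gene–lncRNA pairs on one chromosome with span-to-span gap strictly
below the window (default 100 000 nt; overlap counts as gap 0),
strand-agnostic because proximity regulation has no strand rule. Span-gap
distance is symmetric in its anchors, so anchoring windows on lncRNAs or
on genes yields the same pair set.

*Trans*: restricted to antisense-classified lncRNAs. Pairing is a gapless
position-wise pseudo-energy — GC −3, AT −2, G:U wobble −1, else 0 — over a
window of length min(|lnc|, |mRNA|, 200), evaluated at **every** (lncRNA
offset, mRNA offset) pair via diagonal prefix sums of the score matrix
(O(n·m) per pair instead of enumerating windows; small-integer
accumulators, widened automatically for long inputs). The most negative
length-normalised score (ndG) is kept and reported iff ndG ≤ `ndg_max` and
the window ≥ 20 nt. The default cutoff −0.1 is maximally permissive; under
this scoring a random best window sits near −1.2 (expected per-position
score −0.75 plus the extreme-value excess of the offset scan) while a
200-nt window containing ≥ 120 nt of perfect complementarity scores about
−1.8, so −1.5 is the natural operating point when discrimination is wanted
and is what the worked example and the acceptance script use. Both the
score weights and the cutoff are parameters, not claims about free-energy
physics.

*Mimics*: every offset where the lncRNA subsequence pairs the
reverse-oriented miRNA with mismatches strictly below the maximum
(default 3). G:U wobble (lncRNA G against miRNA U, or U against G) is
tolerated and counted separately; with `allow_gu` off it counts as a
mismatch. Hits are ranked by score = mismatches + 0.5·(G:U pairs). The
alignment is gapless — no bulge modelling — since the rule being
implemented constrains only mismatch and wobble counts.

## Enrichment and networks

Term enrichment is the plain upper-tail hypergeometric test
P(X ≥ k | N, K, n); terms absent from the universe are skipped;
significance follows the raw p-value (default 0.05) with BH FDRs reported
alongside. No transcript-length bias correction is applied: that
correction needs read-level data this pipeline deliberately abstracts
away, and the divergence is noted here rather than hidden.

Co-expression edges use Pearson r on log₂(FPKM+1) across all samples,
kept iff |r| ≥ 0.8 (configurable); zero-variance vectors are skipped with
a warning since r is undefined there. The edge-calling recipe is a stated
convention, not an estimate of anything.

The network is a typed multigraph: lncRNA, PCgene, miRNA nodes, with
PCgenes re-typed TF when a transcription-factor family table lists them;
edge types cis / trans / mimic / mirna_target / coexpression, unique per
(source, target, type). `--de-only` keeps only DE-flagged lncRNAs'
edges. Exports (SIF, GraphML, edge TSV) sort nodes and edges, so
assembling and exporting twice is byte-identical.

## The synthetic-data generator

The generator's defaults *are* the study conditions the pipeline targets:
2 chromosomes × 30 genes, 40 lncRNAs (10 per class), and a 24-sample
design (2 tissues × 4 conditions CK/LS/SS/R × 3 replicates). It emulates:

* a toy annotation with coding genes (3–5 exons, one guaranteed long
  intron to host intronic lncRNAs) laid down sequentially with intergenic
  gaps of 3–15 kb;
* planted lncRNAs constructed so the classifier's precedence rules
  recover the planted class exactly: intergenic ones in dedicated slots
  whose near-side gap is the planted cis distance (5–80 kb) with the far
  side kept ≥ 150 kb clear, so the nearest-gene distance is exact;
  negative controls at 120–140 kb straddle the 100-kb window from above;
* transcript sequences i.i.d. uniform over A/C/G/T except planted
  features: coding transcripts carry an ATG···stop ORF spanning most of
  their length; lncRNA sequences are post-edited (TAA written into the
  middle of any long ORF, never inside a planted site) until the longest
  ORF is < 300 nt; each antisense lncRNA receives a ~120-nt reverse
  complement of its host mRNA so the trans scan has true positives;
* NB counts with Var = μ + αμ² (α = 0.05), log-normal per-transcript
  means (location 5.0, scale 1.0 on the natural log, median ≈ 150),
  per-sample size factors uniform in [0.5, 2], and a planted ±3 log₂ fold
  change on 30% of transcripts between CK and SS in both tissues (LS and
  R stay null so other contrasts exercise the null path);
* 5 random 21-nt miRNAs and mimic sites written into lncRNAs at exact
  (mismatch, G:U) counts — the default plan plants 0-, 1-, 2-mismatch
  sites, a pure-wobble site, and a 3-mismatch negative control that the
  default scanner must reject.

Everything is driven by `numpy.random.Generator` streams derived from one
seed (separate streams for genome, miRNAs, mimic planting and counts), so
identical seeds give byte-identical files on any platform.

What it does **not** emulate — and therefore what passing tests do not
show about real data: isoform complexity and overlapping genes, GC and
length bias, realistic codon usage or hexamer structure, batch effects,
transcript-specific dispersions, unbalanced designs, and assembler
artefacts in class codes. Recovery rates of 100% on this bench mean the
logic is implemented correctly, not that real surveys are noise-free.

## Numerical and determinism choices

* Dispersion floor 10⁻⁸; ε = 1 pseudo-mean; p-values clipped to [0, 1];
  zero-total-count transcripts p = 1.
* Ties: supporting gene by smaller id; mimic hits by (score, offset);
  every writer sorts rows by primary then secondary id; mergesort
  (stable) everywhere a sort could see ties.
* Degenerate inputs fail loudly: empty predictor list, overlapping DE
  groups, < 2 replicates, missing verdicts/sequences/lengths, selection
  outside the enrichment universe, chromosome-length overflow in the
  generator (with the required minimum in the message).
* Problem sizes in the bench were chosen so the whole suite and the
  acceptance script run in well under a minute of CPU each at the default
  design; the calibration simulations use 2000 transcripts, which bounds
  the Monte-Carlo error of the null p < 0.05 fraction at about ±0.01.

## Known limitations

* The coding-potential stand-ins are deliberately simple; they do not
  reproduce CPC/CNCI/CPAT/Pfam scores, only the intersection semantics.
* The shared-dispersion Wald test is calibrated for cohort-like
  dispersion; strong per-transcript dispersion heterogeneity or designs
  beyond two-group contrasts need a heavier tool.
* The pairing pseudo-energy is not a thermodynamic ΔG; cutoffs on it rank
  complementarity, nothing more.
* Enrichment ignores transcript-length bias.
* gffcompare/cuffcompare class-code dialect differences are surfaced by
  the cross-check report, not resolved.
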