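# Methods

`adtrx` re-implements, as a tested library, the bespoke analysis stages of a
bulk brain-transcriptome study of Alzheimer's disease (normal / MCI / AD
groups): lncRNA identification with a unanimous coding-potential vote and
genomic classification, alternative-splicing event detection with PSI
testing, differential-transcript filtering, single-sample gene-set
enrichment, principal-component-regression inference of lncRNA pathway
regulators with cis/trans target prediction, and unique protein-function
re-annotation.  Cohort-scale inputs (hundreds of RNA-seq libraries,
terabytes of reads) are out of scope; a synthetic-study generator with
serialized ground truth stands in for them, and every stage is validated by
rule-conformance tests, independent oracles and parameter recovery against
that ground truth.

## Coordinate conventions

All internal coordinates are 0-based half-open on a named sequence with an
explicit strand.  GTF files (1-based inclusive) are converted exactly once,
in the reader/writer pair, which round-trips catalogs byte-identically.
Strand `.` is accepted on input and treated as `+` for orientation-dependent
rules, with a warning.

## LncRNA discovery

Candidates are transcripts with spliced length >= 200 nt and >= 2 exons
(both inclusive).  Five in-house scorers replace the five external
coding-potential predictors usually run at this step; the unanimous-vote
rule — lncRNA only when all five call noncoding — is preserved exactly,
because the vote, not the tools, is the computation of interest.

The scorers: (1) Fickett TESTCODE (codon-periodicity/composition statistic
from bundled lookup tables); (2) an in-frame hexamer log-likelihood ratio
over the longest ORF, with tables estimated from training CDS vs noncoding
sequence under add-one smoothing (no ORF scores `-inf`: absence of any
reading frame is maximal evidence against coding); (3) ORF coverage
(longest-ORF length / transcript length); (4) longest-ORF length in nt;
(5) G+C fraction as a composition stand-in.

**Threshold calibration.** Each scorer votes "coding" when its score
strictly exceeds a threshold set to the *maximum* score observed on the
noncoding half of a labeled training split (a separately seeded synthetic
study with 200 lncRNAs).  Rationale: under the unanimity rule a single false
coding-vote loses a lncRNA, so per-scorer specificity must be near 1; coding
transcripts are still vetoed reliably because ORF length and the hexamer
ratio separate ORF-bearing coding sequence from random sequence with
essentially no overlap.  On synthetic data the Fickett scorer has little
discriminative power in the coding-high direction and in practice almost
never votes; it is retained for the five-vote structure.

**Class codes and categories.**  A novel transcript is `i` when every base
lies within a single reference transcript's intron; `u` when it overlaps no
reference span; `x` when every exon base falls within one reference gene's
exonic space (the literal reading of the source procedure, which differs
from the gffcompare convention of antisense exonic overlap); otherwise `o`.
Categories use precedence antisense > intronic > intergenic: any
opposite-strand overlap makes a lncRNA antisense; class `i` on the sense
strand is intronic; class `u` is intergenic; anything else defaults to
intergenic with a warning.  Both rules are checked against a per-base
brute-force oracle on random catalogs.

**Read regions.**  Reads are assigned one region by precedence
CDS > 3'UTR > intron > upstream-10 kb; 5'UTR bases are deliberately not a
category (they fall into "unassigned", which is excluded from the reported
fractions), matching the region list of the source analysis.

## Splicing events and PSI

Events are detected by pairwise comparison of transcript models within a
gene: SE (internal exon present in one isoform, absent in the other, flanking
splice sites shared), A5SS/A3SS (two introns sharing exactly one boundary,
with the exons adjacent to the differing boundary sharing their outer
boundary — the extra condition keeps a skipped exon from also registering as
an alternative splice site; 5'/3' is resolved by strand), MXE (two disjoint
middle exons between shared flanks, never co-occurring), and RI (one
isoform's single exon exactly spanning the other's two exons plus the
intervening intron).  Events deduplicate on (gene, type, coordinates).

PSI is length-normalized: psi = (I/l_I) / (I/l_I + S/l_S), with junction
support sizes l_I/l_S of 2/1 for SE, 2/2 for MXE and 1/1 otherwise;
0/0 evidence leaves PSI undefined and the sample is dropped.  Groups are
compared by a two-sided Mann–Whitney test on per-sample PSI (the original
pipeline's event-level test statistic is not specified; the rank-sum test is
the documented stand-in), and an event is kept when p < 0.05 and
|dPSI| > 0.05.  The source text literally says events with |dPSI| > 0.05
were *removed*; that reading contradicts the purpose of the filter and the
default here retains them, with `direction="remove"` available.

## Differential transcripts

A transcript is differential between two groups when |log2 FC| >= log2(1.3)
(symmetric: down-regulation at FC <= 1/1.3 qualifies), BH-adjusted p < 0.05,
and at least one group mean >= 1; transcripts below 1 in both group means
are excluded before testing and before the BH family is formed.  The
per-transcript p-value again comes from a two-sided Mann–Whitney test — a
documented stand-in for a negative-binomial count model, feeding the same
thresholds.  `size_factor_normalize` provides median-of-ratios scaling of
raw counts as an alternative input normalization to TPM.

The BH step-up is implemented directly (sort, scale by m/rank, running
minimum from the largest p, clamp at 1) and is checked against statsmodels'
`multipletests`.  Note the step-up is *not* idempotent — re-applying it to
adjusted values rescales them again — so no such property is claimed.

## Single-sample enrichment

Genes are ranked by expression, descending, ties broken by id.  The raw
statistic walks the ranking, accumulating the weighted in-set ECDF (weights
rank-score^0.25, rank score n..1 from the top) minus the unweighted
out-of-set ECDF, and sums the difference at every position.  Two deliberate
departures from the common formulation: the sum is divided by the number of
ranked genes (scale stability across gene universes) and centered by its
analytic set-size-free null expectation, `sum_i(CW(i)/CW(n) - i/n)/n` with
`CW` the cumulative all-gene weights.  Without centering the statistic has a
positive null mean of order 0.05·n — a random gene set would score "up" —
because decaying weights make the in-set ECDF stochastically dominate the
out-set ECDF under random membership.  The centered score keeps the intended
reading: positive means set genes sit high in the ranking.  Rank-basedness
(invariance under strictly monotone transforms) and the direct-summation
oracle are unaffected.

## Regulator inference

For each pathway, member-gene expression rows are centered and unit-scaled
(correlation-matrix PCA, so high-variance transcripts do not dominate;
covariance PCA via `scale=False`), and the smallest k PCs whose cumulative
explained variance reaches 60% (inclusive at the boundary) are retained.
Each lncRNA is regressed (OLS on mean-centered response and predictors —
the centering is what drives the intercept to zero, honoring the
"minimize |b0|" formulation; |b0| is reported as a diagnostic) on the
retained PCs; significance is an overall F-test with df (k, n-k-1),
BH-adjusted across all (lncRNA, pathway) fits as one family.

Cis targets are other-gene transcripts whose span lies within 100 kb
(inclusive; gap distance between spans, 0 when overlapping, strand-agnostic)
and that are co-expressed: Spearman |r| > 0 with BH-adjusted p < 0.05, one
family across all tested cis pairs.  Trans targets must show an ungapped
duplex with hybridization energy strictly below -10 kcal/mol plus the same
co-expression criterion (its own BH family); genes inside the cis window are
excluded from trans testing.  The duplex scan pairs the lncRNA against the
reverse complement of the target along every antiparallel register,
accumulating stacking energies from a bundled 16-entry nearest-neighbor
table (kcal/mol, all stabilizing, symmetric under reverse complementation of
the step, so the energy is invariant under swapping the strands); a mismatch
terminates a stack run, and the minimum-energy run is reported.  The table
is a documented simplification, not a full thermodynamic parameterization.

A lncRNA is called a regulator of a pathway when R^2 >= 0.6 (the "high R^2"
of the source is unquantified; 0.6 is the package default and is echoed in
CLI output), regression p_adj < 0.05, and at least one kept cis or trans
target belongs to the pathway.

## Unique functional assignment

Each transcript's longest ATG-initiated ORF (ties to the 5'-most start;
codons containing N translate as X) is aligned to every database protein by
Smith–Waterman local alignment (BLOSUM62; affine gaps where a length-L gap
costs 11 + (L-1)·1, biopython's convention).  Pairs scoring below 40 are
discarded.  Assignment is globally greedy: repeatedly take the
highest-scoring remaining pair with both sides free, ties broken
lexicographically — deterministic, input-order independent, and injective by
construction, which is exactly the no-two-variants-share-a-function
guarantee.  Hungarian optimal assignment is available (`method="optimal"`)
for comparison; greedy is the specified behavior.

## The synthetic study

The generator writes a single ~370 kb chromosome carrying, by default, 60
protein-coding genes (10 of them event genes: two isoform pairs per splicing
event type) and 30 lncRNAs, and simulates 30 samples per group.  Defaults
were chosen once as a desk-scale world that runs in seconds and are not
tuned to outcomes.

* **Sequence.**  Coding ORFs draw codons with weight 2^(G+C), giving coding
  sequence a learnable hexamer and composition signature; lncRNA and UTR
  sequence is uniform random.  The generator rejection-samples each ORF
  until it is its transcript's *longest* ORF: the GC bias depletes stop
  codons in shifted frames, occasionally producing longer spurious frames —
  something real coding genes, whose shifted frames are stop-rich, do not do
  — and which would break the longest-ORF translation bridge.
* **Placement.**  lncRNA classes cycle u/i/o/x.  `i` lncRNAs sit inside a
  host gene's enlarged intron (sense strand, intronic category); `o` and `x`
  lncRNAs lie antisense over host genes' 3'UTR exons — over UTR rather than
  CDS so their extracted sequence is not reverse-complemented codon-biased
  CDS, which would confound the coding-potential scorers by construction.
  `u` lncRNAs occupy intergenic gaps; the first of them are designated cis
  regulators (placed in the gap adjacent to their target pathway gene) and
  trans regulators (placed >100 kb from their target, carrying an embedded
  25-nt reverse complement of a window of the target's ORF).
* **Expression.**  Counts are negative binomial (dispersion 0.1) around
  log-normal baseline means; 10% of transcripts receive a 2.0-fold mean
  increase in MCI, AD or both.  Each planted regulator pair has a per-sample
  latent factor f ~ N(0,1) loading with 0.8 on the log-mean of the lncRNA
  and its pathway's genes.  Fold changes are planted only on factor-free
  transcripts: the factor inflates per-transcript variance roughly
  seven-fold, and a fold change planted on a loaded transcript is
  unrecoverable by any two-group test — the two kinds of planted structure
  are kept orthogonal so each truth is meaningful.  TPM columns sum to 1e6.
* **Junctions.**  Per event and sample, total depth is Poisson(50) and
  inclusion reads are binomial with the read-level probability implied by
  the group PSI and the form lengths; planted events shift PSI by +0.3 in
  MCI and AD; 60 null events have no shift.  Zero-depth samples propagate
  undefined PSI.
* **Proteins.**  One protein per coding gene (CDS translation at 5% point
  substitutions) plus 20 shuffled decoys.

What the generator does **not** emulate: read-level artifacts, alignment and
assembly error, batch effects, library-composition biases, isoform-level
quantification uncertainty, and realistic genome architecture (repeats, GC
isochores, overlapping genes).  A green parameter-recovery test therefore
establishes that the *decision rules* behave as specified under the assumed
statistical structure — not that the pipeline is robust to the failure modes
of real cohort data.

## Evaluation choices

Parameter-recovery checks pool counts over replicate generator seeds where
the per-study estimate is heavily quantized: lncRNA sensitivity/precision
and DET sensitivity/FDR pool 10 studies (a single study yields ~8 DET
discoveries, so one chance false positive — which BH at 0.05 permits —
would swing the observed FDP from 0 to 0.125), and regulator sensitivity is
the median over 20 seeds with a pooled false-call rate.  Functional
assignment is evaluated on CDS-carrying transcripts, the ones with a source
protein in the database: the second isoform of an event gene carries the
identical ORF as its sibling, and under an injective map its protein is
necessarily taken, so such duplicate-ORF isoforms end up with arbitrary
low-score homologs by design of the world, not by failure of the rule.

## Numerical notes

Ties in ranking are broken by id everywhere (ssGSEA ordering, greedy
assignment, 5'-most ORF starts).  The PC count uses a 1e-12 tolerance at the
60% boundary.  Constant vectors are rejected or flagged rather than scored:
Spearman returns NaN with a warning, PCA drops zero-variance genes with a
warning, identical-in-both-groups rows get p = 1.  All generator stages
derive independent random streams from (seed, stage index), so each stage is
individually reproducible and whole runs are byte-identical at a fixed seed.
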