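# Methods

This note records the models, thresholds, and numerical choices behind
the package, and what the synthetic study does and does not establish
about real data.

## The setting

Sugarcane cultivars are interspecific hybrids with 100–130 chromosomes
and no usable reference genome; their transcriptome is assembled de novo
from full-length-enriched cDNA reads and interpreted by comparison with
six sequenced grasses.  Every operation here takes the *tabular products*
of the standard external tools (hit tables in the 12-column outfmt-6
dialect, domain-hit tables, read-alignment records) as its interface;
running the search and mapping tools themselves is out of scope, and a
naive seed-and-extend aligner exists only so synthetic end-to-end runs
need no external binary.

## Read QC

Reads are trimmed by three interacting operators iterated jointly to a
fixpoint, which makes the composite idempotent:

1. terminal runs of ≥ `end_run_min` (default 5) N, A, or T bases are
   stripped from either end (poly-A/T tails, end N blocks);
2. an end whose terminal `window`-base (default 10) mean Phred quality is
   below `mean_quality_floor` (default 20) loses its terminal base,
   repeatedly;
3. reads shorter than `min_length_after` (default 70) are discarded.

The trimming window size and the run/quality ordering are not dictated by
the protocol being emulated; both are configuration, with run-trimming
first as the default.  Low complexity is scored with the DUST triplet
statistic: for each 64 nt window, `sum c_t(c_t-1)/2 / (w-3)` over triplet
counts `c_t`, maximised over windows; scores above 7 (the method's
conventional cutoff) flag the read.  A homopolymer window scores
`(w-2)/2` (≈ 31), uniform-random sequence ≈ 0.5.

## Codon-usage ORF prediction

A log-odds matrix is trained on in-frame reference CDSs: foreground =
codon frequencies with pseudocount 1; background = codon probability
under the training set's mononucleotide composition (so the matrix scores
codon *preference*, not base composition).  Prediction enumerates
stop-to-stop spans in all six frames; each span's candidate CDS runs from
its first ATG through the closing stop; the score is the summed log-odds
and the best-scoring candidate with ≥ `min_codons` (default 30) codons
and score ≥ 0 wins, ties broken by longer CDS, then plus strand, then
lower frame.

This is deliberately frameshift-free.  Indel-tolerant HMM decoding (the
approach of EST-oriented predictors) corrects sequencing frameshifts but
adds substantial machinery; the downstream analyses consume only CDS
spans, start/stop completeness, and proteins, which the frame-pure
procedure provides.  Consequences: contigs with internal indels yield
truncated or missed ORFs, and no 5'-partial rescue is attempted.  The
acceptance-score threshold for a prediction is a config value
(default 0), as the emulated workflow's own threshold is not published.

## Annotation transfer

SBH: per contig, species are walked in the annotation priority order
(*S. bicolor*, *O. sativa*, *Z. mays*, *B. distachyon*, *P. virgatum*,
*S. italica*); the first species with a best hit of bit score strictly
above 30 supplies the gene, and its label classes (free-text annotation,
pathways, TF family) transfer to the contig.  Species order wins over raw
score by design: a weaker sorghum hit beats a stronger millet hit.

BHR: the published workflow cites a reciprocal-hit-rate method without
printing its formula; the single most consequential assumption of this
module is the reconstruction `BHR = (b(a→b)/max_b' b(a→b')) ·
(b(b→a)/max_a' b(b→a'))`, the product of forward and reverse
max-normalised bit-score ratios (each ratio ≤ 1, so BHR ∈ [0, 1] and
reciprocal unique best hits score exactly 1).  A geometric-mean combiner
is available by flag.  Assignment requires BHR strictly > 0.95 and both
directional scores > 30; whether the score floor binds the reverse
direction too is unstated in the source workflow — it is applied to both
here, configurable.

## Full-length classification

Thresholds: gene-CDS coverage ≥ 0.95, identity ≥ 80%, contig coverage
≥ 0.50, e-value ≤ 1e-15.  "Coverage ≥ 50%" is read as *contig* coverage
(fraction of the contig aligned), since the companion clause names gene
hit coverage separately.  The species priority order for full-length
work (*S. bicolor*, *Z. mays*, *P. virgatum*, *S. italica*, *O. sativa*,
*B. distachyon*) differs from the annotation order; each module carries
its own default.

Analysis I implements "first gene hit" semantics: a contig is judged
against its best hit in the current species only.  Within a species,
qualifying (contig, gene) pairs are consumed in descending bit-score
order, so when several contigs fully cover one gene the strongest claims
it; a contig whose first-hit gene was claimed is *not* re-evaluated
against its second-best gene (it remains available to later species and
analyses).  "Completely covered" is operationalised as CDS coverage
≥ 0.95 by the single hit, not literal 100%.

Analysis II merges the remaining qualifying hits per remaining gene with
interval-union (non-overlapping) coverage — internally 0-based half-open
with conversion at the outfmt-6 boundary, verified against a per-base
marking oracle — and calls the gene at union ≥ 0.95 with ≥ 2 contributing
contigs (strictly two or more; a single-contig union is never called).
Multi-contig identity is reported alignment-length weighted.

Analysis III calls remaining contigs whose predicted ORF has both start
and stop and whose CDS length strictly exceeds the mean reference CDS
length (the six-grass default set centres near 1,030.85 bp).

Family collapsing replaces a tree-guided ortholog-profile aggregator with
deterministic single-linkage clustering, since only cluster membership is
consumed downstream.  A link requires global edit-distance identity
(edlib, NW) ≥ `score_cutoff` (default 0.7) and a length-ratio gate
min/max ≥ `overlap_cutoff` (default 0.5) — with global alignment the
shorter protein is always fully aligned, so the length ratio is the bound
on attainable overlap.  Unique totals attribute each family to the first
analysis (I, II, III) in which it appears, which is why a raw
Analysis-III contig count can exceed its collapsed unique count; both are
reported.

## NATs and pathway activity

Reads with alignments < 100 bp are ignored; a read on the strand opposite
its target's sense strand is antisense.  Per-contig antisense coverage is
the interval-union percent of the contig tiled by antisense alignments;
"fully overlapped" full-length NATs require exactly 100%.

Intensity `g_j` is antisense read count per gene, normalised to
reads-per-million within each sample by default (raw counts by flag); a
gene is detected at intensity > 0 (configurable floor).  `PA = (Σ g_j) /
(N/M)` with per-sample `N` (a global-N mode is a flag); pathways with no
detected gene in a sample are unscored there.  PA is linear in the
intensities and reduces to the plain sum whenever detection is complete.
Scores are log2(PA + 1) transformed and row-median-centred; pathways
cluster by average linkage over Euclidean distance, samples by average
linkage over Spearman-correlation distance (undefined correlations from
constant profiles are treated as distance 0).  The cluster count k is
chosen by maximising the silhouette index over k ∈ [2, min(10, rows−1)] —
one internal index in place of a full index battery, which is all the
emulated analysis used its battery for.

## TF rules

Classification is a pure function of a protein's significant domain set
(e-value ≤ 0.001, set semantics): the first rule by priority whose
required domains are all present and forbidden domains all absent wins.
The rule list is data; the bundled `data/tf_rules_example.tsv` is a
synthetic illustration of the schema (14 families with realistic
required/forbidden interactions, e.g. SANT_extra separating MYB from
MYB-related), not a curated registry export.  An optional min-copies
column is supported but unused by default.

## The synthetic study

The generator defines the conditions every test runs under:

* **Gene models.**  Six grass species, CDS lengths normal(1030.85, 350)
  truncated at 60 codons; 5'UTR normal(150, 60), 3'UTR normal(250, 90),
  truncated at 20 nt.  CDS bodies draw codons from a fixed
  lognormal-weighted (σ = 0.8) codon distribution — real coding sequence
  carries strong codon preference (~0.5 bits/codon here), the very signal
  a codon-usage matrix is trained on; uniform codons would leave the
  matrix uninformative.  5'UTRs are uORF-poor: the in-frame codon
  immediately upstream of the start is a stop, so the true start is the
  first ATG of its stop-to-stop span and is recoverable by the
  first-ATG rule.  All generation is `numpy` Generator-seeded and
  byte-reproducible.
* **Assembly.**  Gene slots split 40% intact single contigs / 30%
  fragmented into 2–4 pieces / 20% lineage-specific (random sequence,
  matching nothing) / 10% variant slots (one primary copy plus mutated
  2%-substitution variants sharing a family).  Fragment cut points fall
  strictly inside the CDS with a margin of (1 − coverage gate + 1%) of
  the CDS length from either CDS end, so no single fragment can pass the
  single-hit full-length gate while the pieces still partition the whole
  mRNA.
* **Reads.**  Five libraries (three hybrid tissues, one leaf library per
  ancestor genotype), read lengths normal(194, 40) ≥ 40 nt, antisense
  fraction 5.8% by default; the template strand is encoded in the read
  name (`/s`, `/a`) and the generator emits the alignment records a
  strand-aware mapper would produce, so NAT detection is testable without
  a spliced aligner.  Genotype presence follows a fixed mixture in which
  78.3% of contigs are expressed in all three genotypes and under 1.6%
  are absent from the hybrid.
* **Truth hit tables** bypass any aligner: planted contigs yield hits
  with Hamming-exact identities and coordinates; specific contigs yield
  no rows.  Bit scores are length-and-identity-scaled stand-ins adequate
  for ranking, not statistical bit scores.

What passing tests show — and don't.  The planted studies prove the
*logic*: exact recovery of the planted Analysis-I/II sets at zero noise,
antisense fractions within binomial error, TF rules recovering planted
families, coverage arithmetic agreeing with brute force.  They do not
exercise assembly chimeras, indel-induced frameshifts, cross-species
homology gradients (each synthetic gene is unrelated to every other), or
biased library chemistry; conclusions about real-data sensitivity should
not be drawn from the synthetic recovery rates.

## Problem sizes and numerics

The default test and acceptance runs use 6 × 200 genes (~2,200 contigs)
and 200,000 reads — sizes chosen so the full suite exercises every stage
in seconds while keeping binomial standard errors small enough for the
3-s.e. recovery checks.  Degenerate inputs are errors, not silent
passes: empty training sets, empty length lists, pathways with no member
genes, hits outside subject bounds, mismatched sequence/quality lengths.
Ties everywhere break deterministically (bit score, then e-value, then
lexicographic id; longer CDS, then plus strand, then lower frame), so
every pipeline output is byte-stable under a fixed seed.

Known limitations: no frameshift correction; no gapped alignment in the
naive aligner; single-linkage families can chain through intermediate
variants at permissive cutoffs; PA scores for pathways with very few
detected genes are noisy by construction (the N/M normaliser amplifies
single-gene signals); the paper-style truncated percent formatting
(46.85 → 46.8) is applied only at the reporting layer.
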