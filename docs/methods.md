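# Methods

This note records the models and procedures nbskit implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic test bed does and does not show.

## Coordinate conventions and I/O

All genomic coordinates are 1-based and inclusive (the GFF3 convention);
promoter extraction and cluster-gap arithmetic are written against it and
covered by round-trip tests. GFF3 is the only annotation dialect; a gene's
variant count is the number of its mRNA children (transcripts without a
parent gene are ignored with a warning, since locus/variant bookkeeping in
published annotations is often internally inconsistent and counting mRNA
children is the one assumption-free reading). Sequences are upper-cased on
read with IUPAC ambiguity codes preserved.

## Architecture classification

The decision rule over a gene's domain calls is:
TIR+NBS+LRR → TNL; RPW8+NBS+LRR → RNL; CC+NBS+LRR → CNL when the CC call
comes from the heptad scorer, XNL when only a domain database (CDD, Pfam,
SMART) reports it; NBS+LRR without CC → NL; and the LRR-less counterparts
N, CN, XN. Scorer evidence takes precedence over database evidence. A gene
with no NBS call, with both TIR and RPW8, or with TIR/RPW8 but no LRR is a
declared error: no class exists for those combinations, and an
exhaustiveness test enumerates every evidence combination to confirm the
rule is total. An "intact N-terminus" helper (pre-NBS region ≥ 120 aa,
configurable) is exposed for reporting; predicted CC evidence typically
spans residues ~35–95, so an intact N-terminus comfortably exceeds it. The
length criterion is deliberately not a branch of the decision rule — the
rule above is already total, and entangling the two would change labels for
inputs the vocabulary covers.

### Coiled-coil scorer

A Lupas-style sliding-window scorer with windows of 14, 21 (default) or 28
residues. Each window is scored as the geometric mean of per-residue heptad
propensities from a bundled 20×7 table, maximised over the seven register
phases, then mapped to a probability through the two-Gaussian likelihood
ratio P = N_cc/(N_cc + N_gl) with bundled per-window means and standard
deviations. A residue's score is the maximum over covering windows; a CC
call is any maximal run of residues at or above the 0.9 threshold.
Propensity table and Gaussian parameters are this package's own
calibration: hydrophobics (L, I, M, V) are strongly favoured at heptad
positions a/d, charged and polar residues at the outward positions, proline
is uniformly penalised. The scorer reproduces the qualitative behaviour of
heptad-based predictors (ideal heptads score ~1, proline runs score ~0,
random globular sequence rarely crosses 0.9) but is not bit-compatible with
any published implementation; precomputed CC calls from external tools are
equally accepted through the domain table, and the classifier does not care
which source produced them. Non-standard residues score a neutral
propensity of 1 and are logged.

### Consensus scan

The degenerate CC consensus (30 positions, bracket syntax) is scanned
exactly: every start position where each residue lies in its allowed set,
overlaps included. The parser treats hyphens as position separators and
ignores them inside brackets, which also normalises the typographic variant
`[GK][-QR]` to `[GK]-[QR]` — the only reading consistent with hyphen usage
in the rest of the expression.

## Physical clusters and chromosomal enrichment

Clusters are maximal runs of NBS genes in which every consecutive pair is
separated by <200 kb and by ≤8 non-NBS genes, with at least two members.
The gap is measured edge-to-edge (start of the next gene minus end of the
previous); the convention is not fixed by the rule's usual statement, and
edge-to-edge is the standard reading of inter-gene distance. Both bounds
are applied per neighbouring pair; maximal-run construction is equivalent
to connected components of the pairwise relation on chromosome-consecutive
genes, which is how the test-suite oracle recomputes it. A cluster is
monophyletic when all clade-assigned members share one clade, mixed with
two or more clades, untyped with fewer than two assigned members.

Chromosome-level enrichment uses the plain chi-squared statistic with
expected counts proportional to chromosome length, df = k − 1, no
continuity correction, over exactly the chromosomes appearing in the count
map — callers decide whether zero-count chromosomes enter the test, since
published analyses are ambiguous on that point. Genes on unanchored
scaffolds should be excluded upstream by the caller (the pipeline passes
only placed genes).

## Families and duplication modes

Pairwise CDS similarity is the best local alignment under affine-gap
dynamic programming (match +1, mismatch −2, gap open −5, gap extend −2;
configurable — the thresholds, not the scoring scheme, carry the biology).
Identity is matches over alignment columns, gap columns included; coverage
is the aligned span in the longer sequence over that sequence's length.
Families are single-linkage connected components over edges passing
identity > t AND coverage > t (both strict, per the literal ">70%"
criterion), with t swept over 70/80/90%. Raising t can only refine the
partition; the suite checks this refinement property and equivalence with
a brute-force transitive closure.

Within-family pairs are classified: tandem when both members lie in one
detected cluster (tandem takes precedence when both criteria hold, since
tandem is the cluster-based category); otherwise the 15 annotated genes on
each side of each member (fewer at chromosome ends; the member itself
excluded — the "30 genes" of the published criterion are the two 15-gene
flanks) form two blocks, and the pair is segmental when more than five
cross-block gene pairs are homologous at E < 10⁻¹⁰. Homologous pairs are
counted with greedy one-to-one matching (best e-value first) so a single
promiscuous gene cannot inflate the count. Gene-level homology is consumed
as input — either from the synthetic truth tables or from external
all-vs-all search results through the 6-column import path — because
recomputing genome-wide homology is the job of a dedicated search tool,
not this package.

## Promoter cis-element statistics

Promoters are the `upstream` (default 1500) bases immediately 5′ of the
annotated gene start for '+' genes, and the reverse complement of the bases
immediately 3′ of the end for '−' genes, truncated at chromosome edges,
with an exclusion list for promoters flagged as overlapping other
annotation. The gene start is taken as the translation start anchor; for
annotations that separate TSS and ATG, callers can re-anchor by adjusting
gene coordinates.

Motif matching is exact IUPAC class membership on the forward strand with
overlaps counted; ambiguous sequence bases never match. The expected total
count under an i.i.d. background parameterised by G+C alone is
E = n · (L − m + 1) · Π_j Σ_{b∈class_j} p(b), with p(G) = p(C) = GC/2.
Forward-strand-only counting is the convention that reproduces the
published expected counts for six of the ten surveyed motifs exactly after
rounding; double-strand counting reproduces none. Expected counts are
reported rounded half-up to match the published integer column, and the
enrichment factor divides the observed count by the *rounded* expectation —
the published table reports ∞ for a motif whose true expectation is 0.19,
which identifies the authors' convention. The remaining four published
expected values (GAAAAA 45, CAACA 66, AATAGAAAA 2, CAATNATTG 3 vs analytic
41.3, 67.6, 1.4, 2.3) are reproducible under no single i.i.d. convention we
could find and are treated as an open question of the source analysis, not
a target.

Monte-Carlo p-values come from control sets of n i.i.d. sequences (default
2000 sets of 43 × 1500 bp at 35% G+C) with the add-one estimator
p = (1 + #{sets ≥ observed})/(N + 1). One shared stream of control sets
scores all motifs at once — statistically identical to per-motif
simulation and several-fold cheaper. Calibration is part of the test
suite: the null mean of every bundled motif sits within 3 standard errors
of the closed form, and on no-signal data the test rejects at the nominal
5% rate within ±0.02 (checked with the 5-mer CAACA, whose count
distribution is fine-grained enough for the discrete p-value to reach the
nominal level; rarer motifs are conservative, as empirical p-values are).

Positional profiles bin match starts into 100-bp windows in upstream
coordinates (−1500 … −1, anchored at the gene start) with a per-bin
2.5/97.5-percentile envelope over simulated sets of matched size, length
and G+C. The envelope is pointwise: each bin is covered at ~95%, so with
15 bins a no-signal profile will breach *some* bin in roughly half of
datasets — positional claims should rest on the specific enriched window,
not on any-bin excursions.

## Digital expression

Hits are kept when alignment length >100 bp and identity >90% (both
strict), then reduced to one hit per read per library with a fully
deterministic tie-break (identity, then length, then gene id), so the
result is a function of the input multiset. Counts are normalised to
counts-per-million — the published analysis says only "normalized counts",
and CPM is the minimal choice at this resolution. Enrichment between two
libraries uses ratio = (a + pc)/(b + pc) with pseudo-count pc equal to the
smallest positive normalised value across the two libraries, preserving
ranks while keeping ratios finite; a gene is called for a library when the
ratio in its favour exceeds 8. MA coordinates (mean, log₂ ratio) are
emitted for plotting. No dispersion modelling is attempted: with two
unreplicated libraries a ratio threshold is all the data support.

## Synthetic test bed

The generator is a pure function of its recipe (seed mandatory). Defaults
mirror the study conditions where the source states them — the cluster rule
(200 kb / 8), promoter geometry (43 × 1500 bp at 35% G+C), expression
filters (>100 bp, >90%) and the ratio threshold 8 — and desk-scale choices
elsewhere: 3 chromosomes × 3 Mb, 14 NBS genes of 300 codons, ~200 filler
genes, placements isolated by 260 kb so planted structure cannot merge by
accident.

Family tiers mutate each member from a shared ancestor at *half* the tier's
divergence so the pairwise member divergence approximates the stated rate
(a 5% tier aligns at ~95% identity, a 25% tier at ~77%), making
tier-threshold correspondence analytic: 5% tiers cohere at the 90%
threshold, 25% tiers only at 70%. Substitution-only by default; an indel
rate exists for aligner stress tests. Segmental blocks copy a family pair
with 15 flanking genes per side, a controlled number of which are exact
copies recorded in the homology truth table (e-value 10⁻¹⁸⁰).

Motif planting realises rate r per promoter as ⌊r⌋ plus a Bernoulli
remainder, so integral rates plant exact counts; fixed positions land the
match start at the stated upstream coordinate. Planting overwrites
background bases and records every injected position.

Expression truth plants 16-fold enriched genes at means of 400 vs 25 reads,
flat genes at 150, and near-silent genes at 3. The near-silent genes are
there for realism — many resistance genes are barely transcribed — and
because the pseudo-count anchors to the smallest positive normalised value:
a dataset in which every gene is deeply expressed would inflate the
pseudo-count and shrink true ratios. A configurable fraction (default 20%)
of simulated reads is drawn below the length/identity filters.

What passing on this test bed does *not* show: the background model is the
generator's own model, so promoter calibration demonstrates internal
consistency, not robustness to dinucleotide structure or per-promoter G+C
heterogeneity in real promoters; family recovery uses substitution-only
divergence, so aligner behaviour under heavy indels is exercised only via
the optional indel rate; and filler genes are unrelated random ORFs, so the
synteny test never faces paralogous flank noise.

## Problem sizes and numerical choices

The test suite runs the Monte-Carlo calibration at the full 2000 control
sets (shared across the ten bundled motifs) with 1000 no-signal sets for
the type-I check, and planted-structure recovery over 20 seeded genomes;
these sizes give standard errors comfortably inside the asserted bands
while keeping the suite in a few minutes. The pipeline's default positional
profile uses 200 envelope simulations. All randomness flows through
`numpy.random.default_rng` seeded from the recipe or config; identical
seeds give byte-identical outputs, which the suite asserts.

## Known limitations

* The coiled-coil scorer is a calibrated reimplementation, not a clone of
  any published predictor; borderline CC calls can differ from COILS.
  Precomputed calls are first-class inputs for exactly this reason.
* The i.i.d. background has no dinucleotide or positional composition
  structure; promoters with strong CpG-like skew will miscalibrate the
  closed form (the Monte-Carlo null inherits the same assumption by
  design).
* Identity/coverage are computed from the single best local alignment;
  summed-HSP conventions used by some search pipelines will differ near
  thresholds. External hit tables are accepted unchanged for that case.
* The chi-squared enrichment test relies on expected counts that are not
  tiny; with very few genes per chromosome an exact multinomial test would
  be preferable.
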