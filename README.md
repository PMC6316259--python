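# nbskit

A toolkit for genome-wide analysis of the NBS-LRR (nucleotide-binding-site /
leucine-rich-repeat) disease-resistance gene family, written for plant
genomicists cataloguing *R*-gene repertoires in newly assembled genomes. It
implements, as one tested pipeline:

* **Domain-architecture classification** into the eight canonical classes
  (TNL, CNL, NL, RNL, XNL, N, CN, XN) from per-protein domain calls, with
  two coiled-coil detectors: a Lupas-style heptad-propensity scorer
  (threshold 0.9) and an exact degenerate-consensus scan.
* **Physical clustering** of NBS genes on chromosomes under the standard
  rule — ≥2 genes, neighbouring members <200 kb apart, ≤8 intervening
  genes — with monophyletic/mixed typing against a phylogenetic clade map,
  and a chi-squared test of chromosome-level enrichment against expectations
  proportional to chromosome length:
  χ² = Σᵢ (Oᵢ − Eᵢ)²/Eᵢ, Eᵢ = N·Lᵢ/ΣL, df = k − 1.
* **Multigene families and duplication modes**: single-linkage families over
  pairwise CDS alignments (identity > t and coverage-of-longer-gene > t,
  swept over t = 70/80/90%), tandem calls for family pairs sharing a
  physical cluster, and segmental calls when the 15-gene flanking blocks of
  the two members share >5 homologous pairs at E < 10⁻¹⁰.
* **Promoter cis-regulatory-element enrichment**: ~1500-bp strand-aware
  promoters; overlapping forward-strand IUPAC motif matches; closed-form
  expectation under an i.i.d. background with
  E = n·(L − m + 1)·Πⱼ p(classⱼ), p(G) = p(C) = GC/2; Monte-Carlo p-values
  from 2000 control sets (n = 43, 1500 bp, matched G+C) with the add-one
  estimator p = (1 + #{null ≥ obs})/(N + 1); and 100-bp positional profiles
  with a simulated 95% envelope.
* **Digital expression** from tabular read-mapping hits: filters
  (>100 bp, >90% identity, one hit per read), counts-per-million
  normalisation, and tissue-enrichment calls at a count ratio >8.
* A **synthetic-data generator** that plants known clusters, divergence-
  controlled families, segmental blocks, promoter motifs and expression
  ratios, so every stage can be scored against ground truth.

## Worked example

Run the whole pipeline on the bundled synthetic test bed (or point a YAML
config at your own FASTA/GFF3/TSV inputs):

```sh
nbskit all --seed 1 --out report/
```

In Python, the same stages compose directly:

```python
from nbskit import simulate as sim, clusters as clu, families as fam, promoters as pro

g = sim.simulate_genome(sim.default_recipe(1))
found = [clu.type_cluster(c, g.clade_map)
         for c in clu.detect_clusters(g.nbs_genes, g.all_genes)]
summary = clu.cluster_summary(found, n_mapped=len(g.nbs_genes))
```

which for seed 1 prints two planted clusters, both recovered exactly:

```
 cluster  span_kb  n_genes chromosome cluster_type
       1    102.7        3       chr1 monophyletic
       2     62.7        3       chr2 monophyletic
clustered: 6 singletons: 8
```

Six of fourteen NBS genes sit in clusters; the remaining eight are
singletons. The family sweep over the same genome,

```python
cds = {x.gene_id: x.cds for x in g.nbs_genes}
sweep = fam.threshold_sweep(fam.all_vs_all(cds), set(cds))
```

reports

```
t=70: 85.7% in 3 families, max 6, mean 4.0
t=80: 57.1% in 2 families, max 6, mean 4.0
t=90: 57.1% in 2 families, max 6, mean 4.0
```

— the high-divergence (25%) planted family passes only the 70% threshold,
while the low-divergence (5%) families persist at 90%, which is how recent
and older duplications are separated. Promoter enrichment on the matching
synthetic promoter set (two RAV1AAT elements planted per promoter):

```
RAV1AAT observed=155 in 43 promoters, expected=67.7, factor=2.28, p=0.0005
```

The observed count combines the 86 planted occurrences with the ~68
expected by chance at 35% G+C; the Monte-Carlo p-value is the add-one
estimate at its floor for 2000 control sets.

## Layout

```
src/nbskit/
  model.py       shared data model (GeneModel, Genome, DomainCall, ...)
  io.py          FASTA/GFF3/TSV/newick readers and writers
  domains.py     architecture classes, coiled-coil scorer, consensus scan
  clusters.py    physical clusters, cluster typing, chromosome enrichment
  families.py    pairwise similarity, families, tandem/segmental calls
  promoters.py   promoter extraction, motif scan, enrichment statistics
  expression.py  hit filtering, CPM normalisation, ratio calls
  simulate.py    synthetic genomes / promoters / hit tables with truth
  pipeline.py    stage orchestration with resume markers
  cli.py         command-line interface (nbskit <stage>|all|simulate)
```

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
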