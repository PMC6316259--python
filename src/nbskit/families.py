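"""Multigene families and tandem/segmental duplication classification.

Two genes belong to one family when their best local CDS alignment covers
more than a threshold percentage of the longer gene AND its identity exceeds
the same threshold (both strict); families are the connected components of
the resulting graph (single linkage). Within-family pairs are classified as
tandem when both members sit in the same physical gene cluster, or as
segmental when the 15-gene flanking blocks around the two members share more
than five homologous gene pairs at E < 1e-10; all other pairs remain
unclassified.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd
from Bio import Align

from .clusters import GeneCluster
from .model import GeneModel, ValidationError, group_by_chromosome

DNA_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class PairwiseSimilarity:
    gene_a: str
    gene_b: str
    pct_identity: float
    pct_coverage: float
    evalue: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0
                and 0.0 <= self.pct_coverage <= 100.0):
            raise ValidationError(
                f"{self.gene_a}/{self.gene_b}: identity/coverage out of range")

    @property
    def pair(self) -> FrozenSet[str]:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class FamilySet:
    threshold: float
    families: List[Set[str]]
    singletons: Set[str]

    def family_of(self) -> Dict[str, int]:
        """gene_id -> family index (families sorted by size desc, then name)."""
        ordered = sorted(self.families,
                         key=lambda fam: (-len(fam), min(fam)))
        return {g: i for i, fam in enumerate(ordered) for g in fam}

    @property
    def genes_in_families(self) -> int:
        return sum(len(f) for f in self.families)


@dataclass(frozen=True)
class DuplicationCall:
    gene_a: str
    gene_b: str
    mode: str  # tandem | segmental | unclassified
    n_syntenic_pairs: int = 0


def _make_aligner(match: float = 1.0, mismatch: float = -2.0,
                  gap_open: float = -5.0, gap_extend: float = -2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def pairwise_similarity(cds_a: str, cds_b: str, gene_a: str = "a",
                        gene_b: str = "b", match: float = 1.0,
                        mismatch: float = -2.0, gap_open: float = -5.0,
                        gap_extend: float = -2.0) -> PairwiseSimilarity:
    """Best local alignment of two CDSs as identity/coverage percentages.

    Identity is matches over alignment columns (gap columns included);
    coverage is the aligned span in the longer sequence over that sequence's
    length. Affine-gap dynamic programming; scoring parameters configurable.
    """
    for name, seq in ((gene_a, cds_a), (gene_b, cds_b)):
        if not seq:
            raise ValidationError(f"{name}: empty sequence")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValidationError(f"{name}: non-ACGTN characters {sorted(bad)}")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(cds_a, cds_b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    blocks_a, blocks_b = aln.aligned
    longer_idx = 0 if len(cds_a) >= len(cds_b) else 1
    blocks = (blocks_a, blocks_b)[longer_idx]
    span = int(blocks[-1][1] - blocks[0][0]) if len(blocks) else 0
    coverage = 100.0 * span / max(len(cds_a), len(cds_b))
    return PairwiseSimilarity(gene_a=gene_a, gene_b=gene_b,
                              pct_identity=identity, pct_coverage=coverage)


def all_vs_all(genes: Mapping[str, str], **aligner_kwargs) -> List[PairwiseSimilarity]:
    """Pairwise similarity for every unordered pair of CDSs."""
    out = []
    for a, b in itertools.combinations(sorted(genes), 2):
        out.append(pairwise_similarity(genes[a], genes[b], gene_a=a, gene_b=b,
                                       **aligner_kwargs))
    return out


def build_families(pairs: Iterable[PairwiseSimilarity], genes: Set[str],
                   threshold: float) -> FamilySet:
    """Single-linkage families over edges passing identity AND coverage.

    Both criteria are strict (> threshold); components of size one are
    singletons.
    """
    if not 0 < threshold <= 100:
        raise ValidationError("threshold must be in (0, 100]")
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for p in pairs:
        unknown = {p.gene_a, p.gene_b} - genes
        if unknown:
            raise ValidationError(f"edge references unknown genes: {sorted(unknown)}")
        if p.pct_identity > threshold and p.pct_coverage > threshold:
            graph.add_edge(p.gene_a, p.gene_b)
    families, singletons = [], set()
    for comp in nx.connected_components(graph):
        if len(comp) >= 2:
            families.append(set(comp))
        else:
            singletons.update(comp)
    families.sort(key=lambda fam: (-len(fam), min(fam)))
    return FamilySet(threshold=threshold, families=families,
                     singletons=singletons)


@dataclass(frozen=True)
class FamilyMetrics:
    pct_in_families: float
    n_families: int
    max_size: int
    mean_size: float
    mean_defined: bool = True


def family_metrics(fs: FamilySet, n_total: int) -> FamilyMetrics:
    """Share of genes in families, family count, largest and mean family size."""
    n_in = fs.genes_in_families
    if n_total < n_in:
        raise ValidationError("n_total smaller than genes in families")
    if not fs.families:
        return FamilyMetrics(0.0, 0, 0, 0.0, mean_defined=False)
    return FamilyMetrics(pct_in_families=100.0 * n_in / n_total,
                         n_families=len(fs.families),
                         max_size=max(len(f) for f in fs.families),
                         mean_size=n_in / len(fs.families))


def _flank_block(ordered: Sequence[GeneModel], idx: int, flank: int) -> Set[str]:
    lo = max(0, idx - flank)
    block = [g.gene_id for g in ordered[lo:idx]]
    block += [g.gene_id for g in ordered[idx + 1:idx + 1 + flank]]
    return set(block)


def count_syntenic_pairs(block_a: Set[str], block_b: Set[str],
                         homology: Mapping[FrozenSet[str], float],
                         max_evalue: float) -> int:
    """Cross-block homologous gene pairs, greedily matched one-to-one.

    Candidate pairs below the e-value cutoff are sorted by e-value and each
    gene participates in at most one counted pair, so a single promiscuous
    gene cannot inflate the count.
    """
    candidates = []
    for a in block_a:
        for b in block_b:
            if a == b:
                continue
            ev = homology.get(frozenset((a, b)))
            if ev is not None and ev < max_evalue:
                candidates.append((ev, a, b))
    candidates.sort()
    used_a: Set[str] = set()
    used_b: Set[str] = set()
    n = 0
    for _, a, b in candidates:
        if a not in used_a and b not in used_b:
            used_a.add(a)
            used_b.add(b)
            n += 1
    return n


def classify_duplications(fs: FamilySet, clusters: Sequence[GeneCluster],
                          all_genes: Sequence[GeneModel],
                          homology: Mapping[FrozenSet[str], float],
                          flank: int = 15, min_pairs: int = 5,
                          max_evalue: float = 1e-10) -> List[DuplicationCall]:
    """Label within-family pairs as tandem, segmental or unclassified.

    Tandem: both members in one detected cluster (takes precedence).
    Segmental: the two members' flanking blocks (``flank`` annotated genes
    per side, fewer at chromosome ends, member excluded) share more than
    ``min_pairs`` homologous gene pairs at ``evalue < max_evalue``.
    """
    if flank < 1:
        raise ValidationError("flank must be >= 1")
    cluster_of: Dict[str, int] = {}
    for c in clusters:
        for g in c.members:
            cluster_of[g] = c.cluster_id
    by_chrom = group_by_chromosome(all_genes)
    index_of: Dict[str, Tuple[str, int]] = {}
    for chrom, ordered in by_chrom.items():
        for i, g in enumerate(ordered):
            index_of[g.gene_id] = (chrom, i)

    calls: List[DuplicationCall] = []
    for fam in fs.families:
        for a, b in itertools.combinations(sorted(fam), 2):
            if a in cluster_of and cluster_of.get(a) == cluster_of.get(b):
                calls.append(DuplicationCall(a, b, "tandem"))
                continue
            if a not in index_of or b not in index_of:
                calls.append(DuplicationCall(a, b, "unclassified"))
                continue
            chrom_a, ia = index_of[a]
            chrom_b, ib = index_of[b]
            block_a = _flank_block(by_chrom[chrom_a], ia, flank)
            block_b = _flank_block(by_chrom[chrom_b], ib, flank)
            n_syn = count_syntenic_pairs(block_a - {b}, block_b - {a},
                                         homology, max_evalue)
            if n_syn > min_pairs:
                calls.append(DuplicationCall(a, b, "segmental", n_syn))
            else:
                calls.append(DuplicationCall(a, b, "unclassified", n_syn))
    return calls


@dataclass
class SweepResult:
    family_sets: Dict[float, FamilySet]
    metrics: Dict[float, FamilyMetrics]
    transitions: pd.DataFrame  # gene x threshold -> family id (singleton: -1)


def threshold_sweep(pairs: Sequence[PairwiseSimilarity], genes: Set[str],
                    thresholds: Sequence[float] = (70, 80, 90)) -> SweepResult:
    """Family construction at each threshold plus a membership-transition table.

    Thresholds must be ascending; the transition table is consumable by
    alluvial plotters (one row per gene, one column per threshold, -1 for
    singletons).
    """
    if list(thresholds) != sorted(thresholds):
        raise ValidationError("thresholds must be sorted ascending")
    family_sets, metrics = {}, {}
    columns = {}
    for t in thresholds:
        fs = build_families(pairs, genes, t)
        family_sets[t] = fs
        metrics[t] = family_metrics(fs, n_total=len(genes))
        fam_of = fs.family_of()
        columns[f"t{t:g}"] = {g: fam_of.get(g, -1) for g in genes}
    transitions = pd.DataFrame(columns, index=sorted(genes))
    transitions.index.name = "gene_id"
    return SweepResult(family_sets=family_sets, metrics=metrics,
                       transitions=transitions)
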