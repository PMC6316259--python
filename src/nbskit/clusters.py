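"""Physical clustering of NBS genes and chromosome-level enrichment.

A cluster is a maximal run of NBS genes on one chromosome in which every
consecutive pair is separated by less than ``max_gap_kb`` (edge-to-edge,
start of the next minus end of the previous) with at most
``max_intervening`` non-NBS genes between them; runs need at least
``min_size`` members. Clusters are typed monophyletic or mixed against a
phylogenetic clade map. Chromosome-level enrichment is a chi-squared test
of observed gene counts against expectations proportional to chromosome
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd
from scipy.stats import chisquare

from .model import CladeMap, GeneModel, ValidationError, group_by_chromosome


@dataclass
class GeneCluster:
    cluster_id: int
    chromosome: str
    members: List[str]
    span_kb: float
    n_intervening: int
    cluster_type: str = "untyped"

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValidationError("a cluster needs at least two members")
        if self.cluster_type not in ("monophyletic", "mixed", "untyped"):
            raise ValidationError(f"bad cluster_type {self.cluster_type!r}")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class EnrichmentTest:
    observed: Dict[str, int]
    expected: Dict[str, float]
    statistic: float
    p_value: float


def detect_clusters(nbs_genes: Sequence[GeneModel],
                    all_genes: Sequence[GeneModel],
                    max_gap_kb: float = 200.0,
                    max_intervening: int = 8,
                    min_size: int = 2) -> List[GeneCluster]:
    """Maximal runs of NBS genes satisfying the physical-cluster rule.

    ``all_genes`` is the complete annotation (NBS genes included) and is
    used to count intervening non-NBS genes. Runs shorter than ``min_size``
    are discarded; clusters never span chromosomes.
    """
    nbs_ids = {g.gene_id for g in nbs_genes}
    all_ids = {g.gene_id for g in all_genes}
    missing = nbs_ids - all_ids
    if missing:
        raise ValidationError(
            f"NBS genes absent from the annotation: {sorted(missing)}")

    by_chrom = group_by_chromosome(all_genes)
    clusters: List[GeneCluster] = []
    next_id = 1
    for chrom in sorted(by_chrom):
        ordered = by_chrom[chrom]
        nbs_idx = [i for i, g in enumerate(ordered) if g.gene_id in nbs_ids]
        run: List[int] = []
        run_intervening = 0

        def flush(run, run_intervening, next_id):
            if len(run) >= min_size:
                first, last = ordered[run[0]], ordered[run[-1]]
                clusters.append(GeneCluster(
                    cluster_id=next_id, chromosome=chrom,
                    members=[ordered[i].gene_id for i in run],
                    span_kb=(last.end - first.start) / 1000.0,
                    n_intervening=run_intervening))
                return next_id + 1
            return next_id

        for i in nbs_idx:
            if not run:
                run, run_intervening = [i], 0
                continue
            prev = ordered[run[-1]]
            cur = ordered[i]
            gap_kb = (cur.start - prev.end) / 1000.0
            between = sum(1 for j in range(run[-1] + 1, i)
                          if ordered[j].gene_id not in nbs_ids)
            if gap_kb < max_gap_kb and between <= max_intervening:
                run.append(i)
                run_intervening += between
            else:
                next_id = flush(run, run_intervening, next_id)
                run, run_intervening = [i], 0
        next_id = flush(run, run_intervening, next_id)
    return clusters


def type_cluster(cluster: GeneCluster, clades: CladeMap) -> GeneCluster:
    """Type a cluster against clade assignments.

    Monophyletic when all assigned members share one clade; mixed when two
    or more clades occur; untyped when fewer than two members carry an
    assignment.
    """
    labels = [clades.get(g) for g in cluster.members]
    labels = [lb for lb in labels if lb is not None]
    if len(labels) < 2:
        ctype = "untyped"
    elif len(set(labels)) == 1:
        ctype = "monophyletic"
    else:
        ctype = "mixed"
    return replace(cluster, cluster_type=ctype)


@dataclass
class ClusterSummary:
    table: pd.DataFrame
    genes_in_clusters: int
    n_singletons: int
    n_clusters: int
    largest_cluster: int


def cluster_summary(clusters: Sequence[GeneCluster],
                    n_mapped: int) -> ClusterSummary:
    """Per-cluster table plus the clustered/singleton tally."""
    rows = [{"cluster": c.cluster_id, "span_kb": round(c.span_kb, 2),
             "n_genes": c.size, "n_intervening": c.n_intervening,
             "chromosome": c.chromosome, "members": ",".join(c.members),
             "cluster_type": c.cluster_type}
            for c in clusters]
    table = pd.DataFrame(rows, columns=["cluster", "span_kb", "n_genes",
                                        "n_intervening", "chromosome",
                                        "members", "cluster_type"])
    in_clusters = int(table["n_genes"].sum()) if len(table) else 0
    return ClusterSummary(table=table, genes_in_clusters=in_clusters,
                          n_singletons=n_mapped - in_clusters,
                          n_clusters=len(clusters),
                          largest_cluster=int(table["n_genes"].max()) if len(table) else 0)


def chromosome_enrichment(counts: Mapping[str, int],
                          lengths: Mapping[str, int]) -> EnrichmentTest:
    """Chi-squared test of gene counts vs chromosome-length expectation.

    Expected count per chromosome is proportional to its length; the test
    uses only the chromosomes present in ``counts`` and (k-1) degrees of
    freedom, with no continuity correction.
    """
    chroms = sorted(counts)
    missing = [c for c in chroms if c not in lengths]
    if missing:
        raise ValidationError(f"no length for chromosomes: {missing}")
    for c in chroms:
        if lengths[c] <= 0:
            raise ValidationError(f"zero-length chromosome {c!r}")
    total = sum(counts[c] for c in chroms)
    if total < 1:
        raise ValidationError("at least one gene count required")
    total_len = sum(lengths[c] for c in chroms)
    expected = {c: total * lengths[c] / total_len for c in chroms}
    stat, p = chisquare([counts[c] for c in chroms],
                        f_exp=[expected[c] for c in chroms])
    return EnrichmentTest(observed=dict(counts), expected=expected,
                          statistic=float(stat), p_value=float(p))
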