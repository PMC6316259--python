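"""Synthetic genomes, promoters and hit tables with planted, known structure.

Every generator is a pure function of its recipe (seed included), and each
emits a truth table sufficient to score the corresponding pipeline stage
without re-deriving ground truth:

* :func:`simulate_genome` — chromosomes of i.i.d. background DNA carrying
  planted NBS gene clusters (gaps obeying or violating the 200-kb rule),
  gene families built by copy-and-mutate at controlled divergence, and
  segmentally duplicated blocks with a controlled number of homologous
  flanking-gene pairs;
* :func:`simulate_promoters` — fixed-length promoters at a stated G+C with
  motifs planted at controlled rates and positions;
* :func:`simulate_hits` — read-mapping hit tables with controlled
  per-library count ratios and a stated fraction of reads failing the
  length/identity filters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import yaml
from Bio.Seq import Seq

from .model import (CladeMap, DomainCall, GeneModel, Genome, HitRecord,
                    ValidationError, reverse_complement)
from .promoters import IUPAC_SETS, Motif, PromoterSet

_BASES = np.array(list("ACGT"), dtype="U1")
_NONSTOP_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                   if a + b + c not in ("TAA", "TAG", "TGA")]


class GeometryError(ValueError):
    """Planted geometry does not fit on the chromosomes."""


@dataclass(frozen=True)
class PlantedCluster:
    chromosome: str
    n_genes: int
    gap_kb: float          # edge-to-edge gap planted between consecutive members
    n_intervening: int     # non-NBS genes planted inside each gap


@dataclass(frozen=True)
class FamilyTier:
    n_genes: int
    divergence: float      # target pairwise substitution fraction between members


@dataclass(frozen=True)
class SegmentalBlock:
    n_flank_homologs: int  # flanking-gene pairs shared between the two blocks
    block_size: int = 15   # flanking genes per side


@dataclass(frozen=True)
class PlantedMotif:
    motif: Motif
    rate: float                      # planted occurrences per promoter
    position: Optional[int] = None   # fixed upstream coordinate (e.g. -550)


@dataclass
class SimulationRecipe:
    """Parameters of the synthetic study; the defaults mirror the real one
    at desk scale (cluster rule 200 kb / 8, promoters 43 x 1500 bp at 35%
    G+C, library filters >100 bp / >90% identity, ratio threshold 8)."""

    seed: int
    n_chromosomes: int = 3
    chrom_length: int = 3_000_000
    n_nbs: int = 14
    planted_clusters: List[PlantedCluster] = field(default_factory=list)
    family_tiers: List[FamilyTier] = field(default_factory=list)
    segmental_blocks: List[SegmentalBlock] = field(default_factory=list)
    genome_gc: float = 0.35
    cds_codons: int = 300
    indel_rate: float = 0.0
    promoter_gc: float = 0.35
    n_promoters: int = 43
    promoter_length: int = 1500
    planted_motifs: List[PlantedMotif] = field(default_factory=list)
    expression_truth: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    library_sizes: Dict[str, int] = field(
        default_factory=lambda: {"leaf": 1_000_000, "root": 1_000_000})
    hit_fail_rate: float = 0.2
    ratio_threshold: float = 8.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        for t in self.family_tiers:
            if not 0 <= t.divergence <= 1:
                raise ValidationError("tier divergence must be in [0, 1]")
        for m in self.planted_motifs:
            if m.rate < 0:
                raise ValidationError("motif rate must be >= 0")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["planted_motifs"] = [
            {"name": m.motif.name, "iupac": m.motif.iupac, "rate": m.rate,
             "position": m.position} for m in self.planted_motifs]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationRecipe":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["planted_clusters"] = [PlantedCluster(**c)
                                    for c in data.get("planted_clusters", [])]
        data["family_tiers"] = [FamilyTier(**t)
                                for t in data.get("family_tiers", [])]
        data["segmental_blocks"] = [SegmentalBlock(**b)
                                    for b in data.get("segmental_blocks", [])]
        data["planted_motifs"] = [
            PlantedMotif(motif=Motif(m["name"], m["iupac"]), rate=m["rate"],
                         position=m.get("position"))
            for m in data.get("planted_motifs", [])]
        data["expression_truth"] = {g: tuple(v) for g, v in
                                    data.get("expression_truth", {}).items()}
        return cls(**data)


def default_recipe(seed: int) -> SimulationRecipe:
    """The bundled study-shaped recipe: two clustered low-divergence family
    groups, one high-divergence dispersed family, one segmental pair, and a
    20-gene expression truth with planted 16-fold tissue ratios."""
    expression = {}
    for i in range(1, 6):
        expression[f"NBS{i:03d}"] = (400.0, 25.0)    # leaf-enriched (16x)
    for i in range(6, 11):
        expression[f"NBS{i:03d}"] = (25.0, 400.0)    # root-enriched (16x)
    for i in range(11, 13):
        expression[f"NBS{i:03d}"] = (150.0, 150.0)
    for i in range(13, 15):
        expression[f"NBS{i:03d}"] = (3.0, 3.0)       # near-silent background
    return SimulationRecipe(
        seed=seed,
        n_chromosomes=3,
        n_nbs=14,
        planted_clusters=[PlantedCluster("chr1", 3, 50.0, 2),
                          PlantedCluster("chr2", 3, 30.0, 0)],
        family_tiers=[FamilyTier(6, 0.05), FamilyTier(4, 0.25),
                      FamilyTier(2, 0.05)],
        segmental_blocks=[SegmentalBlock(n_flank_homologs=8)],
        planted_motifs=[PlantedMotif(Motif("RAV1AAT", "CAACA"), 2.0, None),
                        PlantedMotif(Motif("MYCATERD22", "CACATG"), 1.0, -550)],
        expression_truth=expression,
    )


def _random_orf(n_codons: int, rng: np.random.Generator) -> str:
    codons = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 1)
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in codons)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = base_codes[base_codes != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _random_dna(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return np.searchsorted(cum, rng.random(length)).astype(np.uint8)


_CLASS_MIX = [("CNL", 29), ("NL", 6), ("RNL", 4), ("XNL", 3), ("N", 4),
              ("CN", 2), ("XN", 1)]
_CLADES = ["Ia", "Ib", "II", "III"]


@dataclass
class SimulatedGenome:
    genome: Genome
    all_genes: List[GeneModel]
    nbs_genes: List[GeneModel]
    domain_calls: List[DomainCall]
    clade_map: CladeMap
    cluster_truth: List[List[str]]
    family_truth: Dict[str, int]                 # gene -> tier index
    duplication_truth: Dict[FrozenSet[str], str]  # pair -> tandem|segmental
    homology: Dict[FrozenSet[str], float]        # gene pair -> e-value
    class_truth: Dict[str, str]

    @property
    def nbs_ids(self) -> List[str]:
        return [g.gene_id for g in self.nbs_genes]


def _domain_calls_for(gene_id: str, cls: str, prot_len: int) -> List[DomainCall]:
    calls = [DomainCall(gene_id, "NBS", 160, min(460, prot_len), "PFAM", 50.0)]
    if cls in ("CNL", "CN"):
        calls.append(DomainCall(gene_id, "CC", 35, 80, "COILS", 0.95))
    if cls in ("XNL", "XN"):
        calls.append(DomainCall(gene_id, "CC", 35, 80, "CDD", 10.0))
    if cls == "RNL":
        calls.append(DomainCall(gene_id, "RPW8", 20, 120, "PFAM", 30.0))
    if cls.endswith("L"):
        calls.append(DomainCall(gene_id, "LRR", min(470, prot_len - 1),
                                prot_len, "PFAM", 40.0))
    return calls


class _ChromosomeBuilder:
    """Places genes left-to-right on one chromosome."""

    ISOLATION_BP = 260_000     # > the 200-kb rule, so separate placements
    ISOLATION_FILLERS = 10     # > the 8-intervening rule
    FILLER_CODONS = 120
    LOCAL_GAP = 2_000

    def __init__(self, name: str, length: int, rng: np.random.Generator):
        self.name = name
        self.length = length
        self.rng = rng
        self.cursor = 40_000
        self.placed: List[GeneModel] = []
        self._n_fillers = 0

    def _check(self) -> None:
        if self.cursor > self.length:
            raise GeometryError(
                f"{self.name}: planted geometry overflows chromosome "
                f"({self.cursor} > {self.length} bp)")

    def _place(self, gene_id: str, cds: str, strand: str,
               n_variants: int = 1) -> GeneModel:
        start = self.cursor
        end = start + len(cds) - 1
        gene = GeneModel(gene_id=gene_id, chromosome=self.name, start=start,
                         end=end, strand=strand, cds=cds,
                         protein=str(Seq(cds).translate()),
                         n_variants=n_variants)
        self.placed.append(gene)
        self.cursor = end + 1
        self._check()
        return gene

    def filler(self, cds: Optional[str] = None,
               gene_id: Optional[str] = None) -> GeneModel:
        if cds is None:
            cds = _random_orf(self.FILLER_CODONS, self.rng)
        if gene_id is None:
            self._n_fillers += 1
            gene_id = f"FIL_{self.name}_{self._n_fillers:04d}"
        return self._place(gene_id, cds, "+")

    def advance(self, bp: int) -> None:
        self.cursor += bp
        self._check()

    def isolate(self) -> None:
        """Advance far enough that the next gene cannot join a previous run."""
        step = self.ISOLATION_BP // self.ISOLATION_FILLERS
        for _ in range(self.ISOLATION_FILLERS):
            self.advance(step - self.FILLER_CODONS * 3)
            self.filler()


def simulate_genome(recipe: SimulationRecipe) -> SimulatedGenome:
    """Generate the genome, annotation and truth tables of the recipe.

    NBS genes are drawn from the family tiers in order (each member mutated
    from the tier ancestor at half the tier divergence, so pairwise member
    divergence approximates the recipe value), topped up with unrelated
    genes to ``n_nbs``. Planted clusters consume genes from the front of
    that list; segmental blocks consume pairs from the back of the tiered
    members; everything else is placed as isolated singletons.
    """
    rng = np.random.default_rng(recipe.seed)

    # --- NBS gene sequences -------------------------------------------------
    tier_members: List[Tuple[str, int]] = []   # (gene_id, tier index)
    cds_of: Dict[str, str] = {}
    gid = itertools.count(1)
    for ti, tier in enumerate(recipe.family_tiers):
        ancestor = _random_orf(recipe.cds_codons, rng)
        for _ in range(tier.n_genes):
            g = f"NBS{next(gid):03d}"
            cds_of[g] = _mutate(ancestor, tier.divergence / 2, rng)
            if recipe.indel_rate > 0:
                cds_of[g] = _apply_indels(cds_of[g], recipe.indel_rate, rng)
            tier_members.append((g, ti))
    n_tiered = len(tier_members)
    if recipe.n_nbs < n_tiered:
        raise ValidationError("n_nbs smaller than the family tiers' total")
    extras = []
    for _ in range(recipe.n_nbs - n_tiered):
        g = f"NBS{next(gid):03d}"
        cds_of[g] = _random_orf(recipe.cds_codons, rng)
        extras.append((g, -1))

    family_truth = {g: ti for g, ti in tier_members}

    # --- assignment ---------------------------------------------------------
    queue = [g for g, _ in tier_members] + [g for g, _ in extras]
    cluster_truth: List[List[str]] = []
    for pc in recipe.planted_clusters:
        if pc.n_genes > len(queue):
            raise ValidationError("not enough NBS genes for planted clusters")
        cluster_truth.append([queue.pop(0) for _ in range(pc.n_genes)])
    seg_pairs: List[Tuple[str, str]] = []
    tiered_left = [g for g in queue if family_truth.get(g, -1) >= 0]
    for sb in recipe.segmental_blocks:
        if len(tiered_left) < 2:
            raise ValidationError("not enough tiered genes for segmental blocks")
        b = tiered_left.pop()
        a = tiered_left.pop()
        queue.remove(a)
        queue.remove(b)
        seg_pairs.append((a, b))
    singletons = list(queue)

    # --- layout -------------------------------------------------------------
    chrom_names = [f"chr{i + 1}" for i in range(recipe.n_chromosomes)]
    builders = {c: _ChromosomeBuilder(c, recipe.chrom_length, rng)
                for c in chrom_names}
    homology: Dict[FrozenSet[str], float] = {}
    duplication_truth: Dict[FrozenSet[str], str] = {}

    def nbs_strand() -> str:
        return "+" if rng.random() < 0.8 else "-"

    def nbs_cds(g: str) -> str:
        return cds_of[g]

    variant_choices = np.array([2, 3, 5, 7])

    def place_nbs(builder: _ChromosomeBuilder, g: str) -> GeneModel:
        n_var = 1
        if rng.random() < 0.14:
            n_var = int(rng.choice(variant_choices))
        return builder._place(g, nbs_cds(g), nbs_strand(), n_var)

    for pc, members in zip(recipe.planted_clusters, cluster_truth):
        if pc.chromosome not in builders:
            raise ValidationError(f"unknown chromosome {pc.chromosome!r}")
        b = builders[pc.chromosome]
        b.isolate()
        prev = place_nbs(b, members[0])
        for g in members[1:]:
            gap_bp = int(pc.gap_kb * 1000)
            filler_span = pc.n_intervening * (b.FILLER_CODONS * 3 + b.LOCAL_GAP)
            if gap_bp <= filler_span:
                raise GeometryError(
                    f"cluster gap {pc.gap_kb} kb cannot hold "
                    f"{pc.n_intervening} intervening genes")
            lead = (gap_bp - filler_span) // 2
            b.advance(lead)
            for _ in range(pc.n_intervening):
                b.filler()
                b.advance(b.LOCAL_GAP)
            b.advance(gap_bp - filler_span - lead)
            place_nbs(b, g)

    for si, (sb, (a, b_gene)) in enumerate(zip(recipe.segmental_blocks,
                                               seg_pairs)):
        src_chrom = chrom_names[si % len(chrom_names)]
        dst_chrom = chrom_names[(si + len(chrom_names) - 1) % len(chrom_names)]
        src = builders[src_chrom]
        dst = builders[dst_chrom]
        if sb.n_flank_homologs > 2 * sb.block_size:
            raise ValidationError("more flank homologs than flank genes")
        src.isolate()
        dst.isolate()
        left = [_random_orf(src.FILLER_CODONS, rng)
                for _ in range(sb.block_size)]
        right = [_random_orf(src.FILLER_CODONS, rng)
                 for _ in range(sb.block_size)]
        src_flank_ids: List[str] = []
        for cds in left:
            src_flank_ids.append(src.filler(cds=cds).gene_id)
            src.advance(src.LOCAL_GAP)
        place_nbs(src, a)
        for cds in right:
            src.advance(src.LOCAL_GAP)
            src_flank_ids.append(src.filler(cds=cds).gene_id)
        # destination block: first n_flank_homologs flank genes are copies
        order = list(range(2 * sb.block_size))
        dst_flank_cds = left + right
        dst_ids: List[str] = []
        for k in order[:sb.block_size]:
            copied = k < sb.n_flank_homologs
            gm = dst.filler(cds=dst_flank_cds[k] if copied else
                            _random_orf(dst.FILLER_CODONS, rng))
            if copied:
                homology[frozenset((src_flank_ids[k], gm.gene_id))] = 1e-180
            dst.advance(dst.LOCAL_GAP)
        place_nbs(dst, b_gene)
        for k in order[sb.block_size:]:
            copied = k < sb.n_flank_homologs
            dst.advance(dst.LOCAL_GAP)
            gm = dst.filler(cds=dst_flank_cds[k] if copied else
                            _random_orf(dst.FILLER_CODONS, rng))
            if copied:
                homology[frozenset((src_flank_ids[k], gm.gene_id))] = 1e-180
        duplication_truth[frozenset((a, b_gene))] = "segmental"

    for i, g in enumerate(singletons):
        b = builders[chrom_names[i % len(chrom_names)]]
        b.isolate()
        place_nbs(b, g)
    for b in builders.values():
        b.isolate()   # trailing fillers so late NBS genes have flanks

    # tandem truth: within-tier pairs planted in the same cluster
    for members in cluster_truth:
        for x, y in itertools.combinations(members, 2):
            if (family_truth.get(x, -2) == family_truth.get(y, -3)):
                duplication_truth[frozenset((x, y))] = "tandem"

    # --- sequences ----------------------------------------------------------
    sequences: Dict[str, str] = {}
    for name in chrom_names:
        arr = _random_dna(recipe.chrom_length, recipe.genome_gc, rng)
        chrom = _BASES[arr]
        for gene in builders[name].placed:
            seq = gene.cds if gene.strand == "+" else reverse_complement(gene.cds)
            chrom[gene.start - 1:gene.end] = list(seq)
        sequences[name] = "".join(chrom)

    all_genes = sorted((g for b in builders.values() for g in b.placed),
                       key=lambda g: (g.chromosome, g.start))
    nbs_set = set(cds_of)
    nbs_genes = [g for g in all_genes if g.gene_id in nbs_set]

    # --- domain calls, classes, clades -------------------------------------
    class_labels = [c for c, n in _CLASS_MIX for _ in range(n)]
    class_truth: Dict[str, str] = {}
    domain_calls: List[DomainCall] = []
    for g in nbs_genes:
        cls = class_labels[int(rng.integers(0, len(class_labels)))]
        class_truth[g.gene_id] = cls
        domain_calls.extend(_domain_calls_for(g.gene_id, cls, len(g.protein)))
    clade_assign = {}
    for g in nbs_genes:
        ti = family_truth.get(g.gene_id, -1)
        clade_assign[g.gene_id] = (_CLADES[ti % len(_CLADES)] if ti >= 0
                                   else _CLADES[int(rng.integers(0, 4))])

    return SimulatedGenome(
        genome=Genome(sequences=sequences), all_genes=all_genes,
        nbs_genes=nbs_genes, domain_calls=domain_calls,
        clade_map=CladeMap(assignments=clade_assign),
        cluster_truth=cluster_truth, family_truth=family_truth,
        duplication_truth=duplication_truth, homology=homology,
        class_truth=class_truth)


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:
            continue                       # deletion
        out.append(ch)
        if r > 1 - rate / 2:
            out.append("ACGT"[int(rng.integers(0, 4))])  # insertion
    return "".join(out)


@dataclass(frozen=True)
class PlantedOccurrence:
    seq_id: str
    motif_name: str
    start: int        # 1-based within the promoter
    coordinate: int   # upstream coordinate of the match start


def simulate_promoters(recipe: SimulationRecipe
                       ) -> Tuple[PromoterSet, List[PlantedOccurrence]]:
    """Promoter set at the recipe's G+C with motifs planted per the recipe.

    The planting rate r per promoter is realised as floor(r) plus a
    Bernoulli(frac(r)) extra, so integral rates plant exact counts. A fixed
    ``position`` places the match start at that upstream coordinate;
    otherwise positions are uniform. Collisions with already-planted
    occurrences are re-drawn (bounded retries) and finally an error.
    """
    rng = np.random.default_rng(recipe.seed + 1)
    L = recipe.promoter_length
    truth: List[PlantedOccurrence] = []
    sequences: Dict[str, str] = {}
    for i in range(recipe.n_promoters):
        seq_id = f"prom{i + 1:03d}"
        arr = _BASES[_random_dna(L, recipe.promoter_gc, rng)]
        occupied: List[Tuple[int, int]] = []
        for pm in recipe.planted_motifs:
            m = len(pm.motif)
            count = int(pm.rate) + (1 if rng.random() < pm.rate % 1 else 0)
            for _ in range(count):
                placed = False
                for _attempt in range(100):
                    if pm.position is not None:
                        idx0 = L + pm.position   # coord -550 -> 0-based index
                        if not 0 <= idx0 <= L - m:
                            raise ValidationError(
                                f"position {pm.position} does not fit")
                    else:
                        idx0 = int(rng.integers(0, L - m + 1))
                    if any(idx0 < e and idx0 + m > s for s, e in occupied):
                        if pm.position is not None:
                            break   # fixed position occupied: skip silently
                        continue
                    real = "".join(
                        IUPAC_SETS[letter][int(rng.integers(0, len(IUPAC_SETS[letter])))]
                        for letter in pm.motif.iupac)
                    arr[idx0:idx0 + m] = list(real)
                    occupied.append((idx0, idx0 + m))
                    truth.append(PlantedOccurrence(
                        seq_id=seq_id, motif_name=pm.motif.name,
                        start=idx0 + 1, coordinate=idx0 - L))
                    placed = True
                    break
                if not placed and pm.position is None:
                    raise GeometryError(
                        f"could not place motif {pm.motif.name} without collision")
        sequences[seq_id] = "".join(arr)
    return PromoterSet(sequences=sequences, target_length=L), truth


@dataclass(frozen=True)
class ExpressionTruthLabel:
    gene_id: str
    label: str   # library id or "none"


def simulate_hits(recipe: SimulationRecipe
                  ) -> Tuple[List[HitRecord], List[ExpressionTruthLabel]]:
    """Hit tables with planted per-library count means.

    Per gene and library, read counts are Poisson with the truth mean; a
    ``hit_fail_rate`` fraction of reads is drawn below the length or
    identity filter thresholds. The truth records the intended enrichment
    label from the ratio of the planted means.
    """
    if not recipe.expression_truth:
        raise ValidationError("expression_truth is empty")
    libs = sorted(recipe.library_sizes)
    if len(libs) != 2:
        raise ValidationError("exactly two libraries expected")
    rng = np.random.default_rng(recipe.seed + 2)
    hits: List[HitRecord] = []
    labels: List[ExpressionTruthLabel] = []
    for gene, means in sorted(recipe.expression_truth.items()):
        mean_by_lib = dict(zip(libs, means))
        for lib in libs:
            n = int(rng.poisson(mean_by_lib[lib]))
            for r in range(n):
                fail = rng.random() < recipe.hit_fail_rate
                if fail and rng.random() < 0.5:
                    length = int(rng.integers(30, 101))      # <= 100 bp
                    ident = float(rng.uniform(91, 100))
                elif fail:
                    length = int(rng.integers(120, 301))
                    ident = float(rng.uniform(75, 90))       # <= 90 %
                else:
                    length = int(rng.integers(120, 301))
                    ident = float(rng.uniform(91, 100))
                hits.append(HitRecord(read_id=f"{lib}:{gene}:{r}",
                                      gene_id=gene, aln_length=length,
                                      pct_identity=round(ident, 2),
                                      library_id=lib))
        a, b = (mean_by_lib[libs[0]], mean_by_lib[libs[1]])
        if b > 0 and a / b > recipe.ratio_threshold:
            label = libs[0]
        elif a > 0 and b / a > recipe.ratio_threshold:
            label = libs[1]
        else:
            label = "none"
        labels.append(ExpressionTruthLabel(gene_id=gene, label=label))
    return hits, labels
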