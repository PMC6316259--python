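import itertools

import numpy as np
import pytest

from nbskit import clusters as clu
from nbskit import families as fam
from nbskit.model import ValidationError
from conftest import make_gene


def mutated_copy(seq, n_subs, rng):
    out = list(seq)
    for i in rng.choice(len(seq), size=n_subs, replace=False):
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


def random_dna(n, rng):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestPairwiseSimilarity:
    def test_identical_sequences(self):
        s = fam.pairwise_similarity("ACGT" * 75, "ACGT" * 75)
        assert s.pct_identity == pytest.approx(100.0)
        assert s.pct_coverage == pytest.approx(100.0)

    def test_ten_percent_substitutions(self, rng):
        a = random_dna(300, rng)
        b = mutated_copy(a, 30, rng)
        s = fam.pairwise_similarity(a, b)
        # local alignment may trim a few terminal mismatches
        assert 88.0 <= s.pct_identity <= 92.5
        assert s.pct_coverage >= 97.0

    def test_unrelated_sequences_low_coverage(self):
        rng = np.random.default_rng(5)
        low = sum(fam.pairwise_similarity(random_dna(300, rng),
                                          random_dna(300, rng)).pct_coverage < 70
                  for _ in range(100))
        assert low >= 95

    def test_non_dna_characters_rejected(self):
        with pytest.raises(ValidationError):
            fam.pairwise_similarity("ACGT", "ACQT")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            fam.pairwise_similarity("", "ACGT")


def edge(a, b, ident=95.0, cov=95.0):
    return fam.PairwiseSimilarity(gene_a=a, gene_b=b, pct_identity=ident,
                                  pct_coverage=cov)


def brute_force_families(pairs, genes, threshold):
    """Oracle: repeated-pass transitive closure over passing edges."""
    parent = {g: {g} for g in genes}
    groups = [set([g]) for g in genes]
    passing = [(p.gene_a, p.gene_b) for p in pairs
               if p.pct_identity > threshold and p.pct_coverage > threshold]
    changed = True
    while changed:
        changed = False
        for a, b in passing:
            ga = next(g for g in groups if a in g)
            gb = next(g for g in groups if b in g)
            if ga is not gb:
                groups.remove(gb)
                ga.update(gb)
                changed = True
    return sorted(sorted(g) for g in groups if len(g) >= 2)


class TestBuildFamilies:
    def test_single_linkage_chain(self):
        pairs = [edge("a", "b"), edge("b", "c"), edge("a", "c", ident=50)]
        fs = fam.build_families(pairs, {"a", "b", "c"}, 70)
        assert fs.families == [{"a", "b", "c"}]

    def test_no_passing_edges_all_singletons(self):
        fs = fam.build_families([edge("a", "b", ident=10, cov=10)],
                                {"a", "b", "c"}, 70)
        assert fs.families == [] and fs.singletons == {"a", "b", "c"}

    def test_threshold_strict(self):
        fs = fam.build_families([edge("a", "b", ident=70.0, cov=90.0)],
                                {"a", "b"}, 70)
        assert fs.families == []  # identity must exceed the threshold

    def test_unknown_gene_error(self):
        with pytest.raises(ValidationError):
            fam.build_families([edge("a", "zz")], {"a", "b"}, 70)

    def test_matches_bruteforce_closure(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(3, 50))
            genes = {f"g{i}" for i in range(n)}
            pairs = []
            for a, b in itertools.combinations(sorted(genes), 2):
                if rng.random() < 0.15:
                    pairs.append(edge(a, b, ident=float(rng.uniform(40, 100)),
                                      cov=float(rng.uniform(40, 100))))
            fs = fam.build_families(pairs, genes, 70)
            got = sorted(sorted(f) for f in fs.families)
            assert got == brute_force_families(pairs, genes, 70)

    def test_refinement_across_thresholds(self, sim_genome):
        cds = {g.gene_id: g.cds for g in sim_genome.nbs_genes}
        pairs = fam.all_vs_all(cds)
        sweep = fam.threshold_sweep(pairs, set(cds), thresholds=[70, 80, 90])
        for t1, t2 in [(70, 80), (80, 90)]:
            fams1 = sweep.family_sets[t1].families
            for f2 in sweep.family_sets[t2].families:
                assert any(f2 <= f1 for f1 in fams1)


class TestFamilyMetrics:
    def test_published_style_metrics(self):
        fs = fam.FamilySet(threshold=70,
                           families=[set(f"a{i}" for i in range(19)),
                                     set(f"b{i}" for i in range(4)),
                                     set(f"c{i}" for i in range(3)),
                                     set(f"d{i}" for i in range(2)),
                                     set(f"e{i}" for i in range(2))],
                           singletons=set())
        m = fam.family_metrics(fs, n_total=49)
        assert m.pct_in_families == pytest.approx(61.2, abs=0.05)
        assert m.mean_size == pytest.approx(6.0)
        assert m.max_size == 19
        assert m.max_size / fs.genes_in_families == pytest.approx(0.633,
                                                                  abs=0.005)

    def test_two_gene_universe(self):
        fs = fam.FamilySet(threshold=70, families=[{"a", "b"}],
                           singletons=set())
        m = fam.family_metrics(fs, n_total=2)
        assert m.pct_in_families == 100.0 and m.mean_size == 2

    def test_empty_families_flagged(self):
        fs = fam.FamilySet(threshold=70, families=[], singletons={"a"})
        m = fam.family_metrics(fs, n_total=1)
        assert m.mean_size == 0.0 and not m.mean_defined


class TestClassifyDuplications:
    def test_cluster_pair_is_tandem(self):
        genes = [make_gene("a", 1000, 1999), make_gene("b", 5000, 5999)]
        cluster = clu.GeneCluster(cluster_id=1, chromosome="chr1",
                                  members=["a", "b"], span_kb=5.0,
                                  n_intervening=0)
        fs = fam.FamilySet(threshold=70, families=[{"a", "b"}],
                           singletons=set())
        calls = fam.classify_duplications(fs, [cluster], genes, {})
        assert calls == [fam.DuplicationCall("a", "b", "tandem")]

    def test_planted_segmental_block_recovered(self, sim_genome):
        cds = {g.gene_id: g.cds for g in sim_genome.nbs_genes}
        pairs = fam.all_vs_all(cds)
        fs = fam.build_families(pairs, set(cds), 70)
        found = clu.detect_clusters(sim_genome.nbs_genes,
                                    sim_genome.all_genes)
        calls = fam.classify_duplications(fs, found, sim_genome.all_genes,
                                          sim_genome.homology)
        seg = {frozenset((c.gene_a, c.gene_b)): c for c in calls
               if c.mode == "segmental"}
        truth_seg = {p for p, m in sim_genome.duplication_truth.items()
                     if m == "segmental"}
        assert set(seg) == truth_seg
        assert all(c.n_syntenic_pairs == 8 for c in seg.values())

    def test_distant_pair_without_homologs_unclassified(self):
        genes = [make_gene("a", 1000, 1999),
                 make_gene("b", 1000, 1999, chromosome="chr2")]
        fs = fam.FamilySet(threshold=70, families=[{"a", "b"}],
                           singletons=set())
        calls = fam.classify_duplications(fs, [], genes, {})
        assert calls[0].mode == "unclassified"

    def test_flank_must_be_positive(self):
        fs = fam.FamilySet(threshold=70, families=[], singletons=set())
        with pytest.raises(ValidationError):
            fam.classify_duplications(fs, [], [], {}, flank=0)

    def test_no_pair_both_tandem_and_segmental(self, sim_genome):
        cds = {g.gene_id: g.cds for g in sim_genome.nbs_genes}
        fs = fam.build_families(fam.all_vs_all(cds), set(cds), 70)
        found = clu.detect_clusters(sim_genome.nbs_genes,
                                    sim_genome.all_genes)
        calls = fam.classify_duplications(fs, found, sim_genome.all_genes,
                                          sim_genome.homology)
        assert len({(c.gene_a, c.gene_b) for c in calls}) == len(calls)
        chrom_of = {g.gene_id: g.chromosome for g in sim_genome.all_genes}
        for c in calls:
            if c.mode == "tandem":
                assert chrom_of[c.gene_a] == chrom_of[c.gene_b]


class TestThresholdSweep:
    def test_single_threshold_reduces_to_build(self):
        pairs = [edge("a", "b")]
        sweep = fam.threshold_sweep(pairs, {"a", "b", "c"}, thresholds=[70])
        direct = fam.build_families(pairs, {"a", "b", "c"}, 70)
        assert sweep.family_sets[70].families == direct.families

    def test_divergence_tiers_split_by_threshold(self, sim_genome):
        """Low-divergence family members stay together at 90%; the
        high-divergence tier survives only at 70%."""
        cds = {g.gene_id: g.cds for g in sim_genome.nbs_genes}
        sweep = fam.threshold_sweep(fam.all_vs_all(cds), set(cds))
        tiers = {}
        for g, t in sim_genome.family_truth.items():
            tiers.setdefault(t, set()).add(g)
        low, high = tiers[0], tiers[1]  # divergence 0.05 and 0.25
        assert any(low <= f for f in sweep.family_sets[90].families)
        assert any(high <= f for f in sweep.family_sets[70].families)
        assert not any(high <= f for f in sweep.family_sets[90].families)

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            fam.threshold_sweep([], set(), thresholds=[90, 70])

    def test_transition_table_shape(self, sim_genome):
        cds = {g.gene_id: g.cds for g in sim_genome.nbs_genes}
        sweep = fam.threshold_sweep(fam.all_vs_all(cds), set(cds))
        assert list(sweep.transitions.columns) == ["t70", "t80", "t90"]
        assert len(sweep.transitions) == len(cds)
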