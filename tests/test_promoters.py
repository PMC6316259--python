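import math

import numpy as np
import pytest

from nbskit import promoters as pro
from nbskit import simulate as sim
from nbskit.model import Genome, ValidationError, reverse_complement
from conftest import make_gene


def random_chrom(n, rng):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestExtractPromoters:
    def test_plus_strand_index_arithmetic(self, rng):
        chrom = random_chrom(3000, rng)
        genome = Genome(sequences={"chr1": chrom})
        gene = make_gene("g1", 2001, 2500)
        ps = pro.extract_promoters(genome, [gene])
        assert ps.sequences["g1"] == chrom[500:2000]  # bases 501..2000

    def test_minus_strand_reverse_complement(self, rng):
        chrom = random_chrom(3000, rng)
        genome = Genome(sequences={"chr1": chrom})
        gene = make_gene("g1", 500, 1000, strand="-")
        ps = pro.extract_promoters(genome, [gene])
        assert ps.sequences["g1"] == reverse_complement(chrom[1000:2500])

    def test_truncation_at_chromosome_start(self, rng):
        chrom = random_chrom(3000, rng)
        genome = Genome(sequences={"chr1": chrom})
        ps = pro.extract_promoters(genome, [make_gene("g1", 301, 600)])
        assert ps.sequences["g1"] == chrom[:300]

    def test_gene_at_position_one_empty_with_warning(self, rng, caplog):
        genome = Genome(sequences={"chr1": random_chrom(2000, rng)})
        with caplog.at_level("WARNING"):
            ps = pro.extract_promoters(genome, [make_gene("g1", 1, 300)])
        assert ps.sequences["g1"] == ""
        assert "empty promoter" in caplog.text

    def test_exclusion_list(self, rng):
        genome = Genome(sequences={"chr1": random_chrom(60000, rng)})
        genes = [make_gene(f"g{i}", 2000 + i * 1000, 2400 + i * 1000)
                 for i in range(48)]
        ps = pro.extract_promoters(genome, genes,
                                   exclude={"g0", "g1", "g2", "g3", "g4"})
        assert len(ps.sequences) == 43

    def test_promoter_never_overlaps_gene_body(self, sim_genome):
        ps = pro.extract_promoters(sim_genome.genome, sim_genome.nbs_genes)
        for g in sim_genome.nbs_genes:
            seq = ps.sequences[g.gene_id]
            chrom = sim_genome.genome.sequences[g.chromosome]
            if g.strand == "+":
                assert seq == chrom[g.start - 1 - len(seq):g.start - 1]
            else:
                assert seq == reverse_complement(
                    chrom[g.end:g.end + len(seq)])


class TestScanMotif:
    def test_overlapping_matches(self):
        assert pro.scan_motif("CAACAACA", pro.Motif("m", "CAACA")) == [1, 4]

    def test_degenerate_letter(self):
        m = pro.Motif("WBBOX", "TTTGACY")
        assert pro.scan_motif("TTTGACC", m) == [1]
        assert pro.scan_motif("TTTGACT", m) == [1]
        assert pro.scan_motif("TTTGACA", m) == []

    def test_motif_longer_than_sequence(self):
        assert pro.scan_motif("ACG", pro.Motif("m", "ACGTT")) == []

    def test_ambiguous_sequence_base_never_matches(self):
        assert pro.scan_motif("CANCA", pro.Motif("m", "CANCA")) == []

    def test_matches_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(17)
        iupac = list(pro.IUPAC_SETS)
        for _ in range(100):
            n = int(rng.integers(0, 300))
            seq = random_chrom(n, rng) if n else ""
            m = int(rng.integers(1, 9))
            motif = pro.Motif("m", "".join(rng.choice(iupac, m)))
            brute = [i + 1 for i in range(len(seq) - m + 1)
                     if all(seq[i + j] in pro.IUPAC_SETS[motif.iupac[j]]
                            for j in range(m))]
            assert pro.scan_motif(seq, motif) == brute


class TestExpectedCount:
    @pytest.mark.parametrize("iupac,rounded", [
        ("CACATG", 12), ("CATGTG", 12), ("TTTGACY", 11), ("CACCTG", 6),
        ("ACGTGTC", 2), ("TGGCCGAC", 0)])
    def test_closed_form_reference_values(self, iupac, rounded):
        e = pro.expected_count(pro.Motif("m", iupac), 43, 1500, 0.35)
        assert pro.round_half_up(e) == rounded

    def test_hand_computed_float(self):
        e = pro.expected_count(pro.Motif("m", "CACATG"), 43, 1500, 0.35)
        # C,A,C,A,T,G -> (gc/2)^3 * ((1-gc)/2)^3 per start position
        assert e == pytest.approx(43 * 1495 * 0.175 ** 3 * 0.325 ** 3,
                                  rel=1e-9)

    def test_single_n_certainty(self):
        assert pro.expected_count(pro.Motif("m", "N"), 10, 100, 0.4) == \
            pytest.approx(10 * 100)


class TestEnrichmentFactor:
    def test_infinite_when_rounded_expectation_zero(self):
        assert math.isinf(pro.enrichment(3, 0.19))

    def test_zero_when_both_zero(self):
        assert pro.enrichment(0, 0.3) == 0.0

    def test_divides_by_rounded_expectation(self):
        assert pro.enrichment(94, 65.8) == pytest.approx(94 / 66)


class TestMonteCarloNull:
    def test_mean_matches_closed_form(self):
        m = pro.Motif("m", "CACATG")
        null = pro.monte_carlo_null(m, observed=20, n_sets=500, seed=5)
        se = null.sd / math.sqrt(null.n_sets)
        analytic = pro.expected_count(m, 43, 1500, 0.35)
        assert abs(null.mean - analytic) < 3 * se

    def test_observed_zero_gives_p_one(self):
        null = pro.monte_carlo_null(pro.Motif("m", "CAACA"), observed=0,
                                    n_sets=50, seed=1)
        assert null.p_value == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        a = pro.monte_carlo_null(pro.Motif("m", "CAACA"), 80, n_sets=50,
                                 seed=9)
        b = pro.monte_carlo_null(pro.Motif("m", "CAACA"), 80, n_sets=50,
                                 seed=9)
        assert a.p_value == b.p_value and a.mean == b.mean

    def test_p_antimonotone_in_observed(self):
        null = pro.monte_carlo_null(pro.Motif("m", "CAACA"), 0, n_sets=200,
                                    seed=3)
        ps = [pro.empirical_p(null.counts, obs) for obs in range(0, 120, 10)]
        assert ps == sorted(ps, reverse=True)

    def test_seed_required(self):
        with pytest.raises(ValidationError):
            pro.monte_carlo_null(pro.Motif("m", "CAACA"), 1)


class TestPositionalProfile:
    def test_planted_position_hits_expected_bin(self):
        rec = sim.default_recipe(21)
        ps, truth = sim.simulate_promoters(rec)
        prof = pro.positional_profile(ps, pro.Motif("MYCATERD22", "CACATG"),
                                      n_sims=20, seed=2)
        peak_bin = prof.bin_starts[int(np.argmax(prof.counts))]
        assert peak_bin == -600  # planted at -550 -> bin [-600, -500)

    def test_counts_conserve_scan_total(self):
        rec = sim.default_recipe(22)
        ps, _ = sim.simulate_promoters(rec)
        m = pro.Motif("RAV1AAT", "CAACA")
        prof = pro.positional_profile(ps, m, n_sims=10, seed=2)
        assert sum(prof.counts) == pro.count_occurrences(ps, m)[0]

    def test_envelope_per_bin_coverage(self):
        """On no-signal input each bin lies inside its envelope at ~ the
        nominal 95% rate."""
        m = pro.Motif("m", "CAACA")
        inside = total = 0
        for rep in range(25):
            rng = np.random.default_rng(500 + rep)
            seqs = pro.decode_sequences(
                pro.random_sequences(43, 1500, 0.35, rng))
            ps = pro.PromoterSet({f"p{i}": s for i, s in enumerate(seqs)})
            prof = pro.positional_profile(ps, m, n_sims=150, seed=900 + rep)
            for c, (lo, hi) in zip(prof.counts, prof.mc_envelope):
                inside += lo <= c <= hi
                total += 1
        assert inside / total >= 0.93

    def test_bin_width_must_divide(self):
        ps = pro.PromoterSet({"a": "ACGT" * 10}, target_length=40)
        with pytest.raises(ValidationError):
            pro.positional_profile(ps, pro.Motif("m", "ACG"), n_sims=1,
                                   seed=0, bin_width=7)


class TestGCContent:
    def test_simple_values(self):
        assert pro.gc_content(pro.PromoterSet({"a": "GGCC"},
                                              target_length=10)).pooled == 1.0
        assert pro.gc_content(pro.PromoterSet({"a": "ATGC"},
                                              target_length=10)).pooled == 0.5

    def test_synthetic_set_concentrates(self):
        rng = np.random.default_rng(8)
        seqs = pro.decode_sequences(pro.random_sequences(43, 1500, 0.35, rng))
        ps = pro.PromoterSet({f"p{i}": s for i, s in enumerate(seqs)})
        assert pro.gc_content(ps).pooled == pytest.approx(0.35, abs=0.01)

    def test_all_ambiguous_sequence_excluded(self, caplog):
        ps = pro.PromoterSet({"a": "NNNN", "b": "ATGC"}, target_length=10)
        with caplog.at_level("WARNING"):
            s = pro.gc_content(ps)
        assert s.pooled == 0.5 and "a" not in s.per_sequence

    def test_empty_set_error(self):
        with pytest.raises(ValidationError):
            pro.gc_content(pro.PromoterSet({}, target_length=10))


def test_bundled_motifs_cover_published_list():
    motifs = {m.name: m.iupac for m in pro.load_bundled_motifs()}
    assert motifs["RAV1AAT"] == "CAACA"
    assert motifs["WBBOXPCWRKY1"] == "TTTGACY"
    # both spellings of the sucrose-responsive element ship, flagged
    assert {"SURE1STPAT21", "SURE2STPAT21"} <= set(motifs)
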