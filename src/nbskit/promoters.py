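"""Promoter extraction, IUPAC motif scanning and enrichment statistics.

The workflow mirrors a promoter cis-regulatory-element (CRE) survey:

1. extract ~1500 bp upstream of each gene start (strand-aware, truncated at
   chromosome edges, with an exclusion list for promoters that overlap other
   annotation);
2. count overlapping, forward-strand matches of degenerate IUPAC motifs;
3. compare observed totals to a closed-form expectation under an i.i.d.
   background parameterised only by G+C content;
4. attach empirical p-values from a Monte-Carlo null of simulated control
   sets of matched size, length and composition; and
5. profile match positions in 100-bp bins against a simulated envelope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .model import GeneModel, Genome, ValidationError, reverse_complement

logger = logging.getLogger(__name__)

IUPAC_SETS: Dict[str, str] = {k: v for k, v in ambiguous_dna_values.items()}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class Motif:
    """A named degenerate DNA motif in IUPAC code."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValidationError(f"{self.name}: empty motif")
        bad = set(self.iupac) - set(IUPAC_SETS)
        if bad:
            raise ValidationError(f"{self.name}: non-IUPAC letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.iupac)

    def match_probability(self, gc: float) -> float:
        """Per-position match probability under the i.i.d. G+C background."""
        if not 0 < gc < 1:
            raise ValidationError("gc must be in (0, 1)")
        probs = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
        p = 1.0
        for letter in self.iupac:
            p *= sum(probs[b] for b in IUPAC_SETS[letter])
        return p


def load_bundled_motifs() -> List[Motif]:
    """The ten CRE motifs surveyed in the study, plus one flagged spelling.

    SURE2STPAT21 (AATACAAAA) and SURE1STPAT21 (AATAGAAAA) are two printed
    spellings of the same sucrose-responsive element; both are shipped.
    """
    path = resources.files("nbskit.data") / "motifs.tsv"
    df = pd.read_csv(path, sep="\t")
    return [Motif(name=str(r.name_), iupac=str(r.iupac))
            for r in df.rename(columns={"name": "name_"}).itertuples(index=False)]


@dataclass
class PromoterSet:
    sequences: Dict[str, str]
    target_length: int = 1500

    def __post_init__(self) -> None:
        too_long = [g for g, s in self.sequences.items()
                    if len(s) > self.target_length]
        if too_long:
            raise ValidationError(
                f"promoters longer than target: {sorted(too_long)}")

    @property
    def gc_content(self) -> float:
        return gc_content(self).pooled


def extract_promoters(genome: Genome, genes: Sequence[GeneModel],
                      upstream: int = 1500,
                      exclude: Iterable[str] = ()) -> PromoterSet:
    """Strand-aware upstream sequences, anchored at the annotated gene start.

    '+' genes take the ``upstream`` bases immediately 5' of ``start``;
    '-' genes the reverse complement of the bases immediately 3' of ``end``.
    Truncated at chromosome edges (a '+' gene starting at position 1 yields
    an empty promoter with a warning). Genes in ``exclude`` are omitted.
    """
    exclude = set(exclude)
    sequences: Dict[str, str] = {}
    for g in genes:
        if g.gene_id in exclude:
            continue
        if g.chromosome not in genome:
            raise ValidationError(
                f"{g.gene_id}: chromosome {g.chromosome!r} absent from genome")
        chrom = genome.sequences[g.chromosome]
        if g.strand == "+":
            lo = max(0, g.start - 1 - upstream)
            seq = chrom[lo:g.start - 1]
        else:
            seq = reverse_complement(chrom[g.end:g.end + upstream])
        if not seq:
            logger.warning("%s: empty promoter (gene at chromosome edge)",
                           g.gene_id)
        sequences[g.gene_id] = seq
    return PromoterSet(sequences=sequences, target_length=upstream)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        lut[ord(base)] = idx
    return lut[arr]


def _motif_luts(motif: Motif) -> List[np.ndarray]:
    luts = []
    for letter in motif.iupac:
        ok = np.zeros(5, dtype=bool)
        for b in IUPAC_SETS[letter]:
            ok[_BASE_INDEX[b]] = True
        luts.append(ok)
    return luts


def scan_motif(seq: str, motif: Motif) -> List[int]:
    """1-based start positions of all (overlapping) forward-strand matches.

    A position matches when every sequence base lies in the IUPAC class of
    the corresponding motif letter; ambiguous sequence bases never match.
    """
    m = len(motif)
    n = len(seq)
    if m > n:
        return []
    enc = _encode(seq.upper())
    ok = np.ones(n - m + 1, dtype=bool)
    for j, lut in enumerate(_motif_luts(motif)):
        ok &= lut[enc[j:j + n - m + 1]]
    return [int(i) + 1 for i in np.nonzero(ok)[0]]


def count_occurrences(promoters: PromoterSet, motif: Motif) -> Tuple[int, int]:
    """(total occurrences, number of promoters with at least one hit)."""
    total = with_hit = 0
    for seq in promoters.sequences.values():
        hits = scan_motif(seq, motif)
        total += len(hits)
        with_hit += bool(hits)
    return total, with_hit


def expected_count(motif: Motif, n_seqs: int, seq_len: int,
                   gc: float) -> float:
    """Closed-form expected total occurrences under the i.i.d. background."""
    positions = max(0, seq_len - len(motif) + 1)
    return n_seqs * positions * motif.match_probability(gc)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def enrichment(observed: int, expected: float) -> float:
    """Observed over rounded expected; infinity when the rounded expectation
    is zero but occurrences were observed; zero when both are zero."""
    exp_r = round_half_up(expected)
    if exp_r >= 1:
        return observed / exp_r
    return math.inf if observed > 0 else 0.0


def random_sequences(n_seqs: int, seq_len: int, gc: float,
                     rng: np.random.Generator) -> np.ndarray:
    """(n_seqs, seq_len) uint8 array of encoded i.i.d. bases (ACGT=0..3)."""
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    cum = np.cumsum(probs)
    u = rng.random((n_seqs, seq_len))
    return np.searchsorted(cum, u).astype(np.uint8)


def decode_sequences(arr: np.ndarray) -> List[str]:
    bases = np.array(list("ACGT"), dtype="U1")
    return ["".join(bases[row]) for row in arr]


def _count_batch(arr: np.ndarray, motif: Motif) -> np.ndarray:
    """Occurrences per row for an encoded (n, L) sequence array."""
    n, L = arr.shape
    m = len(motif)
    if m > L:
        return np.zeros(n, dtype=np.int64)
    ok = np.ones((n, L - m + 1), dtype=bool)
    for j, lut in enumerate(_motif_luts(motif)):
        ok &= lut[arr[:, j:j + L - m + 1]]
    return ok.sum(axis=1)


def null_set_totals(motifs: Sequence[Motif], n_sets: int, set_n: int,
                    seq_len: int, gc: float, rng: np.random.Generator,
                    chunk: int = 100) -> np.ndarray:
    """Per-control-set total occurrences, shape (len(motifs), n_sets).

    One shared stream of simulated control sets scores all motifs, which is
    statistically identical to simulating per motif.
    """
    totals = np.zeros((len(motifs), n_sets), dtype=np.int64)
    done = 0
    while done < n_sets:
        k = min(chunk, n_sets - done)
        arr = random_sequences(k * set_n, seq_len, gc, rng)
        for mi, motif in enumerate(motifs):
            per_seq = _count_batch(arr, motif)
            totals[mi, done:done + k] = per_seq.reshape(k, set_n).sum(axis=1)
        done += k
    return totals


@dataclass(frozen=True)
class MonteCarloNull:
    mean: float
    sd: float
    p_value: float
    n_sets: int
    counts: np.ndarray = field(repr=False, compare=False, default=None)


def empirical_p(null_counts: np.ndarray, observed: int) -> float:
    """Add-one empirical upper-tail p-value (Davison-Hinkley estimator)."""
    n_sets = len(null_counts)
    return (1 + int((null_counts >= observed).sum())) / (n_sets + 1)


def monte_carlo_null(motif: Motif, observed: int, n_sets: int = 2000,
                     set_n: int = 43, seq_len: int = 1500, gc: float = 0.35,
                     seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None) -> MonteCarloNull:
    """Empirical null for one motif's total occurrence count.

    Each control set is ``set_n`` i.i.d. sequences of ``seq_len`` at the
    stated G+C; the p-value is (1 + #{sets >= observed}) / (n_sets + 1).
    """
    if n_sets < 1:
        raise ValidationError("n_sets must be >= 1")
    if rng is None:
        if seed is None:
            raise ValidationError("supply a seed or an rng")
        rng = np.random.default_rng(seed)
    counts = null_set_totals([motif], n_sets, set_n, seq_len, gc, rng)[0]
    return MonteCarloNull(mean=float(counts.mean()),
                          sd=float(counts.std(ddof=1)) if n_sets > 1 else 0.0,
                          p_value=empirical_p(counts, observed),
                          n_sets=n_sets, counts=counts)


@dataclass(frozen=True)
class EnrichmentResult:
    motif: Motif
    n_promoters_with_hit: int
    n_occurrences: int
    expected_occurrences: float
    enrichment_factor: float
    p_value: float
    mean_per_hit_promoter: float


def enrichment_analysis(promoters: PromoterSet, motifs: Sequence[Motif],
                        gc: Optional[float] = None, n_sets: int = 2000,
                        seed: int = 0) -> List[EnrichmentResult]:
    """Full observed/expected/Monte-Carlo table for a promoter set."""
    if gc is None:
        gc = gc_content(promoters).pooled
    set_n = len(promoters.sequences)
    seq_len = promoters.target_length
    rng = np.random.default_rng(seed)
    null = null_set_totals(motifs, n_sets, set_n, seq_len, gc, rng)
    results = []
    for mi, motif in enumerate(motifs):
        observed, with_hit = count_occurrences(promoters, motif)
        expected = expected_count(motif, set_n, seq_len, gc)
        results.append(EnrichmentResult(
            motif=motif, n_promoters_with_hit=with_hit,
            n_occurrences=observed, expected_occurrences=expected,
            enrichment_factor=enrichment(observed, expected),
            p_value=empirical_p(null[mi], observed),
            mean_per_hit_promoter=observed / with_hit if with_hit else 0.0))
    return results


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [{"cre": r.motif.name, "motif": r.motif.iupac,
             "promoters_observed": r.n_promoters_with_hit,
             "occurrences_observed": r.n_occurrences,
             "avg_per_promoter": round(r.mean_per_hit_promoter, 1),
             "occurrences_expected": round_half_up(r.expected_occurrences),
             "enrichment_factor": (math.inf if math.isinf(r.enrichment_factor)
                                   else round(r.enrichment_factor, 1)),
             "p_value": r.p_value}
            for r in results]
    return pd.DataFrame(rows)


@dataclass
class PositionalProfile:
    bin_width: int
    counts: List[int]
    mc_envelope: List[Tuple[float, float]]
    bin_starts: List[int]  # upstream coordinate of each bin start (e.g. -1500)


def positional_profile(promoters: PromoterSet, motif: Motif,
                       n_sims: int = 1000, seed: int = 0,
                       bin_width: int = 100) -> PositionalProfile:
    """Match-position histogram in upstream coordinates with a MC envelope.

    Promoters are anchored at the gene start: the last base of each promoter
    is position -1 and positions run back to -target_length. The envelope is
    the per-bin 2.5/97.5 percentile band over ``n_sims`` simulated sets of
    matched size, length and G+C.
    """
    L = promoters.target_length
    if L % bin_width:
        raise ValidationError("bin width must divide the target length")
    n_bins = L // bin_width
    counts = np.zeros(n_bins, dtype=np.int64)
    for seq in promoters.sequences.values():
        for start in scan_motif(seq, motif):
            coord = -(len(seq) - start + 1)  # upstream coordinate of match start
            counts[(coord + L) // bin_width] += 1

    gc = gc_content(promoters).pooled if promoters.sequences else 0.5
    set_n = len(promoters.sequences)
    rng = np.random.default_rng(seed)
    sims = np.zeros((n_sims, n_bins), dtype=np.int64)
    m = len(motif)
    for s in range(n_sims):
        arr = random_sequences(set_n, L, gc, rng)
        ok = np.ones((set_n, L - m + 1), dtype=bool)
        for j, lut in enumerate(_motif_luts(motif)):
            ok &= lut[arr[:, j:j + L - m + 1]]
        starts = np.nonzero(ok)[1]  # 0-based; coord = -(L - start)
        sims[s] = np.bincount(starts // bin_width, minlength=n_bins)
    low = np.percentile(sims, 2.5, axis=0)
    high = np.percentile(sims, 97.5, axis=0)
    return PositionalProfile(bin_width=bin_width, counts=counts.tolist(),
                             mc_envelope=list(zip(low.tolist(), high.tolist())),
                             bin_starts=[-L + k * bin_width for k in range(n_bins)])


@dataclass(frozen=True)
class GCSummary:
    pooled: float
    per_sequence: Dict[str, float]

    @property
    def range(self) -> Tuple[float, float]:
        vals = list(self.per_sequence.values())
        return (min(vals), max(vals)) if vals else (math.nan, math.nan)


def gc_content(promoters: PromoterSet) -> GCSummary:
    """Pooled and per-sequence G+C fraction over unambiguous bases.

    Sequences with no A/C/G/T content are excluded from the denominator with
    a warning.
    """
    if not promoters.sequences:
        raise ValidationError("empty promoter set")
    total_gc = total_acgt = 0
    per_seq: Dict[str, float] = {}
    for gene, seq in promoters.sequences.items():
        s = seq.upper()
        gc_n = s.count("G") + s.count("C")
        acgt = gc_n + s.count("A") + s.count("T")
        if acgt == 0:
            logger.warning("%s: no unambiguous bases; excluded from GC", gene)
            continue
        per_seq[gene] = gc_n / acgt
        total_gc += gc_n
        total_acgt += acgt
    pooled = total_gc / total_acgt if total_acgt else math.nan
    return GCSummary(pooled=pooled, per_sequence=per_seq)
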