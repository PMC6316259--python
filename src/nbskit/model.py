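"""Shared genomic data model.

Coordinates are 1-based and inclusive throughout the package, matching the
GFF3 convention; promoter extraction and cluster-gap arithmetic are written
against this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

DOMAIN_VOCAB = frozenset({"TIR", "CC", "NBS", "LRR", "RPW8"})
SOURCE_VOCAB = frozenset({"COILS", "CDD", "PFAM", "SMART", "OTHER"})

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; IUPAC ambiguity codes handled."""
    return seq.translate(_COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when an input violates a closed vocabulary or an invariant."""


@dataclass(frozen=True)
class GeneModel:
    """A located gene: one locus with its representative model.

    ``n_variants`` counts annotated mRNA isoforms at the locus (alternative
    transcripts), not separate loci.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    cds: str = ""
    protein: str = ""
    n_variants: int = 1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.n_variants < 1:
            raise ValidationError(f"{self.gene_id}: n_variants must be >= 1")
        if self.protein and self.cds and len(self.cds) % 3 != 0:
            raise ValidationError(
                f"{self.gene_id}: CDS length {len(self.cds)} not divisible by 3")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Genome:
    """Chromosome sequences keyed by name; lengths derived from sequences."""

    sequences: Dict[str, str]

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chromosome: str) -> bool:
        return chromosome in self.sequences


@dataclass(frozen=True)
class DomainCall:
    """One domain annotation on a protein (amino-acid coordinates)."""

    gene_id: str
    domain: str
    start: int
    end: int
    source: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.domain not in DOMAIN_VOCAB:
            raise ValidationError(f"unknown domain token {self.domain!r}")
        if self.source not in SOURCE_VOCAB:
            raise ValidationError(f"unknown source token {self.source!r}")
        if self.start > self.end:
            raise ValidationError(
                f"{self.gene_id}: domain start {self.start} > end {self.end}")


@dataclass(frozen=True)
class HitRecord:
    """One read-to-gene mapping hit from a tabular mapper output."""

    read_id: str
    gene_id: str
    aln_length: int
    pct_identity: float
    library_id: str

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValidationError(f"{self.read_id}: aln_length must be >= 1")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValidationError(
                f"{self.read_id}: pct_identity {self.pct_identity} out of range")


@dataclass
class CladeMap:
    """Phylogenetic clade labels per gene (e.g. Ia, Ib, II, III)."""

    assignments: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, clade in self.assignments.items():
            if not clade:
                raise ValidationError(f"{gene}: empty clade label")

    def get(self, gene_id: str) -> Optional[str]:
        return self.assignments.get(gene_id)


def group_by_chromosome(genes) -> Dict[str, list]:
    """Genes grouped per chromosome, each group sorted by start position."""
    out: Dict[str, list] = {}
    for g in genes:
        out.setdefault(g.chromosome, []).append(g)
    for members in out.values():
        members.sort(key=lambda g: (g.start, g.end, g.gene_id))
    return out
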