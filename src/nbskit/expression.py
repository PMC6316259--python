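"""Digital expression from read-mapping hit tables.

Hits are filtered (alignment length > 100 bp, identity > 90%, one hit per
read), counted per gene per library, normalised to counts-per-million, and
genes are called tissue-enriched when the normalised count ratio between two
libraries exceeds a threshold (default 8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import HitRecord, ValidationError


def filter_hits(hits: Sequence[HitRecord], min_len: int = 100,
                min_identity: float = 90.0) -> List[HitRecord]:
    """Apply the mapping filters and the one-hit-per-read rule.

    Keeps hits with ``aln_length > min_len`` and ``pct_identity >
    min_identity`` (both strict), then deduplicates to one hit per read per
    library: best identity, ties broken by longest alignment, then
    lexicographically smallest gene id, so the result is a deterministic
    function of the input multiset.
    """
    kept = [h for h in hits
            if h.aln_length > min_len and h.pct_identity > min_identity]
    if not kept:
        return []
    best: Dict[tuple, HitRecord] = {}
    for h in kept:
        key = (h.library_id, h.read_id)
        cur = best.get(key)
        if cur is None or (-h.pct_identity, -h.aln_length, h.gene_id) < \
                (-cur.pct_identity, -cur.aln_length, cur.gene_id):
            best[key] = h
    return [best[k] for k in sorted(best)]


@dataclass
class ExpressionMatrix:
    raw: pd.DataFrame         # genes x libraries, integer counts
    normalized: pd.DataFrame  # genes x libraries, counts-per-million
    library_sizes: Dict[str, int]


def count_and_normalize(hits: Sequence[HitRecord],
                        library_sizes: Mapping[str, int]) -> ExpressionMatrix:
    """Per-gene per-library counts and counts-per-million normalisation."""
    libs = sorted(library_sizes)
    for lib, size in library_sizes.items():
        if size <= 0:
            raise ValidationError(f"library {lib!r} has non-positive size")
    unknown = {h.library_id for h in hits} - set(libs)
    if unknown:
        raise ValidationError(f"hits from unsized libraries: {sorted(unknown)}")
    genes = sorted({h.gene_id for h in hits})
    raw = pd.DataFrame(0, index=genes, columns=libs, dtype=np.int64)
    for h in hits:
        raw.loc[h.gene_id, h.library_id] += 1
    norm = raw.astype(float)
    for lib in libs:
        norm[lib] = raw[lib] * 1e6 / library_sizes[lib]
    raw.index.name = norm.index.name = "gene_id"
    return ExpressionMatrix(raw=raw, normalized=norm,
                            library_sizes=dict(library_sizes))


@dataclass(frozen=True)
class EnrichmentCall:
    gene_id: str
    log2_ratio: float
    mean_expression: float
    label: str  # library id of the enriched side, or "none"
    ratio_threshold: float = 8.0


def call_enrichment(mat: ExpressionMatrix, lib_a: str, lib_b: str,
                    ratio_threshold: float = 8.0) -> List[EnrichmentCall]:
    """Call genes enriched in one of two libraries by normalised count ratio.

    A pseudo-count equal to the smallest positive normalised value across the
    two libraries keeps ratios finite while preserving ranks. The returned
    log2 ratio and mean are the MA-plot coordinates.
    """
    for lib in (lib_a, lib_b):
        if lib not in mat.normalized.columns:
            raise ValidationError(f"library {lib!r} absent from the matrix")
    a = mat.normalized[lib_a]
    b = mat.normalized[lib_b]
    positive = pd.concat([a[a > 0], b[b > 0]])
    pc = float(positive.min()) if len(positive) else 1.0
    calls = []
    for gene in mat.normalized.index:
        ratio = (a[gene] + pc) / (b[gene] + pc)
        if ratio > ratio_threshold:
            label = lib_a
        elif 1.0 / ratio > ratio_threshold:
            label = lib_b
        else:
            label = "none"
        calls.append(EnrichmentCall(gene_id=gene,
                                    log2_ratio=math.log2(ratio),
                                    mean_expression=(a[gene] + b[gene]) / 2,
                                    label=label,
                                    ratio_threshold=ratio_threshold))
    return calls


def ma_table(calls: Sequence[EnrichmentCall]) -> pd.DataFrame:
    return pd.DataFrame([{"gene_id": c.gene_id, "mean": c.mean_expression,
                          "log2_ratio": c.log2_ratio, "label": c.label}
                         for c in calls])
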