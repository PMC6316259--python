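"""Domain-architecture classification of NBS proteins.

NBS-LRR proteins are labelled by the domains flanking the central
nucleotide-binding site: an N-terminal TIR, coiled-coil (CC) or RPW8 domain
and a C-terminal leucine-rich repeat (LRR) region. Eight architecture classes
are distinguished::

    TNL  TIR-NBS-LRR          N   NBS only
    CNL  CC-NBS-LRR           CN  CC-NBS
    RNL  RPW8-NBS-LRR         XN  CC(database-only)-NBS
    NL   NBS-LRR (no CC)      XNL CC(database-only)-NBS-LRR

"Database-only" CC evidence (the X classes) means a CC call from a conserved
domain database (CDD/Pfam/SMART) without support from the heptad-based
coiled-coil scorer; scorer positivity takes precedence.

Two CC detectors are provided: a Lupas-style sliding-window heptad scorer
with a bundled propensity table (:func:`coiled_coil_score`) and an exact scan
for a degenerate amino-acid consensus pattern (:func:`scan_cc_consensus`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import DomainCall, GeneModel, ValidationError

logger = logging.getLogger(__name__)

ARCHITECTURE_CLASSES: Tuple[str, ...] = (
    "TNL", "CNL", "NL", "RNL", "XNL", "N", "CN", "XN")

#: N-terminal length (aa, start of protein to start of NBS) regarded as
#: comparable to an intact CC-bearing N-terminus. Reported alongside
#: classifications; predicted CC evidence typically spans ~35-95 aa, so an
#: intact N-terminus comfortably exceeds this.
MIN_INTACT_NTERM_AA = 120

#: Degenerate CC consensus discovered in asparagus NBS proteins (positions
#: ~30-65); bracket syntax, hyphen-separated.
CC_CONSENSUS = ("M-[KN]-D-D-L-[QEK]-R-R-[KNQ]-[DR]-A-L-P-R-I-[QK]-[AH]-V-"
                "[VL]-[ENH]-[AMD]-A-E-[SR]-[GK]-[QR]-[QGI]-[EQ]-[IS]-[TE]")

COIL_WINDOWS = (14, 21, 28)
#: score -> probability mapping: per-window (mean, sd) of the window score
#: under the coiled-coil and globular reference populations.
_GAUSS = {14: (1.55, 0.26, 0.80, 0.22),
          21: (1.60, 0.24, 0.77, 0.20),
          28: (1.63, 0.22, 0.75, 0.18)}


class ArchitectureError(ValueError):
    """Domain combination outside the eight-class vocabulary."""


@dataclass(frozen=True)
class CCEvidence:
    gene_id: str
    coils_positive: bool
    cdd_positive: bool
    coils_interval: Optional[Tuple[int, int]] = None
    consensus_match_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.coils_interval is not None and not self.coils_positive:
            raise ValidationError("coils_interval requires coils_positive")


@dataclass
class CoiledCoilProfile:
    """Per-residue coiled-coil probabilities for one protein."""

    per_residue_score: np.ndarray
    window: int
    threshold: float = 0.9

    def segments(self) -> List[Tuple[int, int]]:
        """Maximal runs of residues at or above threshold (1-based, incl.)."""
        above = self.per_residue_score >= self.threshold
        segs, start = [], None
        for i, flag in enumerate(above):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                segs.append((start + 1, i))
                start = None
        if start is not None:
            segs.append((start + 1, len(above)))
        return segs

    @property
    def max_score(self) -> float:
        return float(self.per_residue_score.max())


def _load_propensities() -> Dict[str, np.ndarray]:
    path = resources.files("nbskit.data") / "coil_propensities.tsv"
    df = pd.read_csv(path, sep="\t").set_index("aa")
    return {aa: row.to_numpy(dtype=float) for aa, row in df.iterrows()}


_PROPENSITIES = _load_propensities()


def coiled_coil_score(protein: str, window: int = 21,
                      threshold: float = 0.9) -> CoiledCoilProfile:
    """Heptad-propensity coiled-coil scorer.

    Each window of ``window`` residues is scored as the geometric mean of
    per-position propensities under a heptad register (abcdefg), maximised
    over the 7 register phases; the window score is mapped to a [0,1]
    probability through the two-Gaussian (coiled-coil vs globular)
    likelihood ratio. A residue's score is the maximum probability over all
    windows covering it. Non-standard letters score a neutral propensity of
    1.0 and are logged.
    """
    if window not in COIL_WINDOWS:
        raise ValueError(f"window must be one of {COIL_WINDOWS}")
    n = len(protein)
    if n < window:
        raise ValueError(f"protein length {n} shorter than window {window}")

    logp = np.zeros((n, 7))
    for i, aa in enumerate(protein):
        prop = _PROPENSITIES.get(aa)
        if prop is None:
            logger.warning("non-standard residue %r scored neutrally", aa)
            continue
        logp[i] = np.log(prop)

    n_win = n - window + 1
    best = np.full(n_win, -np.inf)
    idx = np.arange(n)
    for phase in range(7):
        per_res = logp[idx, (idx + phase) % 7]
        csum = np.concatenate([[0.0], np.cumsum(per_res)])
        win_mean = (csum[window:] - csum[:-window]) / window
        np.maximum(best, win_mean, out=best)
    win_score = np.exp(best)

    mcc, scc, mgl, sgl = _GAUSS[window]
    ncc = np.exp(-0.5 * ((win_score - mcc) / scc) ** 2) / scc
    ngl = np.exp(-0.5 * ((win_score - mgl) / sgl) ** 2) / sgl
    win_prob = ncc / (ncc + ngl)

    # per-residue score: max over the windows covering the residue
    per_res_score = np.empty(n)
    for i in range(n):
        lo = max(0, i - window + 1)
        hi = min(i, n_win - 1)
        per_res_score[i] = win_prob[lo:hi + 1].max()
    return CoiledCoilProfile(per_residue_score=per_res_score, window=window,
                             threshold=threshold)


def parse_cc_pattern(text: str) -> List[FrozenSet[str]]:
    """Parse a bracket-syntax degenerate pattern into residue sets.

    Hyphens separate positions; hyphens inside brackets are ignored, which
    also normalises the typographic variant ``[GK][-QR]`` to ``[GK]-[QR]``.
    """
    sets: List[FrozenSet[str]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch in "- \t":
            i += 1
        elif ch == "[":
            j = text.index("]", i)
            residues = frozenset(c for c in text[i + 1:j] if c.isalpha())
            if not residues:
                raise ValidationError(f"empty alternative set at offset {i}")
            sets.append(residues)
            i = j + 1
        else:
            sets.append(frozenset(ch.upper()))
            i += 1
    if not sets:
        raise ValidationError("empty pattern")
    return sets


def scan_cc_consensus(protein: str,
                      pattern: Sequence[FrozenSet[str]]) -> List[int]:
    """All 1-based start positions matching the degenerate pattern.

    Overlapping matches are allowed; every pattern position's residue set
    must contain the corresponding protein residue.
    """
    for pos_set in pattern:
        if not pos_set:
            raise ValidationError("empty alternative set in pattern")
    m = len(pattern)
    out = []
    for start in range(len(protein) - m + 1):
        if all(protein[start + j] in pattern[j] for j in range(m)):
            out.append(start + 1)
    return out


def _evidence(domains: Iterable[DomainCall]):
    has = {"TIR": False, "NBS": False, "LRR": False, "RPW8": False}
    cc_coils = cc_db = False
    for d in domains:
        if d.domain == "CC":
            if d.source == "COILS":
                cc_coils = True
            else:
                cc_db = True
        else:
            has[d.domain] = True
    return has, cc_coils, cc_db


def classify_architecture(domains: Sequence[DomainCall],
                          protein_length: Optional[int] = None) -> str:
    """Assign one of the eight architecture classes from domain calls.

    Decision rule: TIR+NBS+LRR -> TNL; RPW8+NBS+LRR -> RNL;
    CC(scorer)+NBS+LRR -> CNL; CC(database only)+NBS+LRR -> XNL;
    NBS+LRR without CC -> NL; NBS only -> N; CC(scorer)+NBS -> CN;
    CC(database only)+NBS -> XN. Scorer (COILS-source) CC evidence takes
    precedence over database evidence. A gene with no NBS call, with both
    TIR and RPW8, or with TIR/RPW8 but no LRR (no class exists for those) is
    an error.
    """
    domains = list(domains)
    if not domains:
        raise ArchitectureError("no domain calls supplied")
    gene_ids = {d.gene_id for d in domains}
    if len(gene_ids) > 1:
        raise ValidationError(f"calls span several genes: {sorted(gene_ids)}")
    has, cc_coils, cc_db = _evidence(domains)
    if not has["NBS"]:
        raise ArchitectureError(f"{gene_ids.pop()}: no NBS domain; not an NBS gene")
    if has["TIR"] and has["RPW8"]:
        raise ArchitectureError("contradictory architecture: both TIR and RPW8")
    if has["TIR"]:
        if not has["LRR"]:
            raise ArchitectureError("TIR-NBS without LRR has no class")
        return "TNL"
    if has["RPW8"]:
        if not has["LRR"]:
            raise ArchitectureError("RPW8-NBS without LRR has no class")
        return "RNL"
    if has["LRR"]:
        if cc_coils:
            return "CNL"
        if cc_db:
            return "XNL"
        return "NL"
    if cc_coils:
        return "CN"
    if cc_db:
        return "XN"
    return "N"


def has_intact_nterm(nbs_start_aa: int,
                     min_len: int = MIN_INTACT_NTERM_AA) -> bool:
    """Whether the pre-NBS region is long enough to host an N-terminal domain."""
    return nbs_start_aa - 1 >= min_len


def summarize_classes(labels: Iterable[str]) -> Dict[str, int]:
    """Count table over the eight classes plus a ``total`` row."""
    counts = {cls: 0 for cls in ARCHITECTURE_CLASSES}
    total = 0
    for label in labels:
        if label not in counts:
            raise ValidationError(f"unknown architecture label {label!r}")
        counts[label] += 1
        total += 1
    counts["total"] = total
    return counts


@dataclass(frozen=True)
class VariantSummary:
    n_models: int
    n_loci: int
    n_multi_variant_loci: int
    fraction_multi: float


def variant_summary(genes: Sequence[GeneModel]) -> VariantSummary:
    """Alternative-transcript tally: models vs loci and the multi-variant share."""
    n_loci = len(genes)
    n_models = sum(g.n_variants for g in genes)
    n_multi = sum(1 for g in genes if g.n_variants > 1)
    frac = n_multi / n_loci if n_loci else 0.0
    return VariantSummary(n_models=n_models, n_loci=n_loci,
                          n_multi_variant_loci=n_multi, fraction_multi=frac)
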