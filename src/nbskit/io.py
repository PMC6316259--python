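"""Readers and writers for the external formats.

Formats: FASTA (genome, CDS, protein), GFF3 (annotation; the only annotation
dialect supported), tab-delimited tables with header rows (domain calls, clade
maps, read-mapping hits, pairwise similarity hits), and newick trees for clade
assignment. Sequences are upper-cased on read; IUPAC ambiguity codes are
preserved.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .model import (CladeMap, DomainCall, GeneModel, Genome, HitRecord,
                    ValidationError, reverse_complement)

logger = logging.getLogger(__name__)


class AnnotationParseError(ValueError):
    """Malformed GFF3 content; message carries the offending line number."""


class ReferenceError_(KeyError):
    """A record references an entity (e.g. chromosome) that is absent."""


def read_fasta(path) -> Dict[str, str]:
    """FASTA file -> mapping of record id to upper-cased sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def _validate_gff3_lines(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise AnnotationParseError(
                    f"{path}: malformed GFF3 line {lineno}: "
                    f"expected 9 tab-separated fields")


def read_annotation(gff3_path, fasta_path) -> Tuple[List[GeneModel], Genome]:
    """Parse a GFF3 annotation plus genome FASTA into gene models.

    One :class:`GeneModel` per ``gene`` feature; ``n_variants`` is the number
    of mRNA children. The CDS is stitched from the first mRNA's CDS features
    (or, for single-exon annotations without explicit CDS rows, the gene span)
    and reverse-complemented for '-' strand genes. Transcripts without a
    parent gene are ignored with a logged warning.
    """
    _validate_gff3_lines(gff3_path)
    genome = Genome(sequences=read_fasta(fasta_path))
    db = gffutils.create_db(str(gff3_path), dbfn=":memory:",
                            merge_strategy="create_unique", keep_order=True)

    for mrna in db.features_of_type("mRNA"):
        if "Parent" not in mrna.attributes:
            logger.warning("mRNA %s has no parent gene; ignored", mrna.id)

    genes: List[GeneModel] = []
    for feat in db.features_of_type("gene"):
        if feat.seqid not in genome:
            raise ReferenceError_(
                f"gene {feat.id} references absent chromosome {feat.seqid!r}")
        mrnas = list(db.children(feat, featuretype="mRNA"))
        n_variants = max(1, len(mrnas))
        cds_feats = sorted(
            db.children(mrnas[0] if mrnas else feat, featuretype="CDS"),
            key=lambda f: f.start)
        chrom_seq = genome.sequences[feat.seqid]
        if cds_feats:
            cds = "".join(chrom_seq[f.start - 1:f.end] for f in cds_feats)
        else:
            cds = chrom_seq[feat.start - 1:feat.end]
        if feat.strand == "-":
            cds = reverse_complement(cds)
        protein = ""
        if cds and len(cds) % 3 == 0 and set(cds) <= set("ACGT"):
            protein = str(Seq(cds).translate()).rstrip("*")
        genes.append(GeneModel(gene_id=feat.id, chromosome=feat.seqid,
                               start=feat.start, end=feat.end,
                               strand=feat.strand, cds=cds, protein=protein,
                               n_variants=n_variants))
    genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return genes, genome


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene + n_variants mRNA children + CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write("\t".join([g.chromosome, "nbskit", "gene", str(g.start),
                                str(g.end), ".", g.strand, ".", attrs]) + "\n")
            for i in range(1, g.n_variants + 1):
                mid = f"{g.gene_id}.t{i}"
                fh.write("\t".join([g.chromosome, "nbskit", "mRNA",
                                    str(g.start), str(g.end), ".", g.strand,
                                    ".", f"ID={mid};Parent={g.gene_id}"]) + "\n")
                fh.write("\t".join([g.chromosome, "nbskit", "CDS",
                                    str(g.start), str(g.end), ".", g.strand,
                                    "0", f"ID={mid}.cds;Parent={mid}"]) + "\n")


def read_domain_table(path) -> List[DomainCall]:
    """TSV with header (gene_id, domain, start, end, source, score)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "domain", "start", "end", "source"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"domain table missing columns: {sorted(missing)}")
    calls = []
    for row in df.itertuples(index=False):
        calls.append(DomainCall(gene_id=str(row.gene_id), domain=str(row.domain),
                                start=int(row.start), end=int(row.end),
                                source=str(row.source),
                                score=float(getattr(row, "score", 0.0))))
    return calls


def write_domain_table(calls: Iterable[DomainCall], path) -> None:
    pd.DataFrame([c.__dict__ for c in calls]).to_csv(path, sep="\t", index=False)


def read_hits_table(path) -> List[HitRecord]:
    """TSV with header (read_id, gene_id, aln_length, pct_identity, library_id)."""
    df = pd.read_csv(path, sep="\t")
    return [HitRecord(read_id=str(r.read_id), gene_id=str(r.gene_id),
                      aln_length=int(r.aln_length),
                      pct_identity=float(r.pct_identity),
                      library_id=str(r.library_id))
            for r in df.itertuples(index=False)]


def write_hits_table(hits: Iterable[HitRecord], path) -> None:
    pd.DataFrame([h.__dict__ for h in hits]).to_csv(path, sep="\t", index=False)


def read_clade_map(path, node_labels: Optional[Mapping[str, str]] = None) -> CladeMap:
    """Clade assignment from a 2-column TSV or a newick tree.

    For newick input every leaf receives the label of its nearest labelled
    ancestor; ``node_labels`` optionally maps internal-node names to clade
    labels (otherwise the node names themselves are the labels). Leaves with
    no labelled ancestor are left unassigned. Duplicate leaf names are an
    error.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("("):
        return _clades_from_newick(text, node_labels)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValidationError("clade TSV needs two columns (gene_id, clade)")
    gene_col, clade_col = df.columns[:2]
    assignments = {str(r[0]): str(r[1])
                   for r in df[[gene_col, clade_col]].itertuples(index=False)}
    return CladeMap(assignments=assignments)


def _clades_from_newick(text: str,
                        node_labels: Optional[Mapping[str, str]]) -> CladeMap:
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError(f"duplicate leaf names in tree: {exc}") from exc
    leaf_names = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(leaf_names) != len(set(leaf_names)):
        dupes = sorted({n for n in leaf_names if leaf_names.count(n) > 1})
        raise ValidationError(f"duplicate leaf names in tree: {dupes}")
    assignments: Dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:
            continue
        node = leaf.parent_node
        while node is not None:
            label = node.label
            if label is not None:
                if node_labels is not None:
                    if label in node_labels:
                        assignments[leaf.taxon.label] = node_labels[label]
                        break
                else:
                    assignments[leaf.taxon.label] = label
                    break
            node = node.parent_node
    return CladeMap(assignments=assignments)


def write_clade_map(clades: CladeMap, path) -> None:
    pd.DataFrame(sorted(clades.assignments.items()),
                 columns=["gene_id", "clade"]).to_csv(path, sep="\t", index=False)


def read_pairwise_hits(path) -> pd.DataFrame:
    """External all-vs-all hit table: the shape of tabular BLAST output.

    Columns: gene_a, gene_b, pct_identity, aln_length, pct_coverage, evalue.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "pct_identity", "pct_coverage"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"pairwise hit table missing: {sorted(missing)}")
    return df
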