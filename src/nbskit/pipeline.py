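"""Stage orchestration: chaining the analyses with per-stage TSV outputs.

Stages run in dependency order (classify -> distribution -> duplication ->
promoters -> expression), each leaving a TSV and a ``<stage>.done`` marker;
re-running an output directory resumes after completed stages. With no input
paths configured, the bundled synthetic recipe supplies a fully structured
test bed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__, clusters as clu, domains as dom, expression as expr
from . import families as fam, io as nio, promoters as pro, simulate as sim
from .model import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "cluster": {"max_gap_kb": 200, "max_intervening": 8, "min_size": 2},
    "family": {"thresholds": [70, 80, 90]},
    "synteny": {"flank": 15, "min_pairs": 5, "max_evalue": 1e-10},
    "promoter": {"upstream": 1500, "gc": None, "n_sets": 2000,
                 "bin_width": 100},
    "expression": {"min_len": 100, "min_identity": 90, "ratio_threshold": 8},
    "cc_threshold": 0.9,
    "paths": {},
}


def load_config(path: Optional[str] = None,
                overrides: Optional[Mapping] = None) -> Dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        section, _, name = key.partition(".")
        if name:
            cfg.setdefault(section, {})[name] = val
        else:
            cfg[key] = val
    return cfg


def config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class PipelineData:
    """Everything the stages consume, loaded from files or simulated."""

    nbs_genes: List
    all_genes: List
    genome: Optional[object]
    domain_calls: List
    clade_map: Optional[object]
    hits: List
    library_sizes: Dict[str, int]
    motifs: List
    homology: Dict = field(default_factory=dict)
    exclude_promoters: List[str] = field(default_factory=list)


def load_data(cfg: Mapping) -> PipelineData:
    paths = cfg.get("paths") or {}
    if not paths:
        recipe = sim.default_recipe(int(cfg["seed"]))
        g = sim.simulate_genome(recipe)
        hits, _ = sim.simulate_hits(recipe)
        return PipelineData(nbs_genes=g.nbs_genes, all_genes=g.all_genes,
                            genome=g.genome, domain_calls=g.domain_calls,
                            clade_map=g.clade_map, hits=hits,
                            library_sizes=dict(recipe.library_sizes),
                            motifs=pro.load_bundled_motifs(),
                            homology=g.homology)
    genes, genome = nio.read_annotation(paths["gff3"], paths["fasta"])
    domain_calls = nio.read_domain_table(paths["domains"]) \
        if paths.get("domains") else []
    nbs_ids = {d.gene_id for d in domain_calls if d.domain == "NBS"} or \
        {g.gene_id for g in genes}
    clade_map = None
    if paths.get("clades"):
        clade_map = nio.read_clade_map(paths["clades"])
    hits = nio.read_hits_table(paths["hits"]) if paths.get("hits") else []
    library_sizes = {}
    if paths.get("library_sizes"):
        df = pd.read_csv(paths["library_sizes"], sep="\t")
        library_sizes = dict(zip(df.iloc[:, 0].astype(str),
                                 df.iloc[:, 1].astype(int)))
    motifs = pro.load_bundled_motifs()
    if paths.get("motifs"):
        df = pd.read_csv(paths["motifs"], sep="\t")
        motifs = [pro.Motif(str(r.iloc[0]), str(r.iloc[1]))
                  for _, r in df.iterrows()]
    homology = {}
    if paths.get("homology"):
        df = nio.read_pairwise_hits(paths["homology"])
        if "evalue" in df.columns:
            for r in df.itertuples(index=False):
                homology[frozenset((str(r.gene_a), str(r.gene_b)))] = \
                    float(r.evalue)
    exclude = []
    if paths.get("exclude_promoters"):
        exclude = [ln.strip() for ln in
                   Path(paths["exclude_promoters"]).read_text().splitlines()
                   if ln.strip()]
    return PipelineData(
        nbs_genes=[g for g in genes if g.gene_id in nbs_ids],
        all_genes=genes, genome=genome, domain_calls=domain_calls,
        clade_map=clade_map, hits=hits, library_sizes=library_sizes,
        motifs=motifs, homology=homology, exclude_promoters=exclude)


def stage_classify(data: PipelineData, cfg: Mapping, out: Path) -> None:
    by_gene: Dict[str, list] = {}
    for call in data.domain_calls:
        by_gene.setdefault(call.gene_id, []).append(call)
    rows = []
    for gene in data.nbs_genes:
        calls = by_gene.get(gene.gene_id)
        if not calls:
            continue
        rows.append({"gene_id": gene.gene_id,
                     "class": dom.classify_architecture(calls)})
    df = pd.DataFrame(rows)
    df.to_csv(out / "classes.tsv", sep="\t", index=False)
    summary = dom.summarize_classes(df["class"]) if len(df) else \
        dom.summarize_classes([])
    pd.DataFrame(sorted(summary.items()),
                 columns=["class", "n_genes"]).to_csv(
        out / "class_summary.tsv", sep="\t", index=False)
    vs = dom.variant_summary(data.nbs_genes)
    pd.DataFrame([vs.__dict__]).to_csv(out / "variant_summary.tsv", sep="\t",
                                       index=False)


def stage_distribution(data: PipelineData, cfg: Mapping, out: Path) -> None:
    c = cfg["cluster"]
    found = clu.detect_clusters(data.nbs_genes, data.all_genes,
                                max_gap_kb=c["max_gap_kb"],
                                max_intervening=c["max_intervening"],
                                min_size=c["min_size"])
    if data.clade_map is not None:
        found = [clu.type_cluster(x, data.clade_map) for x in found]
    else:
        logger.warning("no clade map supplied; clusters left untyped")
    summary = clu.cluster_summary(found, n_mapped=len(data.nbs_genes))
    summary.table.to_csv(out / "clusters.tsv", sep="\t", index=False)
    counts: Dict[str, int] = {}
    for g in data.nbs_genes:
        counts[g.chromosome] = counts.get(g.chromosome, 0) + 1
    lengths = (data.genome.lengths if data.genome is not None
               else {ch: max(g.end for g in data.all_genes
                             if g.chromosome == ch) for ch in counts})
    test = clu.chromosome_enrichment(counts, lengths)
    pd.DataFrame([{"chromosome": ch, "observed": test.observed[ch],
                   "expected": round(test.expected[ch], 2)}
                  for ch in sorted(test.observed)]).to_csv(
        out / "chromosome_counts.tsv", sep="\t", index=False)
    (out / "chromosome_enrichment.txt").write_text(
        f"chi2={test.statistic:.4f}\tp={test.p_value:.4g}\n")


def stage_duplication(data: PipelineData, cfg: Mapping, out: Path) -> None:
    cds_of = {g.gene_id: g.cds for g in data.nbs_genes if g.cds}
    pairs = fam.all_vs_all(cds_of)
    sweep = fam.threshold_sweep(pairs, set(cds_of),
                                thresholds=cfg["family"]["thresholds"])
    pd.DataFrame([{"threshold": t, **m.__dict__}
                  for t, m in sweep.metrics.items()]).to_csv(
        out / "family_metrics.tsv", sep="\t", index=False)
    sweep.transitions.to_csv(out / "family_transitions.tsv", sep="\t")
    c = cfg["cluster"]
    found = clu.detect_clusters(data.nbs_genes, data.all_genes,
                                max_gap_kb=c["max_gap_kb"],
                                max_intervening=c["max_intervening"],
                                min_size=c["min_size"])
    s = cfg["synteny"]
    base_t = cfg["family"]["thresholds"][0]
    calls = fam.classify_duplications(sweep.family_sets[base_t], found,
                                      data.all_genes, data.homology,
                                      flank=s["flank"],
                                      min_pairs=s["min_pairs"],
                                      max_evalue=s["max_evalue"])
    pd.DataFrame([c_.__dict__ for c_ in calls]).to_csv(
        out / "duplications.tsv", sep="\t", index=False)


def stage_promoters(data: PipelineData, cfg: Mapping, out: Path) -> None:
    if data.genome is None:
        logger.warning("no genome; promoter stage skipped")
        return
    p = cfg["promoter"]
    promoters = pro.extract_promoters(data.genome, data.nbs_genes,
                                      upstream=p["upstream"],
                                      exclude=data.exclude_promoters)
    gcs = pro.gc_content(promoters)
    gc = p["gc"] if p["gc"] is not None else gcs.pooled
    results = pro.enrichment_analysis(promoters, data.motifs, gc=gc,
                                      n_sets=p["n_sets"],
                                      seed=int(cfg["seed"]) + 10)
    pro.results_table(results).to_csv(out / "cre_enrichment.tsv", sep="\t",
                                      index=False)
    nio.write_fasta(promoters.sequences, out / "promoters.fasta")
    if data.motifs:
        prof = pro.positional_profile(promoters, data.motifs[0],
                                      n_sims=200, seed=int(cfg["seed"]) + 11,
                                      bin_width=p["bin_width"])
        pd.DataFrame({"bin_start": prof.bin_starts, "count": prof.counts,
                      "env_low": [e[0] for e in prof.mc_envelope],
                      "env_high": [e[1] for e in prof.mc_envelope]}).to_csv(
            out / "cre_positions.tsv", sep="\t", index=False)


def stage_expression(data: PipelineData, cfg: Mapping, out: Path) -> None:
    if not data.hits or not data.library_sizes:
        logger.warning("no hits/library sizes; expression stage skipped")
        return
    e = cfg["expression"]
    kept = expr.filter_hits(data.hits, min_len=e["min_len"],
                            min_identity=e["min_identity"])
    mat = expr.count_and_normalize(kept, data.library_sizes)
    mat.normalized.to_csv(out / "expression_cpm.tsv", sep="\t")
    libs = sorted(data.library_sizes)
    calls = expr.call_enrichment(mat, libs[0], libs[1],
                                 ratio_threshold=e["ratio_threshold"])
    expr.ma_table(calls).to_csv(out / "expression_calls.tsv", sep="\t",
                                index=False)


STAGES = [("classify", stage_classify),
          ("distribution", stage_distribution),
          ("duplication", stage_duplication),
          ("promoters", stage_promoters),
          ("expression", stage_expression)]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: Mapping, out_dir) -> Path:
    """Run all stages into ``out_dir``; completed stages are skipped on
    re-run (a ``<stage>.done`` marker records completion)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"nbskit {__version__}", f"seed {cfg['seed']}",
                 f"config {config_hash(cfg)}"]
    data = load_data(cfg)
    for name, func in STAGES:
        marker = out / f"{name}.done"
        if marker.exists():
            log_lines.append(f"{name}: resumed (already done)")
            continue
        t0 = time.perf_counter()
        try:
            func(data, cfg, out)
        except Exception as exc:   # noqa: BLE001 - reported with stage name
            log_lines.append(f"{name}: FAILED ({exc})")
            (out / "run.log").write_text("\n".join(log_lines) + "\n")
            raise StageError(name, exc) from exc
        marker.touch()
        log_lines.append(f"{name}: ok ({time.perf_counter() - t0:.2f}s)")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
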