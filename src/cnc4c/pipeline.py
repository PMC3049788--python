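"""End-to-end pipeline: digestion, tag processing (or count-table entry),
interaction calling, conservation statistics, networks and exports.

Two entry modes exist because a 4C study may start from raw alignments
(PSL) or from a precomputed per-fragment count table; everything
downstream is identical. Each run writes a provenance record of the
resolved parameters, and a failure in one library is collected and
reported without aborting the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import cir as cir_mod
from . import conservation as cons_mod
from . import network as net_mod
from . import tags as tags_mod
from .cir import Bait, CIRSet
from .genome import FragmentIndex, GenomeIndex, digest_genome, read_bed
from .network import GeneModel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run; defaults are the standard
    analysis settings (tag threshold 50, one flanking fragment excluded,
    29-nt minimum match, 1-nt maximum gap, 5 kb bait window, 10 kb gene
    window, 10000-fragment null)."""

    # inputs
    genome_fasta: str | None = None
    alignments_psl: dict[str, str] = field(default_factory=dict)  # bait_id -> path
    counts_table: str | None = None
    conserved_bed: str | None = None
    exons_bed: str | None = None
    genes_bed: str | None = None
    baits_table: str | None = None  # TSV: bait_id, kind, chrom, start
    # parameters
    threshold: int = 50
    n_flank: int = 1
    min_match: int = 29
    max_gap: int = 1
    window_bait: int = 5000
    window_gene: int = 10_000
    null_size: int = 10_000
    seed: int = 0
    counts_dialect: str = "one-based-inclusive"
    # output
    out_dir: str = "cnc4c_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def read_baits_table(path: str | Path, index: FragmentIndex) -> list[Bait]:
    """TSV with columns bait_id, kind, chrom, start (0-based, any position
    inside the bait fragment); the fragment is resolved on the index."""
    baits: list[Bait] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[0] == "bait_id":
                continue
            if len(f) < 4:
                raise ValueError(f"line {lineno}: expected 4 columns")
            frag = index.locate(f[2], int(f[3]))
            baits.append(Bait(bait_id=f[0], kind=f[1], fragment=frag))  # type: ignore[arg-type]
    return baits


@dataclass
class PipelineResult:
    config: PipelineConfig
    index: FragmentIndex
    baits: list[Bait]
    cir_sets: dict[str, CIRSet]
    summaries: dict[str, cir_mod.CisTransSummary]
    distance_samples: dict[str, cons_mod.DistanceSample]
    null_sample: cons_mod.DistanceSample | None
    tests: dict[str, cons_mod.RankTestResult]
    edges: list[net_mod.ProximityEdge]
    genes_near: dict[str, list[str]]
    errors: dict[str, str]


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the outputs under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.genome_fasta is None:
        raise FileNotFoundError("genome_fasta is required")
    for name, path in [
        ("genome_fasta", cfg.genome_fasta),
        ("conserved_bed", cfg.conserved_bed),
        ("exons_bed", cfg.exons_bed),
        ("baits_table", cfg.baits_table),
    ]:
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"{name}: {path}")

    genome = GenomeIndex.from_fasta(cfg.genome_fasta)
    index = digest_genome(genome)
    index.to_bed(out / "fragments.bed")

    if cfg.baits_table is None:
        raise FileNotFoundError("baits_table is required")
    baits = read_baits_table(cfg.baits_table, index)
    bait_by_id = {b.bait_id: b for b in baits}

    # --- entry mode: counts table or raw alignments
    libraries: dict[str, tags_mod.LibraryCounts] = {}
    errors: dict[str, str] = {}
    if cfg.counts_table is not None:
        for lib in tags_mod.read_counts_table(
            cfg.counts_table, dialect=cfg.counts_dialect, index=index
        ):
            libraries[lib.bait_id] = lib
    else:
        fcfg = tags_mod.FilterConfig(min_match=cfg.min_match, max_gap=cfg.max_gap)
        for bait_id, psl_path in cfg.alignments_psl.items():
            try:
                tags = tags_mod.parse_psl(psl_path)
                kept = tags_mod.filter_tags(tags, fcfg)
                logger.info(
                    "library %s: %d alignments, %d kept, %d rejected",
                    bait_id, len(tags), len(kept), len(tags) - len(kept),
                )
                libraries[bait_id] = tags_mod.assign_tags(kept, index, bait_id=bait_id)
            except Exception as exc:  # noqa: BLE001 — per-library isolation
                errors[bait_id] = str(exc)
    if not libraries:
        raise FileNotFoundError("no libraries: provide counts_table or alignments_psl")

    # --- interaction calling
    cir_sets: dict[str, CIRSet] = {}
    summaries: dict[str, cir_mod.CisTransSummary] = {}
    for bait_id, lib in libraries.items():
        if bait_id not in bait_by_id:
            errors[bait_id] = "no bait definition"
            continue
        try:
            cirs = cir_mod.call_cirs(
                lib, bait_by_id[bait_id], index,
                threshold=cfg.threshold, n_flank=cfg.n_flank,
            )
            cir_sets[bait_id] = cirs
            summaries[bait_id] = cir_mod.cis_trans_summary(cirs)
            cir_mod.export_bedgraph(lib, out / f"{bait_id}.counts.bedgraph", transform="log2")
            cir_mod.export_link_table(cirs, out / f"{bait_id}.links.tsv")
        except Exception as exc:  # noqa: BLE001
            errors[bait_id] = str(exc)
    _write_summaries(summaries, out / "cis_trans_summary.tsv")

    # --- conservation statistics
    distance_samples: dict[str, cons_mod.DistanceSample] = {}
    null_sample = None
    tests: dict[str, cons_mod.RankTestResult] = {}
    if cfg.conserved_bed is not None:
        conserved = read_bed(cfg.conserved_bed)
        exons = read_bed(cfg.exons_bed) if cfg.exons_bed else []
        blocks = cons_mod.build_nonexonic_blocks(
            conserved, exons, provenance=f"{cfg.conserved_bed} - {cfg.exons_bed}"
        )
        per_bait = []
        for bait_id, cirs in cir_sets.items():
            s = cons_mod.distance_sample(cirs, blocks, label="experiment")
            distance_samples[bait_id] = s
            per_bait.append(s)
        pooled = cons_mod.pool_samples(per_bait, label="experiment")
        distance_samples["pooled"] = pooled
        n_null = min(cfg.null_size, index.n_fragments)
        null_frags = cons_mod.sample_null_fragments(
            index, cons_mod.NullConfig(n_samples=n_null, seed=cfg.seed)
        )
        null_sample = cons_mod.distance_sample(null_frags, blocks, label="simulation")
        if pooled.n and null_sample.n:
            tests["pooled_vs_simulation"] = cons_mod.wilcoxon_rank_sum(pooled, null_sample)
        for bait_id, s in distance_samples.items():
            if bait_id != "pooled" and s.n and null_sample.n:
                tests[f"{bait_id}_vs_simulation"] = cons_mod.wilcoxon_rank_sum(s, null_sample)
        _write_distances(distance_samples, null_sample, out / "distances.tsv")
        _write_tests(tests, out / "rank_tests.tsv")
        if pooled.n and null_sample.n:
            _write_qq(cons_mod.qq_points(pooled, null_sample), out / "qq_pooled_vs_simulation.tsv")

    # --- networks
    edges = net_mod.bait_proximity_edges(
        list(cir_sets.values()), baits, window=cfg.window_bait
    )
    net_mod.export_circos_links(edges, out / "bait_network.links", baits=baits)
    _write_edges(edges, out / "bait_network.tsv")
    genes_near: dict[str, list[str]] = {}
    if cfg.genes_bed is not None:
        genes = [
            GeneModel(
                gene_id=iv.name or f"gene{i}",
                chrom=iv.chrom, start=iv.start, end=iv.end,
                strand=iv.strand or "+",
            )
            for i, iv in enumerate(read_bed(cfg.genes_bed))
        ]
        for bait_id, cirs in cir_sets.items():
            genes_near[bait_id] = net_mod.genes_near_cirs(cirs, genes, window=cfg.window_gene)
        with open(out / "genes_near_cirs.tsv", "w") as fh:
            fh.write("bait_id\tgene_id\n")
            for bait_id in sorted(genes_near):
                for g in genes_near[bait_id]:
                    fh.write(f"{bait_id}\t{g}\n")

    provenance = dataclasses.asdict(cfg) | {"n_fragments": index.n_fragments,
                                            "n_libraries": len(libraries),
                                            "errors": errors}
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    cfg.to_yaml(out / "resolved_config.yaml")
    if errors:
        logger.warning("per-library errors: %s", errors)
    return PipelineResult(
        config=cfg, index=index, baits=baits, cir_sets=cir_sets,
        summaries=summaries, distance_samples=distance_samples,
        null_sample=null_sample, tests=tests, edges=edges,
        genes_near=genes_near, errors=errors,
    )


def _write_summaries(summaries, path) -> None:
    with open(path, "w") as fh:
        fh.write("bait_id\ttrans_tag_pct\ttrans_frag_pct\tn_members\tn_tags\n")
        for bait_id in sorted(summaries):
            s = summaries[bait_id]
            fh.write(
                f"{s.bait_id}\t{s.trans_tag_pct:.4f}\t{s.trans_frag_pct:.4f}\t{s.n_members}\t{s.n_tags}\n"
            )


def _write_distances(samples, null_sample, path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tbait_id\tdistance\n")
        for bait_id, s in samples.items():
            if bait_id == "pooled":
                continue
            for v in s.values:
                fh.write(f"{s.label}\t{bait_id}\t{v:g}\n")
        if null_sample is not None:
            for v in null_sample.values:
                fh.write(f"{null_sample.label}\t-\t{v:g}\n")


def _write_tests(tests, path) -> None:
    with open(path, "w") as fh:
        fh.write("comparison\tstatistic\tp_value\tmethod\tn1\tn2\n")
        for name in sorted(tests):
            t = tests[name]
            fh.write(f"{name}\t{t.statistic:g}\t{t.p_value:.6g}\t{t.method}\t{t.n1}\t{t.n2}\n")


def _write_qq(points, path) -> None:
    with open(path, "w") as fh:
        fh.write("qx\tqy\n")
        for qx, qy in points:
            fh.write(f"{qx:g}\t{qy:g}\n")


def _write_edges(edges, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tchrom\tstart\tend\tcount\tdistance\n")
        for e in edges:
            f = e.supporting_fragment
            fh.write(
                f"{e.source_bait_id}\t{e.target_bait_id}\t{f.chrom}\t{f.start}\t{f.end}\t{e.count}\t{e.distance}\n"
            )
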