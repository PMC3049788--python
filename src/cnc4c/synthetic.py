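"""Synthetic genomes, conservation annotation, baits and 4C libraries with
known ground truth.

The generator emulates the features the pipeline's statistics rest on: a
multi-chromosome genome with GATC restriction sites at geometric spacing,
non-overlapping conservation blocks (a configurable share duplicated into
the exon annotation so exon subtraction removes them), bait fragments on a
small bait chromosome, and libraries drawn from an explicit contact model:
a fixed trans probability, power-law distance decay in cis around the
bait, a multiplicative sampling weight for fragments near conservation
blocks, and a no-cross-link mode that samples fragments uniformly
genome-wide.

Background sequence is drawn from {A, G, T} so that GATC occurs exactly
where planted; real base composition is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cir import Bait, call_cirs, library_cis_trans, replicate_reproducibility
from .conservation import (
    ConservationBlockSet,
    NullConfig,
    build_nonexonic_blocks,
    distance_sample,
    sample_null_fragments,
    wilcoxon_rank_sum,
)
from .genome import FragmentIndex, GenomeIndex, GenomicInterval, digest_genome
from .tags import LibraryCounts

# Default chromosome lengths: human-like proportions scaled down, with the
# bait chromosome the smallest (~1.5% of the genome, as chromosome 21 is).
DEFAULT_CHROM_LENGTHS = (800_000, 650_000, 500_000, 400_000, 300_000, 40_000)

# null-sample size used by the recovery harness (the genome there is small)
DEFAULT_RECOVERY_NULL = 2000


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; defaults are the standard study conditions."""

    seed: int = 0
    chrom_length: int | tuple[int, ...] = DEFAULT_CHROM_LENGTHS
    n_chroms: int = len(DEFAULT_CHROM_LENGTHS)
    site_spacing_mean: int = 256  # expected inter-GATC distance of a 4-cutter
    n_blocks_per_chrom: int = 40  # count on the longest chromosome; scaled by length
    block_length_range: tuple[int, int] = (200, 1500)
    exonic_fraction: float = 0.2
    score_range: tuple[float, float] = (525.0, 710.0)
    n_baits: int = 3
    trans_fraction: float = 0.95
    cis_decay_exponent: float = 1.0
    conservation_enrichment: float = 4.0
    enrichment_window: int = 5000
    total_tags: int = 400_000
    crosslinked: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.trans_fraction <= 1.0):
            raise ValueError("trans_fraction must be in [0, 1]")
        if not (0.0 <= self.exonic_fraction <= 1.0):
            raise ValueError("exonic_fraction must be in [0, 1]")
        if self.conservation_enrichment < 0:
            raise ValueError("conservation_enrichment must be >= 0")
        for length in self.chrom_lengths:
            if length <= 0:
                raise ValueError("chromosome lengths must be positive")

    @property
    def chrom_lengths(self) -> tuple[int, ...]:
        if isinstance(self.chrom_length, int):
            return (self.chrom_length,) * self.n_chroms
        return tuple(self.chrom_length)

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths))]

    @property
    def bait_chrom(self) -> str:
        lengths = self.chrom_lengths
        return self.chrom_names[int(np.argmin(lengths))]


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery checks."""

    config: SyntheticConfig
    blocks: list[GenomicInterval] = field(default_factory=list)
    exons: list[GenomicInterval] = field(default_factory=list)
    baits: list[Bait] = field(default_factory=list)
    libraries: dict[str, dict] = field(default_factory=dict)  # bait_id -> params

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"bait_id": b, **params} for b, params in self.libraries.items()
        ]
        return pd.DataFrame(rows)


def generate_genome(cfg: SyntheticConfig) -> GenomeIndex:
    """Random genome with GATC sites at geometric spacing, nothing else.

    Inter-site start distances are 4 + Geometric(1 / (spacing_mean - 4)),
    giving mean spacing ``site_spacing_mean`` with non-overlapping sites.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    background = np.array(list("AGT"))
    names = cfg.chrom_names
    seqs: dict[str, str] = {}
    for name, length in zip(names, cfg.chrom_lengths):
        mean_gap = max(1, cfg.site_spacing_mean - 4)
        # draw enough inter-site gaps to cover the chromosome
        n_draw = max(8, int(2.5 * length / cfg.site_spacing_mean) + 8)
        gaps = 4 + rng.geometric(1.0 / mean_gap, size=n_draw)
        starts = np.cumsum(gaps)
        starts = starts[starts < length - 4]
        seqs[name] = _assemble(rng, background, starts.tolist(), length)
    lengths = {n: len(s) for n, s in seqs.items()}
    return GenomeIndex(chrom_names=names, chrom_lengths=lengths, sequences=seqs, build="synthetic")


def _assemble(rng: np.random.Generator, background: np.ndarray, starts: list[int], length: int) -> str:
    chars = rng.choice(background, size=length)
    for s in starts:
        chars[s : s + 4] = list("GATC")
    return "".join(chars)


def generate_annotation(
    cfg: SyntheticConfig, genome: GenomeIndex, max_retries: int = 1000
) -> tuple[list[GenomicInterval], list[GenomicInterval], GroundTruth]:
    """Place non-overlapping conservation blocks and an exon annotation.

    Block counts scale with chromosome length (``n_blocks_per_chrom`` is
    the count on the longest chromosome) so the block density — and hence
    the distance-to-block field — is stationary across chromosomes.
    ``exonic_fraction`` of the blocks are duplicated into the exon list, so
    exon subtraction removes them entirely.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    lmax = max(genome.chrom_lengths.values())
    blocks: list[GenomicInterval] = []
    exons: list[GenomicInterval] = []
    lo, hi = cfg.block_length_range
    s_lo, s_hi = cfg.score_range
    for chrom in genome.chrom_names:
        length = genome.chrom_lengths[chrom]
        n_blocks = max(1, round(cfg.n_blocks_per_chrom * length / lmax))
        placed: list[tuple[int, int]] = []
        for i in range(n_blocks):
            for _ in range(max_retries):
                blen = int(rng.integers(lo, hi + 1))
                if blen >= length:
                    blen = max(1, length // 2)
                start = int(rng.integers(0, length - blen))
                if all(start + blen <= s or start >= e for s, e in placed):
                    placed.append((start, start + blen))
                    break
            else:
                raise RuntimeError(
                    f"could not place {n_blocks} non-overlapping blocks on {chrom}"
                )
        placed.sort()
        for i, (s, e) in enumerate(placed):
            score = float(rng.uniform(s_lo, s_hi))
            blocks.append(GenomicInterval(chrom, s, e, name=f"{chrom}.blk{i}", score=score))
    n_exonic = int(round(cfg.exonic_fraction * len(blocks)))
    if n_exonic:
        exonic_idx = rng.choice(len(blocks), size=n_exonic, replace=False)
        for i in sorted(exonic_idx):
            b = blocks[i]
            exons.append(GenomicInterval(b.chrom, b.start, b.end, name=f"{b.name}.ex"))
    truth = GroundTruth(config=cfg, blocks=list(blocks), exons=list(exons))
    return blocks, exons, truth


def make_baits(
    cfg: SyntheticConfig, index: FragmentIndex, kind: str = "CNC"
) -> list[Bait]:
    """Pick ``n_baits`` spread-out bait fragments on the bait chromosome."""
    chrom = cfg.bait_chrom
    frags = index.fragments[chrom]
    if len(frags) < cfg.n_baits:
        raise ValueError("not enough fragments on the bait chromosome")
    picks = np.linspace(len(frags) * 0.2, len(frags) * 0.8, cfg.n_baits).astype(int)
    return [
        Bait(bait_id=f"{kind}{i + 1}", fragment=frags[int(p)], kind=kind)  # type: ignore[arg-type]
        for i, p in enumerate(picks)
    ]


class LibraryModel:
    """Precomputed sampling weights for one genome + annotation.

    Building the per-fragment weight vectors once makes repeated library
    draws (replicates, power simulations) cheap.
    """

    def __init__(
        self,
        index: FragmentIndex,
        blocks: ConservationBlockSet | None,
        cfg: SyntheticConfig,
    ) -> None:
        self.index = index
        self.cfg = cfg
        self.fragments = index.all_fragments()
        self.chroms = np.array([f.chrom for f in self.fragments])
        self.centers = np.array([f.center for f in self.fragments], dtype=np.int64)
        self.near_block = np.zeros(len(self.fragments), dtype=bool)
        if blocks is not None and cfg.conservation_enrichment != 1.0:
            for chrom in set(self.chroms):
                if chrom not in blocks.chroms:
                    continue
                mask = self.chroms == chrom
                dist, _, _ = blocks.nearest_many(chrom, self.centers[mask])
                self.near_block[mask] = dist <= cfg.enrichment_window
        self.enrich = np.where(self.near_block, cfg.conservation_enrichment, 1.0)

    def draw(self, bait: Bait, rng: np.random.Generator, replicate_id: str = "1") -> LibraryCounts:
        cfg = self.cfg
        counts = np.zeros(len(self.fragments), dtype=np.int64)
        if not cfg.crosslinked:
            p = np.ones(len(self.fragments))
            p /= p.sum()
            counts = rng.multinomial(cfg.total_tags, p)
        else:
            bait_chrom = bait.fragment.chrom
            cis_mask = self.chroms == bait_chrom
            n_trans = rng.binomial(cfg.total_tags, cfg.trans_fraction)
            n_cis = cfg.total_tags - n_trans
            w_trans = np.where(~cis_mask, self.enrich, 0.0)
            if n_trans and w_trans.sum() > 0:
                counts += rng.multinomial(n_trans, w_trans / w_trans.sum())
            bait_center = bait.fragment.center
            decay = (1.0 + np.abs(self.centers - bait_center, dtype=float)) ** (
                -cfg.cis_decay_exponent
            )
            w_cis = np.where(cis_mask, decay * self.enrich, 0.0)
            if n_cis and w_cis.sum() > 0:
                counts += rng.multinomial(n_cis, w_cis / w_cis.sum())
        nz = np.nonzero(counts)[0]
        return LibraryCounts(
            bait_id=bait.bait_id,
            counts={self.fragments[i]: int(counts[i]) for i in nz},
            replicate_id=replicate_id,
            crosslinked=cfg.crosslinked,
        )


def generate_library(
    cfg: SyntheticConfig,
    index: FragmentIndex,
    blocks: ConservationBlockSet | None,
    bait: Bait,
    seed: int | None = None,
    replicate_id: str = "1",
) -> LibraryCounts:
    """Draw one library; deterministic given the seed (default: cfg.seed)."""
    model = LibraryModel(index, blocks, cfg)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return model.draw(bait, rng, replicate_id=replicate_id)


@dataclass
class SyntheticBundle:
    """Everything one run of the generator produces."""

    config: SyntheticConfig
    genome: GenomeIndex
    index: FragmentIndex
    conserved: list[GenomicInterval]
    exons: list[GenomicInterval]
    blocks: ConservationBlockSet
    baits: list[Bait]
    libraries: list[LibraryCounts]
    truth: GroundTruth


def generate_bundle(cfg: SyntheticConfig, n_replicates: int = 1) -> SyntheticBundle:
    """Genome + annotation + baits + libraries in one call."""
    genome = generate_genome(cfg)
    index = digest_genome(genome)
    conserved, exons, truth = generate_annotation(cfg, genome)
    blocks = build_nonexonic_blocks(conserved, exons, provenance="synthetic")
    baits = make_baits(cfg, index)
    truth.baits = baits
    model = LibraryModel(index, blocks, cfg)
    rng = np.random.default_rng(cfg.seed + 2)
    libraries: list[LibraryCounts] = []
    for bait in baits:
        for rep in range(1, n_replicates + 1):
            libraries.append(model.draw(bait, rng, replicate_id=str(rep)))
            truth.libraries[f"{bait.bait_id}/{rep}"] = {
                "trans_fraction": cfg.trans_fraction,
                "enrichment": cfg.conservation_enrichment,
                "crosslinked": cfg.crosslinked,
                "bait_chrom": bait.fragment.chrom,
                "bait_start": bait.fragment.start,
            }
    return SyntheticBundle(
        config=cfg,
        genome=genome,
        index=index,
        conserved=conserved,
        exons=exons,
        blocks=blocks,
        baits=baits,
        libraries=libraries,
        truth=truth,
    )


# --- synthetic PSL emission ---------------------------------------------------


def library_to_psl(
    lib: LibraryCounts,
    index: FragmentIndex,
    path,
    read_length: int = 36,
    n_bad_records: int = 0,
    seed: int = 0,
) -> None:
    """Write the library as blat-style PSL records anchored at fragment starts.

    Each tag becomes one clean + strand record starting at its fragment's
    GATC boundary. ``n_bad_records`` appends deliberate failures in equal
    parts: sub-29-nt matches, records with a 2-nt gap, and multi-mapping
    read pairs — all of which the quality filter must discard.
    """
    rng = np.random.default_rng(seed)
    lines = []
    read_no = 0
    for frag, count in lib.nonzero():
        chrom_len = index.genome.chrom_lengths[frag.chrom]
        for _ in range(count):
            read_no += 1
            start = frag.start
            end = min(start + read_length, chrom_len)
            match = end - start
            lines.append(_psl_line(f"tag{read_no}", frag.chrom, chrom_len, start, end, match))
    frags = index.all_fragments()
    for k in range(n_bad_records):
        read_no += 1
        f = frags[int(rng.integers(len(frags)))]
        chrom_len = index.genome.chrom_lengths[f.chrom]
        mode = k % 3
        if mode == 0:  # too short
            end = min(f.start + 25, chrom_len)
            lines.append(_psl_line(f"bad{read_no}", f.chrom, chrom_len, f.start, end, end - f.start))
        elif mode == 1:  # 2-nt gap
            end = min(f.start + read_length + 2, chrom_len)
            lines.append(
                _psl_line(f"bad{read_no}", f.chrom, chrom_len, f.start, end, read_length, gap=2)
            )
        else:  # multi-mapper: same read id at two loci
            g = frags[int(rng.integers(len(frags)))]
            end_f = min(f.start + read_length, chrom_len)
            g_len = index.genome.chrom_lengths[g.chrom]
            end_g = min(g.start + read_length, g_len)
            rid = f"bad{read_no}"
            lines.append(_psl_line(rid, f.chrom, chrom_len, f.start, end_f, end_f - f.start))
            lines.append(_psl_line(rid, g.chrom, g_len, g.start, end_g, end_g - g.start))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def _psl_line(
    read_id: str,
    chrom: str,
    chrom_len: int,
    start: int,
    end: int,
    match: int,
    gap: int = 0,
) -> str:
    qsize = match + gap if gap else match
    if gap:
        b1 = match // 2
        b2 = match - b1
        block_count = 2
        block_sizes = f"{b1},{b2},"
        q_starts = f"0,{b1},"
        t_starts = f"{start},{start + b1 + gap},"
        t_insert = gap
    else:
        block_count = 1
        block_sizes = f"{match},"
        q_starts = "0,"
        t_starts = f"{start},"
        t_insert = 0
    fields = [
        match, 0, 0, 0,  # matches, misMatches, repMatches, nCount
        0, 0, 1 if gap else 0, t_insert,  # qNumInsert, qBaseInsert, tNumInsert, tBaseInsert
        "+", read_id, qsize, 0, match,  # strand, qName, qSize, qStart, qEnd
        chrom, chrom_len, start, end,  # tName, tSize, tStart, tEnd
        block_count, block_sizes, q_starts, t_starts,
    ]
    return "\t".join(str(x) for x in fields)


# --- validation harness -------------------------------------------------------


def run_recovery_experiment(
    configs: Sequence[SyntheticConfig],
    n_replicates: int = 50,
    master_seed: int = 0,
    alpha: float = 0.05,
    threshold: int = 50,
    null_size: int | None = None,
) -> pd.DataFrame:
    """Simulation harness: per config, how well does the pipeline recover
    the generator's parameters and how often does the distance test reject?

    For each replicate: draw one library, estimate the trans tag fraction
    (unthresholded, whole library), call CIRs, measure member distances to
    the nearest non-exonic block, compare against a fresh uniform fragment
    sample with the rank-sum test, and score reproducibility between two
    replicate draws. Deterministic given the master seed.
    """
    rows = []
    for ci, cfg in enumerate(configs):
        genome = generate_genome(cfg)
        index = digest_genome(genome)
        conserved, exons, _ = generate_annotation(cfg, genome)
        blocks = build_nonexonic_blocks(conserved, exons)
        bait = make_baits(replace(cfg, n_baits=1), index)[0]
        model = LibraryModel(index, blocks, cfg)
        n_frags = index.n_fragments
        nsize = min(null_size or DEFAULT_RECOVERY_NULL, n_frags)
        rng = np.random.default_rng(master_seed + 1000 * ci)
        sigma = (
            np.sqrt(cfg.trans_fraction * (1 - cfg.trans_fraction) / cfg.total_tags)
            if 0 < cfg.trans_fraction < 1
            else 0.0
        )
        n_reject = 0
        n_within = 0
        n_tested = 0
        est_trans = []
        repro = []
        member_counts = []
        for rep in range(n_replicates):
            lib1 = model.draw(bait, rng, replicate_id="1")
            est = library_cis_trans(lib1, bait.fragment.chrom) / 100.0
            est_trans.append(est)
            if cfg.crosslinked and sigma > 0:
                n_within += abs(est - cfg.trans_fraction) <= 2 * sigma
            cirs1 = call_cirs(lib1, bait, index, threshold=threshold)
            member_counts.append(cirs1.n_members)
            exp = distance_sample(cirs1, blocks, label="experiment")
            null_frags = sample_null_fragments(
                index,
                NullConfig(n_samples=nsize, seed=int(rng.integers(2**31))),
            )
            sim = distance_sample(null_frags, blocks, label="simulation")
            if exp.n and sim.n:
                res = wilcoxon_rank_sum(exp, sim)
                n_tested += 1
                n_reject += res.p_value < alpha
            lib2 = model.draw(bait, rng, replicate_id="2")
            cirs2 = call_cirs(lib2, bait, index, threshold=threshold)
            if cirs1.n_members:
                repro.append(replicate_reproducibility(cirs1, cirs2))
        rows.append(
            {
                "trans_fraction": cfg.trans_fraction,
                "enrichment": cfg.conservation_enrichment,
                "crosslinked": cfg.crosslinked,
                "total_tags": cfg.total_tags,
                "n_replicates": n_replicates,
                "mean_est_trans": float(np.mean(est_trans)),
                "trans_within_2sigma": float(n_within / n_replicates)
                if cfg.crosslinked and sigma > 0
                else np.nan,
                "rejection_rate": float(n_reject / n_tested) if n_tested else np.nan,
                "n_tested": n_tested,
                "mean_n_members": float(np.mean(member_counts)),
                "mean_reproducibility": float(np.mean(repro)) if repro else np.nan,
            }
        )
    return pd.DataFrame(rows)
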