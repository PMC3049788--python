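"""Bait-bait proximity networks and gene-proximity overlap statistics.

A directed edge A -> B means: the library interrogated from bait A
contains a called interacting fragment lying within a window (default
5 kb) of bait B — evidence that the two viewpoints contact or co-localise.
Genes near a library's interacting fragments (default window 10 kb) feed a
hypergeometric over-representation test against annotated gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from scipy.stats import hypergeom

from .cir import Bait, CIRSet
from .genome import GenomicInterval, RestrictionFragment

DEFAULT_BAIT_WINDOW = 5000
DEFAULT_GENE_WINDOW = 10_000


@dataclass(frozen=True)
class ProximityEdge:
    source_bait_id: str
    target_bait_id: str
    supporting_fragment: RestrictionFragment
    count: int
    distance: int


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("gene start must be < end")


@dataclass
class OverlapResult:
    k: int  # overlap
    n: int  # query gene count
    K: int  # gene-set size
    N: int  # universe size
    p_value: float
    degenerate: bool = False


def bait_proximity_edges(
    libraries: Sequence[CIRSet],
    baits: Sequence[Bait],
    window: int = DEFAULT_BAIT_WINDOW,
    measure: Literal["center", "gap"] = "center",
) -> list[ProximityEdge]:
    """Directed edges: library A holds a member fragment near bait B (A != B).

    ``measure="center"`` compares fragment center to bait-fragment center
    (the same convention as the conservation distances); ``"gap"`` uses the
    edge-to-edge interval gap instead. Every qualifying (member, bait) pair
    yields one edge, so multi-fragment support is visible; edges are sorted
    and de-duplicated per supporting fragment.
    """
    edges: list[ProximityEdge] = []
    for cirs in libraries:
        src = cirs.bait.bait_id
        for frag, count in cirs.members:
            for bait in baits:
                if bait.bait_id == src:
                    continue
                b = bait.fragment
                if frag.chrom != b.chrom:
                    continue
                if measure == "center":
                    dist = abs(frag.center - b.center)
                else:
                    dist = _interval_gap(frag.start, frag.end, b.start, b.end)
                if dist <= window:
                    edges.append(
                        ProximityEdge(
                            source_bait_id=src,
                            target_bait_id=bait.bait_id,
                            supporting_fragment=frag,
                            count=count,
                            distance=int(dist),
                        )
                    )
    edges.sort(key=lambda e: (e.source_bait_id, e.target_bait_id, e.supporting_fragment.key()))
    return edges


def _interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge gap of two intervals; 0 when they overlap or touch."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def genes_near_cirs(
    cirs: CIRSet,
    genes: Sequence[GeneModel],
    window: int = DEFAULT_GENE_WINDOW,
) -> list[str]:
    """Genes whose minimal gap to any member fragment is <= window.

    Overlap counts as gap 0; the result is de-duplicated and sorted.
    """
    members_by_chrom: dict[str, list[RestrictionFragment]] = {}
    for frag, _ in cirs.members:
        members_by_chrom.setdefault(frag.chrom, []).append(frag)
    hits: set[str] = set()
    for gene in genes:
        for frag in members_by_chrom.get(gene.chrom, []):
            if _interval_gap(frag.start, frag.end, gene.start, gene.end) <= window:
                hits.add(gene.gene_id)
                break
    return sorted(hits)


def geneset_overlap_test(
    query_genes: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
) -> OverlapResult:
    """Hypergeometric upper-tail over-representation test.

    With N universe genes of which K are in the set, drawing n query genes,
    the p-value is P[X >= k] for X ~ Hypergeometric(N, K, n). k = 0 (or an
    empty query) gives p = 1 by construction.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    query = set(query_genes)
    gset = set(gene_set)
    if not query <= uni:
        raise ValueError("query genes must be a subset of the universe")
    if not gset <= uni:
        raise ValueError("gene set must be a subset of the universe")
    N, K, n = len(uni), len(gset), len(query)
    k = len(query & gset)
    if n == 0 or k == 0:
        return OverlapResult(k=k, n=n, K=K, N=N, p_value=1.0, degenerate=(n == 0))
    p = float(hypergeom.sf(k - 1, N, K, n))
    return OverlapResult(k=k, n=n, K=K, N=N, p_value=min(p, 1.0))


# --- circos link export -------------------------------------------------------


def export_circos_links(
    items: Sequence[ProximityEdge] | CIRSet,
    path: str | Path,
    baits: Sequence[Bait] | None = None,
) -> None:
    """Write circos-style link lines: two positional interval triples per line.

    For a CIRSet the links run bait -> member fragment; for edges they run
    bait A -> supporting fragment near bait B (``baits`` resolves A).
    Empty input produces a header-only file.
    """
    lines: list[str] = []
    if isinstance(items, CIRSet):
        b = items.bait.fragment
        for frag, _ in items.members:
            lines.append(
                f"{b.chrom}\t{b.start}\t{b.end}\t{frag.chrom}\t{frag.start}\t{frag.end}"
            )
    else:
        bait_by_id = {bt.bait_id: bt for bt in baits or []}
        for e in items:
            if e.source_bait_id not in bait_by_id:
                raise ValueError(f"unknown source bait: {e.source_bait_id}")
            b = bait_by_id[e.source_bait_id].fragment
            f = e.supporting_fragment
            lines.append(f"{b.chrom}\t{b.start}\t{b.end}\t{f.chrom}\t{f.start}\t{f.end}")
    with open(path, "w") as fh:
        fh.write("# chrA\tstartA\tendA\tchrB\tstartB\tendB\n")
        for line in lines:
            fh.write(line + "\n")


def read_circos_links(path: str | Path) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """Parse a link file back into interval pairs (round-trip check)."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            pairs.append(
                (
                    GenomicInterval(f[0], int(f[1]), int(f[2])),
                    GenomicInterval(f[3], int(f[4]), int(f[5])),
                )
            )
    return pairs
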