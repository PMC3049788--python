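"""Alignment-tag filtering and conversion to per-fragment counts.

4C sequencing reads are primed immediately upstream of the bait's DpnII
site, so every informative read starts with GATC and its alignment is
anchored at a restriction-fragment boundary. Reads are aligned upstream
(blat); this module consumes the PSL output, applies the quality filters
(minimum match length, maximum gap size, GATC prefix, unique placement)
and accumulates the accepted tags into fragment counts per library.
"""

from __future__ import annotations

import bisect
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .genome import FragmentIndex, RestrictionFragment

logger = logging.getLogger(__name__)

PSL_N_COLUMNS = 21


class PslFormatError(ValueError):
    pass


class CountsFormatError(ValueError):
    pass


@dataclass(frozen=True)
class AlignedTag:
    """One (read, locus) alignment.

    ``hit_count`` is the number of genomic loci the read aligns to;
    ``max_gap`` the largest single gap (bp) in either query or target;
    ``leading_seq`` the first four nucleotides of the read when the read
    sequence is available, otherwise inferred (see ``parse_psl``).
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    match_length: int
    max_gap: int
    hit_count: int
    leading_seq: str

    def __post_init__(self) -> None:
        if self.match_length < 0 or self.hit_count < 1:
            raise ValueError("invalid AlignedTag")


@dataclass(frozen=True)
class FilterConfig:
    """Alignment quality criteria; defaults are the standard 4C settings."""

    min_match: int = 29
    max_gap: int = 1
    required_prefix: str = "GATC"
    require_unique: bool = True

    def __post_init__(self) -> None:
        if self.min_match < 1 or self.max_gap < 0:
            raise ValueError("invalid FilterConfig")


@dataclass
class LibraryCounts:
    """One 4C library: fragment -> tag count, keyed by fragment identity."""

    bait_id: str
    counts: dict[RestrictionFragment, int]
    replicate_id: str = "1"
    crosslinked: bool = True
    n_unassigned: int = 0

    @property
    def total_tags(self) -> int:
        return sum(self.counts.values())

    def nonzero(self) -> list[tuple[RestrictionFragment, int]]:
        return sorted(
            ((f, c) for f, c in self.counts.items() if c > 0),
            key=lambda fc: fc[0].key(),
        )


def parse_psl(
    path: str | Path, read_seqs: dict[str, str] | None = None
) -> list[AlignedTag]:
    """Parse blat PSL (21 tab-separated columns, optional 5-line header).

    ``hit_count`` is filled in from the number of records sharing a read id.
    When read sequences are unavailable the GATC prefix cannot be observed
    directly; it is then inferred from the alignment covering the query
    from position 0 (the sequencing primer design guarantees reads begin
    with the restriction site).
    """
    raw: list[dict] = []
    with open(path) as fh:
        lines = fh.readlines()
    start_at = 0
    if lines and lines[0].startswith("psLayout"):
        start_at = 5  # psLayout header block
    for lineno, line in enumerate(lines[start_at:], start=start_at + 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != PSL_N_COLUMNS:
            raise PslFormatError(
                f"line {lineno}: expected {PSL_N_COLUMNS} columns, got {len(fields)}"
            )
        raw.append(_psl_record(fields))
    hits = Counter(r["read_id"] for r in raw)
    tags = []
    for r in raw:
        if read_seqs is not None and r["read_id"] in read_seqs:
            leading = read_seqs[r["read_id"]][:4].upper()
        else:
            leading = "GATC" if r["q_start"] == 0 else ""
        tags.append(
            AlignedTag(
                read_id=r["read_id"],
                chrom=r["chrom"],
                start=r["start"],
                end=r["end"],
                strand=r["strand"],
                match_length=r["match_length"],
                max_gap=r["max_gap"],
                hit_count=hits[r["read_id"]],
                leading_seq=leading,
            )
        )
    return tags


def _psl_record(fields: list[str]) -> dict:
    matches = int(fields[0])
    rep_matches = int(fields[2])
    q_insert = int(fields[5])
    t_insert = int(fields[7])
    strand = fields[8]
    block_count = int(fields[17])
    max_gap = max(q_insert, t_insert)
    if block_count > 1:
        sizes = _csl(fields[18])
        q_starts = _csl(fields[19])
        t_starts = _csl(fields[20])
        gaps = []
        for i in range(block_count - 1):
            gaps.append(q_starts[i + 1] - (q_starts[i] + sizes[i]))
            gaps.append(t_starts[i + 1] - (t_starts[i] + sizes[i]))
        max_gap = max(gaps) if gaps else 0
    return {
        "read_id": fields[9],
        "chrom": fields[13],
        "start": int(fields[15]),
        "end": int(fields[16]),
        "strand": strand[0],
        "match_length": matches + rep_matches,
        "max_gap": max_gap,
        "q_start": int(fields[11]),
    }


def _csl(s: str) -> list[int]:
    return [int(x) for x in s.rstrip(",").split(",") if x]


def filter_tags(tags: Iterable[AlignedTag], cfg: FilterConfig | None = None) -> list[AlignedTag]:
    """Keep tags meeting all quality criteria; order preserved."""
    cfg = cfg or FilterConfig()
    kept = [
        t
        for t in tags
        if t.match_length >= cfg.min_match
        and t.max_gap <= cfg.max_gap
        and t.leading_seq == cfg.required_prefix
        and (not cfg.require_unique or t.hit_count == 1)
    ]
    return kept


def assign_tags(
    tags: Sequence[AlignedTag],
    index: FragmentIndex,
    tolerance: int = 0,
    bait_id: str = "unknown",
    replicate_id: str = "1",
    crosslinked: bool = True,
) -> LibraryCounts:
    """Assign boundary-anchored tags to fragments and accumulate counts.

    A + strand tag belongs to the fragment starting at its 5' end; a −
    strand tag to the fragment ending at its 3' end (the read runs into the
    fragment from the GATC boundary). A boundary mismatch of at most
    ``tolerance`` bp snaps to the nearest boundary; anything else is
    counted as unassigned and dropped.
    """
    start_map: dict[str, dict[int, RestrictionFragment]] = defaultdict(dict)
    end_map: dict[str, dict[int, RestrictionFragment]] = defaultdict(dict)
    for frag in index:
        start_map[frag.chrom][frag.start] = frag
        end_map[frag.chrom][frag.end] = frag
    sorted_starts = {c: sorted(m) for c, m in start_map.items()}
    sorted_ends = {c: sorted(m) for c, m in end_map.items()}

    counts: dict[RestrictionFragment, int] = defaultdict(int)
    unassigned = 0
    for tag in tags:
        if tag.chrom not in start_map:
            logger.warning("tag %s on unknown chromosome %s", tag.read_id, tag.chrom)
            unassigned += 1
            continue
        if tag.strand == "+":
            frag = _snap(tag.start, start_map[tag.chrom], sorted_starts[tag.chrom], tolerance)
        else:
            frag = _snap(tag.end, end_map[tag.chrom], sorted_ends[tag.chrom], tolerance)
        if frag is None:
            unassigned += 1
        else:
            counts[frag] += 1
    lib = LibraryCounts(
        bait_id=bait_id,
        counts=dict(counts),
        replicate_id=replicate_id,
        crosslinked=crosslinked,
        n_unassigned=unassigned,
    )
    logger.info(
        "assign_tags[%s]: %d assigned, %d unassigned", bait_id, lib.total_tags, unassigned
    )
    return lib


def _snap(
    pos: int,
    boundary_map: dict[int, RestrictionFragment],
    boundaries: list[int],
    tolerance: int,
) -> RestrictionFragment | None:
    if pos in boundary_map:
        return boundary_map[pos]
    if tolerance <= 0:
        return None
    i = bisect.bisect_left(boundaries, pos)
    best = None
    best_d = tolerance + 1
    for j in (i - 1, i):
        if 0 <= j < len(boundaries):
            d = abs(boundaries[j] - pos)
            if d < best_d:
                best, best_d = boundaries[j], d
    return boundary_map[best] if best is not None else None


# --- count-table I/O (published per-library table dialect) -------------------

COUNTS_COLUMNS = ("BaitID", "Chr", "DpnIIStart", "DpnIIEnd", "NumbReads")


def read_counts_table(
    path: str | Path,
    dialect: str = "one-based-inclusive",
    index: FragmentIndex | None = None,
) -> list[LibraryCounts]:
    """Read a per-library fragment count table (tab-separated).

    Columns: BaitID, Chr, DpnIIStart, DpnIIEnd, NumbReads. The published
    table's coordinate convention is not documented; the default dialect
    treats it as 1-based inclusive and converts to 0-based half-open
    (``dialect="zero-based-half-open"`` disables the conversion). When a
    ``FragmentIndex`` is given, rows are mapped onto its fragments so the
    ordinals are meaningful.
    """
    if dialect not in ("one-based-inclusive", "zero-based-half-open"):
        raise ValueError(f"unknown dialect: {dialect}")
    off = 1 if dialect == "one-based-inclusive" else 0
    per_bait: dict[str, dict[RestrictionFragment, int]] = defaultdict(dict)
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "BaitID":
                continue
            if len(fields) < 5:
                raise CountsFormatError(f"line {lineno}: expected 5 columns")
            bait_id, chrom = fields[0], fields[1]
            try:
                start = int(fields[2]) - off
                end = int(fields[3])
                n_reads = int(fields[4])
            except ValueError as exc:
                raise CountsFormatError(f"line {lineno}: non-integer field") from exc
            if n_reads < 0:
                raise CountsFormatError(f"line {lineno}: negative NumbReads")
            if index is not None:
                frag = index.locate(chrom, start)
            else:
                frag = RestrictionFragment(chrom, start, end)
            if bait_id not in per_bait:
                order.append(bait_id)
            if frag in per_bait[bait_id]:
                raise CountsFormatError(
                    f"line {lineno}: duplicate fragment for bait {bait_id}"
                )
            per_bait[bait_id][frag] = n_reads
    return [LibraryCounts(bait_id=b, counts=per_bait[b]) for b in order]


def write_counts_table(
    libs: Sequence[LibraryCounts],
    path: str | Path,
    dialect: str = "one-based-inclusive",
) -> None:
    seen: set[str] = set()
    for lib in libs:
        if lib.bait_id in seen:
            raise ValueError(f"duplicate BaitID across libraries: {lib.bait_id}")
        seen.add(lib.bait_id)
    off = 1 if dialect == "one-based-inclusive" else 0
    with open(path, "w") as fh:
        fh.write("\t".join(COUNTS_COLUMNS) + "\n")
        for lib in libs:
            for frag, count in lib.nonzero():
                fh.write(
                    f"{lib.bait_id}\t{frag.chrom}\t{frag.start + off}\t{frag.end}\t{count}\n"
                )
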