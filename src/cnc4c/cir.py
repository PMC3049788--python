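"""Interaction calling: bait-flanking exclusion, tag-count thresholding,
cis/trans summaries and replicate reproducibility.

A CIR (CNC-interacting region) is a restriction fragment observed at or
above a tag-count threshold (default 50) in a bait's library, after the
bait fragment and its directly flanking fragments — over-represented
through partial digestion and the proximity effect — have been removed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

from .genome import FragmentIndex, RestrictionFragment
from .tags import LibraryCounts

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 50
DEFAULT_N_FLANK = 1

BaitKind = Literal["CNC", "nonCNC", "control-locus"]


@dataclass(frozen=True)
class Bait:
    """A 4C viewpoint: the fixed restriction fragment a library is amplified from."""

    bait_id: str
    fragment: RestrictionFragment
    kind: BaitKind = "CNC"
    conservation_score: float | None = None
    lod: float | None = None


@dataclass
class CIRSet:
    """Fragments passing the tag threshold in one library, bait flanks excluded."""

    bait: Bait
    threshold: int
    members: list[tuple[RestrictionFragment, int]]
    excluded_flanking: list[RestrictionFragment] = field(default_factory=list)

    @property
    def member_fragments(self) -> list[RestrictionFragment]:
        return [f for f, _ in self.members]

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_tags(self) -> int:
        return sum(c for _, c in self.members)


@dataclass
class CisTransSummary:
    bait_id: str
    trans_tag_pct: float
    trans_frag_pct: float
    n_members: int
    n_tags: int


def exclude_bait_flanking(
    lib: LibraryCounts,
    bait: Bait,
    index: FragmentIndex,
    n_flank: int = DEFAULT_N_FLANK,
) -> LibraryCounts:
    """Drop the bait fragment and ``n_flank`` fragments on each side.

    At a chromosome end fewer fragments exist and fewer are removed.
    Returns a new LibraryCounts; the removed fragments are logged.
    """
    if n_flank < 0:
        raise ValueError("n_flank must be >= 0")
    bait_frag = index.locate(bait.fragment.chrom, bait.fragment.start)
    removed = index.neighbors(bait_frag, n_flank)
    removed_set = set(removed)
    counts = {f: c for f, c in lib.counts.items() if f not in removed_set}
    logger.info(
        "exclude_bait_flanking[%s]: removed %d fragments (%d tags)",
        bait.bait_id,
        len(removed),
        sum(lib.counts.get(f, 0) for f in removed),
    )
    out = LibraryCounts(
        bait_id=lib.bait_id,
        counts=counts,
        replicate_id=lib.replicate_id,
        crosslinked=lib.crosslinked,
        n_unassigned=lib.n_unassigned,
    )
    out.excluded_flanking = removed  # type: ignore[attr-defined]
    return out


def call_cirs(
    lib: LibraryCounts,
    bait: Bait,
    index: FragmentIndex,
    threshold: int = DEFAULT_THRESHOLD,
    n_flank: int = DEFAULT_N_FLANK,
) -> CIRSet:
    """Call CIRs: flank exclusion, then keep fragments with count >= threshold."""
    trimmed = exclude_bait_flanking(lib, bait, index, n_flank)
    members = sorted(
        ((f, c) for f, c in trimmed.counts.items() if c >= threshold),
        key=lambda fc: fc[0].key(),
    )
    return CIRSet(
        bait=bait,
        threshold=threshold,
        members=members,
        excluded_flanking=getattr(trimmed, "excluded_flanking", []),
    )


def cis_trans_summary(cirs: CIRSet) -> CisTransSummary:
    """Trans percentages over member tags and member fragments.

    trans = member on a chromosome different from the bait's. Both
    percentages are 0 for an empty CIR set (``n_members`` flags it).
    """
    bait_chrom = cirs.bait.fragment.chrom
    n_tags = cirs.n_tags
    n_members = cirs.n_members
    trans_tags = sum(c for f, c in cirs.members if f.chrom != bait_chrom)
    trans_frags = sum(1 for f, _ in cirs.members if f.chrom != bait_chrom)
    return CisTransSummary(
        bait_id=cirs.bait.bait_id,
        trans_tag_pct=100.0 * trans_tags / n_tags if n_tags else 0.0,
        trans_frag_pct=100.0 * trans_frags / n_members if n_members else 0.0,
        n_members=n_members,
        n_tags=n_tags,
    )


def library_cis_trans(lib: LibraryCounts, bait_chrom: str) -> float:
    """Unthresholded trans tag percentage of a whole library.

    The thresholded variant (``cis_trans_summary``) describes called CIRs;
    this one is the raw library composition, the natural estimator of the
    generating trans fraction.
    """
    total = lib.total_tags
    if total == 0:
        return 0.0
    trans = sum(c for f, c in lib.counts.items() if f.chrom != bait_chrom)
    return 100.0 * trans / total


def replicate_reproducibility(lib1: CIRSet, lib2: CIRSet) -> float:
    """Percentage of experiment-1 member fragments recovered in experiment 2.

    Asymmetric by definition: the denominator is the experiment-1 member
    count. Fragment identity is identical coordinates.
    """
    if lib1.bait.bait_id != lib2.bait.bait_id:
        raise ValueError("reproducibility requires the same bait")
    m1 = set(lib1.member_fragments)
    if not m1:
        raise ValueError("experiment 1 has no members; reproducibility undefined")
    m2 = set(lib2.member_fragments)
    return 100.0 * len(m1 & m2) / len(m1)


def jaccard_reproducibility(lib1: CIRSet, lib2: CIRSet) -> float:
    """Symmetric companion metric: Jaccard index of the member sets (%)."""
    m1, m2 = set(lib1.member_fragments), set(lib2.member_fragments)
    union = m1 | m2
    if not union:
        raise ValueError("both member sets empty; Jaccard undefined")
    return 100.0 * len(m1 & m2) / len(union)


def export_bedgraph(
    lib: LibraryCounts,
    path: str | Path,
    transform: Literal["none", "log2"] = "none",
    track_name: str | None = None,
) -> None:
    """Write nonzero fragment counts as bedGraph, optionally log2-transformed."""
    with open(path, "w") as fh:
        if track_name:
            fh.write(f"track type=bedGraph name={track_name}\n")
        for frag, count in lib.nonzero():
            value = math.log2(count) if transform == "log2" else count
            fh.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\t{value:g}\n")


def export_link_table(cirs: CIRSet, path: str | Path) -> None:
    """Bait-to-member link table (circos-style columns plus the tag count)."""
    b = cirs.bait.fragment
    with open(path, "w") as fh:
        fh.write("# chrA\tstartA\tendA\tchrB\tstartB\tendB\tcount\n")
        for frag, count in cirs.members:
            fh.write(
                f"{b.chrom}\t{b.start}\t{b.end}\t{frag.chrom}\t{frag.start}\t{frag.end}\t{count}\n"
            )
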