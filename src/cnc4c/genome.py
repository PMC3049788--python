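"""Reference-genome model, in-silico restriction digestion and interval I/O.

All coordinates are 0-based, half-open. DpnII recognises GATC and cleaves
5' of the site, so every cut coordinate is the start of a GATC occurrence
and every internal restriction fragment begins with GATC.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DPNII_SITE = "GATC"


class BedFormatError(ValueError):
    """A BED record violated the interval invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally named and scored."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True, order=True)
class RestrictionFragment:
    """One restriction fragment; ``ordinal`` is its 0-based rank on its chromosome.

    Identity (equality/hash) is by coordinates only: fragments read from
    external count tables without an accompanying digestion carry
    ``ordinal = -1`` yet must compare equal to their digested counterparts.
    """

    chrom: str
    start: int
    end: int
    ordinal: int = field(default=-1, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid fragment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def fragment_center(frag: RestrictionFragment | GenomicInterval) -> int:
    """Floor midpoint of an interval; the anchor of all center-to-center distances."""
    return (frag.start + frag.end) // 2


@dataclass
class GenomeIndex:
    """Chromosome names, lengths and (optionally) sequences."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    sequences: dict[str, str] | None = None
    build: str | None = None  # e.g. "hg18"; metadata only

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        for name in self.chrom_names:
            if self.chrom_lengths[name] <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            if self.sequences is not None:
                if len(self.sequences[name]) != self.chrom_lengths[name]:
                    raise ValueError(f"sequence/length mismatch for {name}")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    @classmethod
    def from_fasta(cls, path: str | Path, build: str | None = None) -> "GenomeIndex":
        names: list[str] = []
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs[rec.id] = str(rec.seq).upper()
        lengths = {n: len(s) for n, s in seqs.items()}
        return cls(chrom_names=names, chrom_lengths=lengths, sequences=seqs, build=build)

    def to_fasta(self, path: str | Path) -> None:
        if self.sequences is None:
            raise ValueError("sequences required")
        records = [
            SeqRecord(Seq(self.sequences[n]), id=n, description="")
            for n in self.chrom_names
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class FragmentIndex:
    """The genome partitioned into restriction fragments.

    Per chromosome the fragments are disjoint, ordered and tile
    ``[0, chrom_length)`` exactly; this is the coordinate system in which
    all tag counting happens.
    """

    genome: GenomeIndex
    fragments: dict[str, list[RestrictionFragment]]
    enzyme_site: str = DPNII_SITE
    _starts: dict[str, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._starts:
            self._starts = {
                chrom: [f.start for f in frags] for chrom, frags in self.fragments.items()
            }

    @property
    def n_fragments(self) -> int:
        return sum(len(v) for v in self.fragments.values())

    def __iter__(self) -> Iterator[RestrictionFragment]:
        for chrom in self.genome.chrom_names:
            yield from self.fragments.get(chrom, [])

    def all_fragments(self) -> list[RestrictionFragment]:
        return list(self)

    def locate(self, chrom: str, pos: int) -> RestrictionFragment:
        """Fragment containing ``pos`` (binary search)."""
        if chrom not in self.fragments:
            raise KeyError(f"unknown chromosome: {chrom}")
        length = self.genome.chrom_lengths[chrom]
        if not (0 <= pos < length):
            raise ValueError(f"position {pos} outside [0, {length}) on {chrom}")
        starts = self._starts[chrom]
        i = bisect.bisect_right(starts, pos) - 1
        return self.fragments[chrom][i]

    def neighbors(self, frag: RestrictionFragment, n_flank: int) -> list[RestrictionFragment]:
        """``frag`` plus up to ``n_flank`` fragments on each side, by ordinal."""
        frags = self.fragments[frag.chrom]
        lo = max(0, frag.ordinal - n_flank)
        hi = min(len(frags), frag.ordinal + n_flank + 1)
        return frags[lo:hi]

    def to_bed(self, path: str | Path) -> None:
        """Serialise as BED4 with name ``chrom:ordinal``."""
        intervals = [
            GenomicInterval(f.chrom, f.start, f.end, name=f"{f.chrom}:{f.ordinal}")
            for f in self
        ]
        write_bed(intervals, path)


def locate_fragment(index: FragmentIndex, chrom: str, pos: int) -> RestrictionFragment:
    return index.locate(chrom, pos)


def digest_genome(genome: GenomeIndex, site: str = DPNII_SITE) -> FragmentIndex:
    """In-silico digestion: cut at the start of every occurrence of ``site``.

    Occurrences containing N never match (repeat-masked genomes contain N
    runs). A site at position 0 would produce a zero-length leading
    fragment, which can hold no tags and is dropped.
    """
    if genome.sequences is None:
        raise ValueError("sequences required")
    site = site.upper()
    if not site or any(c not in "ACGT" for c in site):
        raise ValueError(f"invalid recognition site: {site!r}")
    fragments: dict[str, list[RestrictionFragment]] = {}
    for chrom in genome.chrom_names:
        seq = genome.sequences[chrom].upper()
        cuts = _find_site_starts(seq, site)
        bounds = [0] + [c for c in cuts if c > 0] + [len(seq)]
        frags = [
            RestrictionFragment(chrom, s, e, ordinal=i)
            for i, (s, e) in enumerate(zip(bounds[:-1], bounds[1:]))
        ]
        fragments[chrom] = frags
    return FragmentIndex(genome=genome, fragments=fragments, enzyme_site=site)


def _find_site_starts(seq: str, site: str) -> list[int]:
    # str.find cannot match through N because the site is pure ACGT
    out = []
    i = seq.find(site)
    while i != -1:
        out.append(i)
        i = seq.find(site, i + 1)
    return out


# --- BED I/O -----------------------------------------------------------------

_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6; track/browser/comment lines are ignored.

    A record whose start is not strictly below its end is rejected with its
    line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"line {lineno}: expected >= 3 fields")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedFormatError(f"line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise BedFormatError(
                    f"line {lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                fields.append(_fmt_score(iv.score) if iv.score is not None else ".")
            if iv.strand is not None:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def _fmt_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(score)
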