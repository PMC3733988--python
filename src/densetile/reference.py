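"""Reference sequence handling and repeat-aware segmentation.

A target region of a reference genome is partitioned into *unique
segments*: maximal stretches of unmasked sequence separated by
repeat-masked gaps.  Probes are later tiled to these segments, so each
segment carries the geometry of its flanking masked gaps (distance
across the gap, plus a summary of the repeats inside it: the class of
the longest repeat and the combined length of all repeats).

Coordinates are 0-based half-open throughout; emitted BED files follow
the BED convention, and human-readable reports additionally show
1-based inclusive positions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Six-way repeat grouping: long/short interspersed nuclear elements,
#: long terminal repeats, simple repeats, low-complexity sequence and a
#: catch-all for everything else.
REPEAT_CLASSES = ("LINE", "SINE", "LTR", "Simple", "LC", "Other")

# RepeatMasker class/family prefixes -> six-way grouping
_CLASS_MAP = {
    "LINE": "LINE",
    "SINE": "SINE",
    "LTR": "LTR",
    "Simple_repeat": "Simple",
    "Simple": "Simple",
    "Low_complexity": "LC",
    "LC": "LC",
}

MASK_DIALECTS = ("repeatmasker_out", "bed", "softmask")


@dataclass(frozen=True)
class ReferenceRegion:
    """A contiguous slice of a reference chromosome.

    ``start``/``end`` are 0-based half-open positions on the chromosome;
    ``sequence`` is the corresponding nucleotide string with case
    preserved (lowercase marks soft-masked bases).
    """

    chrom: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"sequence length {len(self.sequence)} != interval length "
                f"{self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatInterval:
    """A single repeat annotation, in region-relative coordinates."""

    start: int
    end: int
    repeat_class: str = "Other"
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty repeat interval ({self.start}, {self.end})")
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FlankSummary:
    """Summary of the repeats inside one masked gap.

    ``repeat_class`` is the class of the longest single repeat in the
    gap; ``combined_length`` is the summed length of all (unmerged)
    repeats recorded in the gap.
    """

    repeat_class: str
    combined_length: int


@dataclass
class UniqueSegment:
    """A maximal unmasked interval, with flanking-gap geometry.

    ``left_gap``/``right_gap`` give the distance in bp across the masked
    region to the adjacent segment, or to the region edge for terminal
    segments.  Interior gaps additionally carry a :class:`FlankSummary`;
    gaps that touch the region boundary do not.
    """

    id: int
    start: int
    end: int
    left_gap: int = 0
    right_gap: int = 0
    left_repeat: FlankSummary | None = None
    right_repeat: FlankSummary | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def map_repeat_class(label: str) -> str:
    """Map a RepeatMasker class/family label onto the six-way grouping.

    The part before the first ``/`` is looked up (``LINE/L1`` -> LINE);
    unknown prefixes fall back to ``Other`` with a logged warning.
    """
    prefix = label.split("/", 1)[0]
    cls = _CLASS_MAP.get(prefix)
    if cls is None:
        logger.warning("unknown repeat class label %r mapped to Other", label)
        return "Other"
    return cls


def load_region(fasta_path: str | Path, chrom: str, start: int, end: int) -> ReferenceRegion:
    """Extract ``chrom:start-end`` (0-based half-open) from a FASTA file."""
    from pyfaidx import Fasta

    if start >= end:
        raise ValueError(f"empty or inverted interval ({start}, {end})")
    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=False)
    try:
        if chrom not in fa:
            raise KeyError(
                f"chromosome {chrom!r} not present in {fasta_path} "
                f"(available: {', '.join(list(fa.keys())[:5])}...)"
            )
        chrom_len = len(fa[chrom])
        if start < 0 or end > chrom_len:
            raise ValueError(
                f"interval ({start}, {end}) out of bounds for {chrom} "
                f"of length {chrom_len}"
            )
        seq = str(fa[chrom][start:end])
    finally:
        fa.close()
    return ReferenceRegion(chrom=chrom, start=start, end=end, sequence=seq)


def _clip(start: int, end: int, region_length: int) -> tuple[int, int] | None:
    s, e = max(start, 0), min(end, region_length)
    if s >= e:
        return None
    return s, e


def _parse_repeatmasker_out(path: Path, region: ReferenceRegion) -> list[RepeatInterval]:
    out: list[RepeatInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            # standard header: two ruler lines then a blank line
            if stripped.startswith(("SW", "score", "bit")):
                continue
            fields = stripped.split()
            if len(fields) < 11:
                raise ValueError(
                    f"{path}:{lineno}: unparseable RepeatMasker line "
                    f"({len(fields)} fields): {stripped[:80]}"
                )
            try:
                qname = fields[4]
                qbegin = int(fields[5])  # 1-based inclusive
                qend = int(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates: {stripped[:80]}") from exc
            if qname != region.chrom:
                continue
            clipped = _clip(qbegin - 1 - region.start, qend - region.start, region.length)
            if clipped is None:
                continue
            out.append(
                RepeatInterval(
                    start=clipped[0],
                    end=clipped[1],
                    repeat_class=map_repeat_class(fields[10]),
                    name=fields[9],
                )
            )
    return out


def _parse_bed(path: Path, region: ReferenceRegion) -> list[RepeatInterval]:
    out: list[RepeatInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split("\t") if "\t" in stripped else stripped.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED record needs >=3 fields")
            try:
                chrom, bstart, bend = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad BED coordinates") from exc
            if chrom != region.chrom:
                continue
            clipped = _clip(bstart - region.start, bend - region.start, region.length)
            if clipped is None:
                continue
            name = fields[3] if len(fields) > 3 else ""
            # class either from the name (RepeatMasker-style label) or Other
            cls = map_repeat_class(name) if name else "Other"
            out.append(RepeatInterval(start=clipped[0], end=clipped[1], repeat_class=cls, name=name))
    return out


def _softmask_intervals(region: ReferenceRegion) -> list[RepeatInterval]:
    out = []
    for m in re.finditer(r"[acgtn]+", region.sequence):
        out.append(RepeatInterval(start=m.start(), end=m.end(), repeat_class="Other", name="softmask"))
    return out


def load_masks(
    path: str | Path | None,
    region: ReferenceRegion,
    dialect: str = "bed",
) -> list[RepeatInterval]:
    """Read repeat annotations for ``region``.

    ``dialect`` is one of ``repeatmasker_out`` (RepeatMasker ``.out``),
    ``bed`` (BED3/BED6, name column optionally a RepeatMasker-style
    class label), or ``softmask`` (lowercase runs in the region sequence
    itself; ``path`` is ignored).

    Intervals are clipped to the region, returned sorted, and *not*
    merged: overlapping or bookended repeats are kept individually so
    that per-repeat metadata survives for the flank summaries.
    """
    if dialect not in MASK_DIALECTS:
        raise ValueError(f"unknown mask dialect {dialect!r}; expected one of {MASK_DIALECTS}")
    if dialect == "softmask":
        masks = _softmask_intervals(region)
    elif dialect == "repeatmasker_out":
        masks = _parse_repeatmasker_out(Path(path), region)
    else:
        masks = _parse_bed(Path(path), region)
    return sorted(masks, key=lambda r: (r.start, r.end))


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or bookended half-open intervals."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _gap_summary(gap: tuple[int, int], masks: Sequence[RepeatInterval]) -> FlankSummary | None:
    inside = [m for m in masks if m.start < gap[1] and m.end > gap[0]]
    if not inside:
        return None
    longest = max(inside, key=lambda m: m.length)
    return FlankSummary(
        repeat_class=longest.repeat_class,
        combined_length=sum(m.length for m in inside),
    )


def segment_region(region: ReferenceRegion, masks: Sequence[RepeatInterval]) -> list[UniqueSegment]:
    """Partition ``region`` into unique segments (complement of the masks).

    Masked intervals are merged for the complement arithmetic, but the
    flank summary of each interior gap is computed from the unmerged
    repeats inside it (class of the longest; combined length of all).
    Terminal gaps — masked runs touching a region boundary — contribute
    to ``left_gap``/``right_gap`` but carry no repeat summary.  A fully
    masked region yields an empty list.
    """
    merged = merge_intervals((m.start, m.end) for m in masks)
    # complement of the merged mask union
    segments: list[tuple[int, int]] = []
    cursor = 0
    for s, e in merged:
        if s > cursor:
            segments.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < region.length:
        segments.append((cursor, region.length))

    out: list[UniqueSegment] = []
    n = len(segments)
    for i, (s, e) in enumerate(segments):
        left_edge = segments[i - 1][1] if i > 0 else 0
        right_edge = segments[i + 1][0] if i < n - 1 else region.length
        left_gap = s - left_edge
        right_gap = right_edge - e
        left_sum = _gap_summary((left_edge, s), masks) if i > 0 and left_gap > 0 else None
        right_sum = _gap_summary((e, right_edge), masks) if i < n - 1 and right_gap > 0 else None
        out.append(
            UniqueSegment(
                id=i,
                start=s,
                end=e,
                left_gap=left_gap,
                right_gap=right_gap,
                left_repeat=left_sum,
                right_repeat=right_sum,
            )
        )
    return out
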