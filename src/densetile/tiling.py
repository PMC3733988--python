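"""Fixed-length probe tiling over unique segments.

Probes of a fixed length (60-mers by default) are tiled on an
arithmetic grid of candidate start positions, with the grid step
("tiling path offset") set per *zone* of the target region — the
default study layout uses a densely tiled central zone (6 bp offset)
flanked by two 26 bp offset zones.  Any candidate probe that extends
into a repeat-masked region is discarded, so probes only ever lie fully
inside unique segments.

Design-geometry annotation follows the competitive-hybridization
covariates: per-segment probe *position* (a symmetric index increasing
toward the segment centre), edge flags, and *distance* (the width of
the masked gap adjacent to an edge probe).  Within the densest zone the
outermost 5' probe of each segment long enough to reach maximum
per-base coverage is replicated four additional times, providing
within-array replicates for repeatability analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .reference import ReferenceRegion, UniqueSegment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Zone:
    """A half-open interval of the region tiled at one offset."""

    start: int
    end: int
    offset: int

    def __post_init__(self) -> None:
        if self.offset < 1:
            raise ValueError(f"offset must be >= 1, got {self.offset}")
        if self.start >= self.end:
            raise ValueError(f"empty zone ({self.start}, {self.end})")


@dataclass
class TilingPlan:
    """Parameters of a tiling design.

    ``anchor`` chooses the candidate grid origin: ``"global"`` anchors
    the grid at each zone's start (the region is tiled as a continuous
    string, so a segment's probe count depends on its phase relative to
    the grid), while ``"per-segment"`` restarts the grid at every
    segment start (maximising each segment's probe count).

    In the zone whose offset equals ``replicate_offset``, the 5'-most
    probe of every segment at least
    :func:`min_segment_length_for_max_coverage` bp long is printed
    ``1 + replicate_copies`` times.
    """

    zones: Sequence[Zone]
    probe_length: int = 60
    anchor: str = "global"
    replicate_offset: int = 6
    replicate_copies: int = 4

    def __post_init__(self) -> None:
        if self.probe_length < 1:
            raise ValueError("probe_length must be positive")
        if self.anchor not in ("global", "per-segment"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        zones = sorted(self.zones, key=lambda z: z.start)
        for a, b in zip(zones, zones[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping zones {a} and {b}")
        self.zones = list(zones)


@dataclass
class Probe:
    """A single designed oligo with geometry annotation.

    ``position`` counts 1, 2, 3, ... inward symmetrically from both
    segment ends; ``distance`` is defined only for edge probes and gives
    the width of the adjacent masked gap.
    """

    id: str
    start: int
    end: int
    sequence: str
    offset: int
    segment_id: int
    segment_length: int = 0
    position: int = 0
    is_edge_5p: bool = False
    is_edge_3p: bool = False
    distance: int | None = None
    replicate_count: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ProbeSet:
    """An ordered collection of probes with their plan and region."""

    plan: TilingPlan
    probes: list[Probe]
    region: ReferenceRegion

    def __len__(self) -> int:
        return len(self.probes)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "probe_id": p.id,
                "start": p.start,
                "end": p.end,
                "sequence": p.sequence,
                "offset": p.offset,
                "segment_id": p.segment_id,
                "segment_length": p.segment_length,
                "position": p.position,
                "is_edge_5p": p.is_edge_5p,
                "is_edge_3p": p.is_edge_3p,
                "distance": p.distance,
                "replicate_count": p.replicate_count,
            }
            for p in self.probes
        ]
        return pd.DataFrame(rows)

    def coverage_fraction(self) -> float:
        """Fraction of region bases under at least one probe."""
        covered = np.zeros(self.region.length, dtype=bool)
        for p in self.probes:
            covered[p.start : p.end] = True
        return float(covered.mean())

    def zone_summary(self) -> pd.DataFrame:
        """Per-offset probe counts and coverage fractions."""
        rows = []
        for zone in self.plan.zones:
            in_zone = [p for p in self.probes if zone.start <= p.start < zone.end]
            covered = np.zeros(zone.end - zone.start, dtype=bool)
            for p in in_zone:
                covered[max(p.start - zone.start, 0) : p.end - zone.start] = True
            rows.append(
                {
                    "zone_start": zone.start,
                    "zone_end": zone.end,
                    "offset": zone.offset,
                    "n_probes": len(in_zone),
                    "n_replicated": sum(p.replicate_count > 1 for p in in_zone),
                    "coverage_fraction": float(covered.mean()),
                }
            )
        return pd.DataFrame(rows)


def min_segment_length_for_max_coverage(probe_length: int, offset: int) -> int:
    """Shortest segment in which some base reaches maximum probe coverage.

    At offset ``o`` and probe length ``p`` the maximum possible per-base
    coverage is ``ceil(p / o)`` probes; the shortest segment where a
    base attains it is ``p + (ceil(p / o) - 1) * o``.  When the offset
    exceeds the probe length, maximum coverage is one probe and the
    answer is the probe length itself.
    """
    if probe_length < 1 or offset < 1:
        raise ValueError("probe_length and offset must be positive")
    if offset > probe_length:
        return probe_length
    max_cov = math.ceil(probe_length / offset)
    return probe_length + (max_cov - 1) * offset


def probe_count_bounds(segment_length: int, probe_length: int, offset: int) -> tuple[int, int]:
    """(min, max) over grid phases of the probe count in a segment.

    On a global grid, the number of fully contained probes in a segment
    of length ``L`` depends on the segment's phase relative to the grid:
    the maximum is ``floor((L - p) / o) + 1`` and the minimum is
    ``floor((L - p - o + 1) / o) + 1`` (clamped at zero).  Segments
    shorter than the probe hold no probes.
    """
    if offset < 1 or probe_length < 1:
        raise ValueError("probe_length and offset must be positive")
    if segment_length < probe_length:
        return (0, 0)
    lo = max(0, (segment_length - probe_length - offset + 1) // offset + 1)
    hi = (segment_length - probe_length) // offset + 1
    return (lo, hi)


def _candidate_starts(plan: TilingPlan, segments: Sequence[UniqueSegment]) -> list[tuple[int, Zone]]:
    """All candidate (start, zone) pairs under the plan's anchoring."""
    out: list[tuple[int, Zone]] = []
    if plan.anchor == "global":
        for zone in plan.zones:
            for s in range(zone.start, zone.end, zone.offset):
                out.append((s, zone))
    else:  # per-segment
        for seg in segments:
            for zone in plan.zones:
                lo = max(seg.start, zone.start)
                if lo >= zone.end:
                    continue
                for s in range(lo, min(zone.end, seg.end), zone.offset):
                    out.append((s, zone))
    return out


def tile(region: ReferenceRegion, segments: Sequence[UniqueSegment], plan: TilingPlan) -> ProbeSet:
    """Tile probes over unique segments, annotate geometry, apply replication.

    A candidate start is kept iff the full probe interval lies inside a
    unique segment (a probe extending into a masked region is
    discarded).  Probes are assigned to the zone containing their start.
    """
    if segments and plan.probe_length > max(s.length for s in segments):
        logger.warning(
            "probe length %d exceeds the longest unique segment (%d bp); no probes tiled",
            plan.probe_length,
            max(s.length for s in segments),
        )
    seg_starts = np.array([s.start for s in segments], dtype=np.int64)
    seg_ends = np.array([s.end for s in segments], dtype=np.int64)
    p = plan.probe_length

    probes: list[Probe] = []
    seen: set[int] = set()
    for s, zone in _candidate_starts(plan, segments):
        if s in seen:
            continue
        if len(seg_starts) == 0:
            break
        i = int(np.searchsorted(seg_starts, s, side="right")) - 1
        if i < 0:
            continue
        if s >= seg_starts[i] and s + p <= seg_ends[i]:
            seen.add(s)
            gstart = region.start + s
            probes.append(
                Probe(
                    id=f"{region.chrom}:{gstart}-{gstart + p}",
                    start=s,
                    end=s + p,
                    sequence=region.sequence[s : s + p].upper(),
                    offset=zone.offset,
                    segment_id=segments[i].id,
                    segment_length=segments[i].length,
                )
            )
    probes.sort(key=lambda pr: pr.start)
    pset = ProbeSet(plan=plan, probes=probes, region=region)
    annotate_geometry(pset, segments)
    select_replicates(pset, plan)
    return pset


def annotate_geometry(probeset: ProbeSet, segments: Sequence[UniqueSegment]) -> ProbeSet:
    """Assign position, edge flags and edge distances, in place.

    Within a segment of ``n`` probes the k-th probe (k = 1..n) gets
    position ``min(k, n - k + 1)``, so positions rise symmetrically
    toward the centre.  The first probe is the 5' edge (distance = left
    gap), the last the 3' edge (distance = right gap); a single-probe
    segment is both edges and takes the larger gap.
    """
    by_segment: dict[int, list[Probe]] = {}
    for p in probeset.probes:
        by_segment.setdefault(p.segment_id, []).append(p)
    seg_by_id = {s.id: s for s in segments}
    for seg_id, plist in by_segment.items():
        plist.sort(key=lambda p: p.start)
        n = len(plist)
        seg = seg_by_id[seg_id]
        for k, probe in enumerate(plist, start=1):
            probe.position = min(k, n - k + 1)
            probe.is_edge_5p = k == 1
            probe.is_edge_3p = k == n
            if probe.is_edge_5p and probe.is_edge_3p:
                probe.distance = max(seg.left_gap, seg.right_gap)
            elif probe.is_edge_5p:
                probe.distance = seg.left_gap
            elif probe.is_edge_3p:
                probe.distance = seg.right_gap
            else:
                probe.distance = None
    return probeset


def select_replicates(probeset: ProbeSet, plan: TilingPlan | None = None) -> ProbeSet:
    """Apply the replicate rule in place.

    Only in the zone tiled at ``replicate_offset``: for each segment at
    least ``min_segment_length_for_max_coverage(probe_length,
    replicate_offset)`` bp long, the 5'-most probe is printed
    ``1 + replicate_copies`` times; every other probe once.
    """
    plan = plan or probeset.plan
    threshold = min_segment_length_for_max_coverage(plan.probe_length, plan.replicate_offset)
    by_segment: dict[int, list[Probe]] = {}
    for p in probeset.probes:
        p.replicate_count = 1
        if p.offset == plan.replicate_offset:
            by_segment.setdefault(p.segment_id, []).append(p)
    for plist in by_segment.values():
        first = min(plist, key=lambda p: p.start)
        if first.segment_length >= threshold:
            first.replicate_count = 1 + plan.replicate_copies
    return probeset


def select_repeat_adjacent_probes(
    probeset: ProbeSet,
    segments: Sequence[UniqueSegment],
    n_per_side: dict[int, int] | None = None,
    default_n: int = 2,
) -> pd.DataFrame:
    """Probes flanking each interior masked gap, with repeat covariates.

    For every masked gap between two segments, the nearest probes on
    each side are selected — by default four per side in 6 bp offset
    zones and two per side in 26 bp zones (the count is looked up from
    the offset of the probe nearest the gap on that side).  Each
    selected probe carries the gap's ``repeat_class`` (class of the
    longest repeat in the gap) and ``repeat_length`` (combined length of
    all repeats in the gap).  Gaps at the region boundary carry no
    repeat summary and contribute no probes.  A probe flanking two gaps
    is assigned to the nearer one.
    """
    if n_per_side is None:
        n_per_side = {6: 4, 26: 2}
    by_segment: dict[int, list[Probe]] = {}
    for p in probeset.probes:
        by_segment.setdefault(p.segment_id, []).append(p)
    for plist in by_segment.values():
        plist.sort(key=lambda p: p.start)

    ordered = sorted(segments, key=lambda s: s.start)
    rows: list[dict] = []
    for left_seg, right_seg in zip(ordered, ordered[1:]):
        summary = right_seg.left_repeat  # == left_seg.right_repeat
        if summary is None:
            continue
        gap = (left_seg.end, right_seg.start)
        # nearest probes to the gap: tail of the left segment, head of the right
        for side, plist, nearest_first in (
            ("left", by_segment.get(left_seg.id, []), False),
            ("right", by_segment.get(right_seg.id, []), True),
        ):
            if not plist:
                continue
            ordered_probes = plist if nearest_first else list(reversed(plist))
            k = n_per_side.get(ordered_probes[0].offset, default_n)
            for probe in ordered_probes[:k]:
                dist_to_gap = (gap[0] - probe.end) if side == "left" else (probe.start - gap[1])
                rows.append(
                    {
                        "probe_id": probe.id,
                        "segment_id": probe.segment_id,
                        "side": side,
                        "gap_start": gap[0],
                        "gap_end": gap[1],
                        "distance_to_gap": abs(dist_to_gap),
                        "repeat_class": summary.repeat_class,
                        "repeat_length": summary.combined_length,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "segment_id",
            "side",
            "gap_start",
            "gap_end",
            "distance_to_gap",
            "repeat_class",
            "repeat_length",
        ],
    )
    if df.empty:
        return df
    # a probe adjacent to gaps on both sides keeps its nearer gap
    df = df.sort_values(["probe_id", "distance_to_gap"]).drop_duplicates("probe_id", keep="first")
    return df.sort_values(["gap_start", "side", "probe_id"]).reset_index(drop=True)
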