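"""Plain-text writers for the pipeline's interchange files.

Everything is emitted as FASTA, BED or TSV with documented headers;
BED records use genomic (chromosome-level) 0-based half-open
coordinates, and TSV reports additionally include 1-based inclusive
positions for browser-style inspection.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

from .reference import ReferenceRegion, RepeatInterval, UniqueSegment
from .tiling import ProbeSet

_WRAP = 60


def write_region_fasta(region: ReferenceRegion, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{region.chrom}\n")
        pad = "N" * region.start  # keep chromosome coordinates addressable
        seq = pad + region.sequence
        for i in range(0, len(seq), _WRAP):
            fh.write(seq[i : i + _WRAP] + "\n")


def write_region_fasta_local(region: ReferenceRegion, path: str | Path) -> None:
    """FASTA of the region sequence alone (region-relative coordinates)."""
    with open(path, "w") as fh:
        fh.write(f">{region.chrom}:{region.start}-{region.end}\n")
        for i in range(0, len(region.sequence), _WRAP):
            fh.write(region.sequence[i : i + _WRAP] + "\n")


def write_masks_bed(
    masks: Sequence[RepeatInterval], region: ReferenceRegion, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for m in masks:
            name = m.name or m.repeat_class
            fh.write(
                f"{region.chrom}\t{region.start + m.start}\t{region.start + m.end}"
                f"\t{name}\t{m.length}\t+\n"
            )


def write_segments_bed(
    segments: Sequence[UniqueSegment], region: ReferenceRegion, path: str | Path
) -> None:
    """Segments as BED6: name = segment id, score = length."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"{region.chrom}\t{region.start + s.start}\t{region.start + s.end}"
                f"\tseg{s.id}\t{s.length}\t+\n"
            )


def write_segments_tsv(
    segments: Sequence[UniqueSegment], region: ReferenceRegion, path: str | Path
) -> None:
    cols = [
        "segment_id", "chrom", "start", "end", "start_1based", "end_1based", "length",
        "left_gap", "right_gap", "left_repeat_class", "left_repeat_length",
        "right_repeat_class", "right_repeat_length",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in segments:
            gs, ge = region.start + s.start, region.start + s.end
            lrc = s.left_repeat.repeat_class if s.left_repeat else ""
            lrl = s.left_repeat.combined_length if s.left_repeat else ""
            rrc = s.right_repeat.repeat_class if s.right_repeat else ""
            rrl = s.right_repeat.combined_length if s.right_repeat else ""
            fh.write(
                f"{s.id}\t{region.chrom}\t{gs}\t{ge}\t{gs + 1}\t{ge}\t{s.length}"
                f"\t{s.left_gap}\t{s.right_gap}\t{lrc}\t{lrl}\t{rrc}\t{rrl}\n"
            )


def read_segments_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return out


def write_probes_bed(probeset: ProbeSet, path: str | Path) -> None:
    """Probes as BED6: name = probe id, score = replicate count."""
    region = probeset.region
    with open(path, "w") as fh:
        for p in probeset.probes:
            fh.write(
                f"{region.chrom}\t{region.start + p.start}\t{region.start + p.end}"
                f"\t{p.id}\t{p.replicate_count}\t+\n"
            )


def write_probes_fasta(probeset: ProbeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probeset.probes:
            fh.write(f">{p.id}\n{p.sequence}\n")


def file_checksum(path: str | Path) -> str:
    digest = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_provenance(
    outdir: str | Path,
    stage: str,
    params: dict,
    inputs: Iterable[str | Path] = (),
    seed: int | None = None,
) -> Path:
    """Record the stage, parameters, seed and input checksums as JSON."""
    from . import __version__

    record = {
        "tool": "densetile",
        "version": __version__,
        "stage": stage,
        "seed": seed,
        "params": params,
        "inputs": {str(p): file_checksum(p) for p in inputs if Path(p).is_file()},
    }
    path = Path(outdir) / "provenance.json"
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1)
    return path
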