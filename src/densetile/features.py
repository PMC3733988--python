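"""Per-probe sequence covariates.

For each designed probe: GC percentage, the longest homopolymer run of
each base, and the genome-wide off-target count of its constituent
k-mers (25-mers by default) against a k-mer count index of the
reference.  Self-folding free energy (kcal/mol, e.g. from UNAFold at
the hybridization temperature) is accepted as an external input column
and never computed here.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID = re.compile(r"^[ACGT]+$")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(sequence: str) -> float:
    """Percentage of G and C bases, to two decimals.

    Raises on any character outside ACGT (uppercase).
    """
    if not _VALID.match(sequence):
        raise ValueError(f"sequence contains non-ACGT characters: {sequence[:40]!r}...")
    gc = sequence.count("G") + sequence.count("C")
    return round(100.0 * gc / len(sequence), 2)


def homopolymer_lengths(sequence: str) -> tuple[int, int, int, int]:
    """Longest run of A, C, G and T respectively (0 if the base is absent)."""
    best = {"A": 0, "C": 0, "G": 0, "T": 0}
    prev = ""
    run = 0
    for ch in sequence:
        if ch == prev:
            run += 1
        else:
            prev, run = ch, 1
        if ch in best and run > best[ch]:
            best[ch] = run
    return (best["A"], best["C"], best["G"], best["T"])


@dataclass
class KmerCountIndex:
    """Occurrence counts of every k-mer in a reference.

    With ``canonical`` pooling a k-mer and its reverse complement share
    one count (hybridization is strand-agnostic); non-canonical mode
    counts each strand's words separately.  Windows containing a non-
    ACGT character are skipped.
    """

    k: int
    counts: dict[str, int]
    canonical: bool = True
    source: str = ""

    def lookup(self, kmer: str) -> int:
        if self.canonical:
            rc = reverse_complement(kmer)
            if rc < kmer:
                kmer = rc
        return self.counts.get(kmer, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\tcanonical={int(self.canonical)}\tsource={self.source}\n")
            for kmer in sorted(self.counts):
                fh.write(f"{kmer}\t{self.counts[kmer]}\n")

    @classmethod
    def load(cls, path: str | Path) -> "KmerCountIndex":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#k="):
                raise ValueError(f"{path}: missing k-mer index header")
            fields = dict(item.split("=", 1) for item in header.lstrip("#").split("\t"))
            counts: dict[str, int] = {}
            for line in fh:
                kmer, cnt = line.split("\t")
                counts[kmer] = int(cnt)
        return cls(
            k=int(fields["k"]),
            counts=counts,
            canonical=bool(int(fields.get("canonical", "1"))),
            source=fields.get("source", ""),
        )


def _iter_sequences(source) -> Iterable[tuple[str, str]]:
    """Yield (name, sequence) from a FASTA path, mapping, or region-like."""
    if isinstance(source, (str, Path)):
        name, chunks = None, []
        with open(source) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if name is not None:
                        yield name, "".join(chunks)
                    name, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
        if name is not None:
            yield name, "".join(chunks)
    elif isinstance(source, Mapping):
        yield from source.items()
    elif hasattr(source, "sequence"):  # ReferenceRegion-like
        yield getattr(source, "chrom", "region"), source.sequence
    else:
        raise TypeError(f"cannot read sequences from {type(source).__name__}")


def build_kmer_index(source, k: int = 25, canonical: bool = True) -> KmerCountIndex:
    """Count every length-``k`` ACGT window of the reference.

    ``source`` may be a FASTA path, a mapping of name -> sequence, or a
    region object with a ``sequence`` attribute.  Case is ignored
    (soft-masked bases are counted); windows containing N are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    digest = hashlib.md5()
    names = []
    for name, seq in _iter_sequences(source):
        names.append(name)
        seq = seq.upper()
        digest.update(seq.encode())
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if not _VALID.match(kmer):
                continue
            if canonical:
                rc = reverse_complement(kmer)
                if rc < kmer:
                    kmer = rc
            counts[kmer] = counts.get(kmer, 0) + 1
    return KmerCountIndex(
        k=k,
        counts=counts,
        canonical=canonical,
        source=f"{','.join(names)}:{digest.hexdigest()[:12]}",
    )


def off_target_matches(probe_sequence: str, index: KmerCountIndex) -> int:
    """Genome-wide off-target count of all k-mers within a probe.

    Sums, over every length-k window of the probe, the window's index
    count minus one — the subtracted one being the window's own
    occurrence at the probe locus.  Requires the index to have been
    built over the reference that contains the probe; a window absent
    from the index indicates an inconsistent reference and raises.
    """
    k = index.k
    if len(probe_sequence) < k:
        raise ValueError(f"probe shorter than k={k}")
    probe_sequence = probe_sequence.upper()
    total = 0
    for i in range(len(probe_sequence) - k + 1):
        window = probe_sequence[i : i + k]
        cnt = index.lookup(window)
        if cnt == 0:
            raise ValueError(
                f"probe window {window} absent from the k-mer index; "
                "was the index built over the reference containing this probe?"
            )
        total += max(0, cnt - 1)
    return total


def compute_features(
    probes: pd.DataFrame | Iterable,
    index: KmerCountIndex | None = None,
    free_energy: pd.DataFrame | Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Feature table for a set of probes.

    ``probes`` is a DataFrame with ``probe_id`` and ``sequence`` columns
    (e.g. ``ProbeSet.to_dataframe()``) or an iterable of objects with
    ``id`` and ``sequence``.  ``free_energy`` maps probe_id -> ΔG
    (kcal/mol); probes without a value get NaN.
    """
    if isinstance(probes, pd.DataFrame):
        items = list(zip(probes["probe_id"], probes["sequence"]))
    else:
        items = [(p.id, p.sequence) for p in probes]
    dg: Mapping[str, float] = {}
    if free_energy is not None:
        if isinstance(free_energy, pd.DataFrame):
            dg = dict(zip(free_energy["probe_id"], free_energy["free_energy"]))
        else:
            dg = dict(free_energy)
    rows = []
    for pid, seq in items:
        pa, pc, pg, pt = homopolymer_lengths(seq)
        rows.append(
            {
                "probe_id": pid,
                "gc_percent": gc_percent(seq),
                "poly_a": pa,
                "poly_c": pc,
                "poly_g": pg,
                "poly_t": pt,
                "off_target_matches": off_target_matches(seq, index) if index else 0,
                "free_energy": dg.get(pid, float("nan")),
            }
        )
    return pd.DataFrame(rows)


def load_free_energy(path: str | Path) -> pd.DataFrame:
    """Read a probe_id / free-energy TSV (UNAFold-compatible)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "probe_id" not in cols or not any(c in cols for c in ("free_energy", "dg")):
        raise ValueError(f"{path}: expected columns probe_id and free_energy/dG")
    dg_col = cols.get("free_energy", cols.get("dg"))
    return df.rename(columns={cols["probe_id"]: "probe_id", dg_col: "free_energy"})[
        ["probe_id", "free_energy"]
    ]
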