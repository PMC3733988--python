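"""Single-channel intensity data model, probe filtering and deletion controls.

The raw datum is the median signal of one probe feature on one array
(44–65,530 on the study scanner), with a per-feature background value.
Filtering removes a probe globally — from every array — when on any
single array its signal exceeds that array's positive-control median,
falls below the negative-control median, or its background exceeds a
cutoff (50 by default); probes inside supplied copy-number-variant
regions are removed as well, so the retained probe set is identical
across arrays.

Deletion stringency control probes (DCP) carry 0–8 bases deleted from
the probe centre; their retention curve (mean signal as a percentage of
the non-deleted parent mean) gauges hybridization of imperfect
duplexes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DNA_SOURCES = ("blood", "saliva")
SATURATION_CEILING = 65_530

_PROBE_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)")


@dataclass(frozen=True)
class ArraySample:
    """One hybridized array: the dog it came from and the DNA source."""

    array_id: str
    dog_id: str
    dna_source: str

    def __post_init__(self) -> None:
        if self.dna_source not in DNA_SOURCES:
            raise ValueError(f"dna_source must be one of {DNA_SOURCES}, got {self.dna_source!r}")


@dataclass
class IntensityMatrix:
    """Probe-by-array raw median signals and backgrounds.

    ``signal`` and ``background`` are DataFrames indexed by probe id
    with one column per array id; ``samples`` describes the arrays.
    Replicated probe features carry ids of the form ``<probe_id>#<k>``
    for the extra copies (the first copy keeps the plain probe id).
    """

    signal: pd.DataFrame
    background: pd.DataFrame
    samples: list[ArraySample]

    @property
    def array_ids(self) -> list[str]:
        return list(self.signal.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.signal.index)

    def sample(self, array_id: str) -> ArraySample:
        for s in self.samples:
            if s.array_id == array_id:
                return s
        raise KeyError(array_id)

    def to_long(self, include_replicates: bool = True) -> pd.DataFrame:
        """Long format: probe_id, array_id, raw_signal, background."""
        sig = self.signal.stack().rename("raw_signal")
        bg = self.background.stack().rename("background")
        df = pd.concat([sig, bg], axis=1).reset_index()
        df.columns = ["probe_id", "array_id", "raw_signal", "background"]
        if not include_replicates:
            df = df[~df["probe_id"].str.contains("#")]
        return df.reset_index(drop=True)


@dataclass
class ControlSet:
    """Control-feature intensities, held long-format.

    ``data`` has columns probe_id, array_id, control_type, deletion_count
    (NaN except for DCP rows), raw_signal.
    """

    data: pd.DataFrame

    def positive(self, array_id: str) -> np.ndarray:
        return self._select("pos", array_id)

    def negative(self, array_id: str) -> np.ndarray:
        return self._select("neg", array_id)

    def _select(self, ctype: str, array_id: str) -> np.ndarray:
        mask = (self.data["control_type"] == ctype) & (self.data["array_id"] == array_id)
        return self.data.loc[mask, "raw_signal"].to_numpy()

    def dcp(self, array_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """DCP rows (optionally restricted to a subset of arrays)."""
        df = self.data[self.data["control_type"] == "dcp"]
        if array_ids is not None:
            df = df[df["array_id"].isin(array_ids)]
        return df


@dataclass
class FilterReport:
    """Accounting of the probe-filtering rules.

    Each removed probe is attributed to the first rule it fails, in the
    order: above positive-control median, below negative-control
    median, background cutoff, CNV region.  ``n_retained`` equals the
    input count minus the size of the union of all removals.
    """

    n_input: int
    n_removed_high: int
    n_removed_low: int
    n_removed_background: int
    n_removed_cnv: int
    n_retained: int
    removed_high: list[str] = field(default_factory=list)
    removed_low: list[str] = field(default_factory=list)
    removed_background: list[str] = field(default_factory=list)
    removed_cnv: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def _parse_control_type(value: str) -> tuple[str, float]:
    if value == "none":
        return "none", float("nan")
    if value in ("pos", "neg"):
        return value, float("nan")
    if value.startswith("dcp:"):
        n = int(value.split(":", 1)[1])
        if not 0 <= n <= 8:
            raise ValueError(f"DCP deletion count out of range 0..8: {value!r}")
        return "dcp", float(n)
    raise ValueError(f"unknown control_type {value!r}")


def load_intensities(
    intensity_tsv: str | Path, samples_tsv: str | Path
) -> tuple[IntensityMatrix, ControlSet]:
    """Read a feature-extraction-style intensity table and sample sheet.

    The intensity TSV needs columns probe_id, array_id, control_type
    (``none``, ``pos``, ``neg`` or ``dcp:<n>`` with n in 0..8),
    raw_signal and background; the sample sheet needs array_id, dog_id
    and dna_source.  Duplicate (probe, array) rows among non-control
    features are rejected.
    """
    df = pd.read_csv(intensity_tsv, sep="\t", dtype={"probe_id": str, "array_id": str})
    required = {"probe_id", "array_id", "control_type", "raw_signal", "background"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{intensity_tsv}: missing columns {sorted(missing)}")
    sheet = pd.read_csv(samples_tsv, sep="\t", dtype=str)
    missing = {"array_id", "dog_id", "dna_source"} - set(sheet.columns)
    if missing:
        raise ValueError(f"{samples_tsv}: missing columns {sorted(missing)}")
    return matrix_from_frames(df, sheet)


def matrix_from_frames(
    df: pd.DataFrame, sheet: pd.DataFrame
) -> tuple[IntensityMatrix, ControlSet]:
    """Build an IntensityMatrix + ControlSet from in-memory frames.

    Same schema as :func:`load_intensities`.
    """
    df = df.copy()
    parsed = df["control_type"].map(_parse_control_type)
    df["ctype"] = [p[0] for p in parsed]
    df["deletion_count"] = [p[1] for p in parsed]

    samples = [
        ArraySample(str(r.array_id), str(r.dog_id), str(r.dna_source))
        for r in sheet.itertuples(index=False)
    ]

    feats = df[df["ctype"] == "none"]
    dup = feats.duplicated(["probe_id", "array_id"])
    if dup.any():
        first = feats[dup].iloc[0]
        raise ValueError(
            f"duplicate (probe, array) row: {first['probe_id']} on {first['array_id']}"
        )
    signal = feats.pivot(index="probe_id", columns="array_id", values="raw_signal")
    background = feats.pivot(index="probe_id", columns="array_id", values="background")
    matrix = IntensityMatrix(signal=signal, background=background, samples=samples)

    controls = df[df["ctype"] != "none"][
        ["probe_id", "array_id", "ctype", "deletion_count", "raw_signal"]
    ].rename(columns={"ctype": "control_type"})
    return matrix, ControlSet(data=controls.reset_index(drop=True))


def parse_probe_interval(probe_id: str) -> tuple[str, int, int] | None:
    """Genomic interval from a ``chrom:start-end`` style probe id."""
    m = _PROBE_ID_RE.match(probe_id)
    if not m:
        return None
    return m.group("chrom"), int(m.group("start")), int(m.group("end"))


def load_cnv_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def filter_probes(
    matrix: IntensityMatrix,
    controls: ControlSet,
    cnv_regions: str | Path | Sequence[tuple[str, int, int]] | None = None,
    background_max: float = 50.0,
    per_array: bool = False,
) -> tuple[IntensityMatrix, FilterReport]:
    """Apply the outlier, background and CNV filtering rules.

    Default (global-union) mode removes a probe from *all* arrays if it
    fails any rule on *any* array, which keeps per-array retained counts
    identical.  ``per_array=True`` instead blanks only the failing
    probe-array cells (probe sets may then differ between arrays; the
    report still counts probes failing anywhere).  CNV regions may be a
    BED path or (chrom, start, end) triples; probes with parseable
    ``chrom:start-end`` ids that intersect any region are removed.
    """
    arrays = matrix.array_ids
    pos_median: dict[str, float] = {}
    neg_median: dict[str, float] = {}
    for a in arrays:
        pos, neg = controls.positive(a), controls.negative(a)
        if len(pos) == 0 or len(neg) == 0:
            raise ValueError(f"array {a} has no positive/negative control features")
        pos_median[a] = float(np.median(pos))
        neg_median[a] = float(np.median(neg))

    sig, bg = matrix.signal, matrix.background
    pos_row = pd.Series(pos_median)[arrays]
    neg_row = pd.Series(neg_median)[arrays]
    high_cells = sig.gt(pos_row, axis=1)
    low_cells = sig.lt(neg_row, axis=1)
    bg_cells = bg.gt(background_max)
    high = high_cells.any(axis=1)
    low = low_cells.any(axis=1)
    bad_bg = bg_cells.any(axis=1)

    if isinstance(cnv_regions, (str, Path)):
        cnv_regions = load_cnv_bed(cnv_regions)
    in_cnv = pd.Series(False, index=sig.index)
    if cnv_regions:
        for pid in sig.index:
            iv = parse_probe_interval(pid)
            if iv is None:
                continue
            chrom, s, e = iv
            if any(chrom == c and s < ce and e > cs for c, cs, ce in cnv_regions):
                in_cnv[pid] = True

    # attribute each probe to the first rule it fails
    rem_high = high
    rem_low = low & ~rem_high
    rem_bg = bad_bg & ~rem_high & ~rem_low
    rem_cnv = in_cnv & ~rem_high & ~rem_low & ~rem_bg
    removed_any = high | low | bad_bg | in_cnv

    if per_array:
        cell_bad = high_cells | low_cells | bg_cells
        cell_bad.loc[in_cnv, :] = True
        new_sig = sig.mask(cell_bad)
        new_bg = bg.mask(cell_bad)
        keep = ~new_sig.isna().all(axis=1)
        filtered = IntensityMatrix(new_sig[keep], new_bg[keep], matrix.samples)
    else:
        keep = ~removed_any
        filtered = IntensityMatrix(sig[keep], bg[keep], matrix.samples)

    report = FilterReport(
        n_input=len(sig),
        n_removed_high=int(rem_high.sum()),
        n_removed_low=int(rem_low.sum()),
        n_removed_background=int(rem_bg.sum()),
        n_removed_cnv=int(rem_cnv.sum()),
        n_retained=int((~removed_any).sum()),
        removed_high=list(sig.index[rem_high]),
        removed_low=list(sig.index[rem_low]),
        removed_background=list(sig.index[rem_bg]),
        removed_cnv=list(sig.index[rem_cnv]),
    )
    return filtered, report


def log_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Natural-log transform of the signals (backgrounds untouched)."""
    vals = matrix.signal.to_numpy(dtype=float)
    if np.nanmin(vals) <= 0:
        raise ValueError("non-positive signal encountered; cannot log-transform")
    return IntensityMatrix(
        signal=pd.DataFrame(np.log(vals), index=matrix.signal.index, columns=matrix.signal.columns),
        background=matrix.background,
        samples=matrix.samples,
    )


def dcp_retention(
    controls: ControlSet, array_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Mean DCP intensity and % of the parent (0-deletion) mean.

    Returns one row per deletion count present, with columns
    deletion_count, n, mean_intensity, retention_pct.
    """
    dcp = controls.dcp(array_ids)
    if dcp.empty:
        raise ValueError("no DCP control features present")
    grouped = dcp.groupby(dcp["deletion_count"].astype(int))["raw_signal"]
    table = grouped.agg(n="size", mean_intensity="mean").reset_index()
    if 0 not in set(table["deletion_count"]):
        raise ValueError("DCP parent (0-deletion) probes missing")
    parent = float(table.loc[table["deletion_count"] == 0, "mean_intensity"].iloc[0])
    if parent <= 0:
        raise ValueError("DCP parent mean must be positive")
    table["retention_pct"] = 100.0 * table["mean_intensity"] / parent
    return table
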