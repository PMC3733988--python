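"""Synthetic masked genomes and single-channel intensity simulation.

The generator emulates the study conditions end-to-end: a target region
with interspersed repeats of the five reported classes (plus unmasked
segmental duplications so off-target k-mer counts are exercised),
probes tiled on a dense central zone flanked by two sparser zones, and
log-scale intensities driven by the fitted fixed-effect structure —
probe GC, log off-target count, free energy, homopolymer lengths, the
offset contrast, log background, log segment length, probe position and
log distance — plus probe, dog and DNA-source random intercepts and
residual noise.  Saliva arrays are attenuated and noisier than blood
arrays; positive, negative and deletion-series (DCP) control features
are drawn at configured levels, and signals saturate at the scanner
ceiling of 65,530.

All randomness flows from one seeded generator per operation, with a
fixed stream order (genome: sequence, repeat geometry, motifs,
duplications; intensities: free energy, probe effects, dog effects,
source effects, then per array backgrounds, residuals and controls), so
every output is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import compute_features
from .qc import ControlSet, IntensityMatrix, matrix_from_frames
from .reference import ReferenceRegion, RepeatInterval, UniqueSegment, segment_region
from .tiling import ProbeSet, TilingPlan, Zone, tile

SATURATION_CEILING = 65_530

#: Fixed-effect defaults: the fitted per-unit effects on log_e intensity
#: (offset contrast handled separately; reference offset effect is 0).
DEFAULT_EFFECTS = {
    "probe_gc": 0.069,          # per GC %
    "log_off_targets": 0.460,   # per log_e(1 + off-target count)
    "free_energy": 0.153,       # per kcal/mol
    "poly_a": 0.034,            # per bp of longest A run
    "poly_c": 0.081,
    "poly_g": 0.132,
    "poly_t": 0.050,
    "log_background": 0.142,    # per log_e background unit
    "log_segment_length": -0.019,
    "position": 0.0002,         # per position index
    "log_distance": 0.024,      # per log_e bp of flanking gap (edge probes)
}

#: Mean % of the parent (non-deleted) signal retained per number of
#: centrally deleted bases; odd deletion counts dent hybridization more
#: than the neighbouring even counts.
DEFAULT_DCP_RETENTION = {0: 100.0, 1: 88.0, 2: 93.0, 3: 72.0, 4: 81.0,
                         5: 57.0, 6: 66.0, 7: 42.0, 8: 24.0}

DEFAULT_CLASS_MIX = {"LINE": 0.35, "SINE": 0.30, "LTR": 0.10, "Simple": 0.15, "LC": 0.10}

# tandem motif length range per repeat class (short motifs for simple /
# low-complexity repeats, longer ones for interspersed elements)
_MOTIF_LEN = {"LINE": (20, 50), "SINE": (15, 40), "LTR": (15, 40), "Simple": (2, 6), "LC": (1, 3)}


@dataclass
class SimulationConfig:
    """All knobs of the simulator, with study-condition defaults."""

    # genome
    region_length: int = 200_000
    chrom: str = "chrSim"
    region_start: int = 0
    repeat_fraction: float = 0.30
    repeat_length_log_mean: float = math.log(300.0)
    repeat_length_log_sd: float = 0.9
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    n_duplications: int = 4
    duplication_length: int = 300

    # design
    probe_length: int = 60
    zone_fractions: tuple = (0.4, 0.2, 0.4)
    zone_offsets: tuple = (26, 6, 26)
    replicate_offset: int = 6
    replicate_copies: int = 4
    anchor: str = "global"

    # arrays
    n_blood: int = 6
    n_saliva: int = 2

    # intensity model (log_e scale)
    beta0: float = 2.0
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    offset_effects: dict = field(default_factory=lambda: {26: 0.190})
    sd_probe: float = 0.15
    sd_dog: float = 0.05
    sd_source: float = 0.05
    sd_residual: float = 0.013
    saliva_multiplier: float = 0.49
    saliva_noise_factor: float = 1.15

    # nuisance distributions
    background_log_mean: float = math.log(36.0)
    background_log_sd: float = 0.13
    free_energy_mean: float = 0.48
    free_energy_sd: float = 1.2
    free_energy_range: tuple = (-9.48, 3.8)

    # controls
    n_pos_controls: int = 30
    n_neg_controls: int = 30
    pos_control_level: float = 9350.0
    neg_control_level: float = 57.0
    control_log_sd: float = 0.10
    dcp_sets: int = 20
    dcp_parent_level: float = 500.0
    dcp_parent_log_sd: float = 0.4
    dcp_noise_log_sd: float = 0.05
    dcp_retention: dict = field(default_factory=lambda: dict(DEFAULT_DCP_RETENTION))

    saturation_ceiling: int = SATURATION_CEILING
    seed: int = 0

    def zones(self) -> list[Zone]:
        bounds = np.cumsum([0.0] + [f for f in self.zone_fractions])
        bounds = np.round(bounds / bounds[-1] * self.region_length).astype(int)
        return [
            Zone(start=int(bounds[i]), end=int(bounds[i + 1]), offset=int(self.zone_offsets[i]))
            for i in range(len(self.zone_offsets))
            if bounds[i + 1] > bounds[i]
        ]

    def plan(self) -> TilingPlan:
        return TilingPlan(
            zones=self.zones(),
            probe_length=self.probe_length,
            anchor=self.anchor,
            replicate_offset=self.replicate_offset,
            replicate_copies=self.replicate_copies,
        )

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["zone_fractions"] = list(self.zone_fractions)
        d["zone_offsets"] = list(self.zone_offsets)
        d["free_energy_range"] = list(self.free_energy_range)
        return d


def simulate_genome(
    config: SimulationConfig, seed: int | None = None
) -> tuple[ReferenceRegion, list[RepeatInterval]]:
    """Random region with planted repeats and unmasked duplications.

    Repeats are realized as tandem copies of a short motif, written
    lowercase (so the softmask dialect applies directly); a handful of
    unmasked chunks are copied elsewhere in unique sequence to mimic
    segmental duplications that escape repeat masking.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    L = config.region_length
    if L <= config.probe_length:
        raise ValueError("region_length must exceed the probe length")

    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=L)

    target_mass = config.repeat_fraction * L
    if target_mass > 0.9 * L:
        raise ValueError("requested repeat mass exceeds the region")
    classes = sorted(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    placed: list[tuple[int, int]] = []
    masks: list[RepeatInterval] = []
    mass = 0.0
    attempts = 0
    while mass < target_mass and attempts < 10_000 and target_mass > 0:
        attempts += 1
        length = int(np.clip(rng.lognormal(config.repeat_length_log_mean,
                                           config.repeat_length_log_sd), 30, L // 10))
        cls = classes[int(rng.choice(len(classes), p=probs))]
        start = int(rng.integers(0, L - length))
        if any(start < e + 1 and start + length > s - 1 for s, e in placed):
            continue
        lo, hi = _MOTIF_LEN[cls]
        motif = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=int(rng.integers(lo, hi + 1)))
        reps = length // len(motif) + 1
        rep_seq = np.tile(motif, reps)[:length]
        seq[start : start + length] = np.char.lower(rep_seq.astype("U1")).astype("S1")
        placed.append((start, start + length))
        masks.append(RepeatInterval(start=start, end=start + length, repeat_class=cls,
                                    name=f"{cls}_sim{len(masks)}"))
        mass += length

    # unmasked segmental duplications: copy a unique chunk elsewhere
    placed_sorted = sorted(placed)
    dlen = config.duplication_length
    used: list[tuple[int, int]] = list(placed_sorted)

    def _free(start: int, length: int) -> bool:
        return not any(start < e and start + length > s for s, e in used)

    for _ in range(config.n_duplications):
        src = dst = None
        for _ in range(200):
            cand = int(rng.integers(0, L - dlen))
            if _free(cand, dlen):
                if src is None:
                    src = cand
                    used.append((cand, cand + dlen))
                else:
                    dst = cand
                    used.append((cand, cand + dlen))
                    break
        if src is not None and dst is not None:
            seq[dst : dst + dlen] = seq[src : src + dlen]

    sequence = seq.tobytes().decode("ascii")
    region = ReferenceRegion(
        chrom=config.chrom,
        start=config.region_start,
        end=config.region_start + L,
        sequence=sequence,
    )
    masks.sort(key=lambda m: (m.start, m.end))
    return region, masks


@dataclass
class SimulatedDataset:
    """Everything one simulation run produced, regenerable from (config, seed)."""

    config: SimulationConfig
    seed: int
    region: ReferenceRegion
    masks: list[RepeatInterval]
    segments: list[UniqueSegment]
    probeset: ProbeSet
    features: pd.DataFrame
    intensity: pd.DataFrame  # long: probe_id, array_id, control_type, raw_signal, background
    samples: pd.DataFrame

    def matrix(self) -> tuple[IntensityMatrix, ControlSet]:
        return matrix_from_frames(self.intensity, self.samples)


def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    n = config.n_blood + config.n_saliva
    for i in range(n):
        rows.append(
            {
                "array_id": f"A{i + 1}",
                "dog_id": f"D{i + 1}",
                "dna_source": "blood" if i < config.n_blood else "saliva",
            }
        )
    return pd.DataFrame(rows)


def simulate_intensities(
    probeset: ProbeSet,
    features: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw per-feature raw signals for every array.

    Returns (intensity long table, sample sheet, features-with-ΔG).
    For each probe-array cell the log_e signal is the intercept plus
    the fixed-effect contributions of the probe's covariates, the
    offset contrast, the log background drawn for that cell, plus probe
    / dog / source random intercepts and residual noise; saliva arrays
    are attenuated by the configured multiplier and get inflated
    residual noise.  Signals are clipped to [1, saturation ceiling].
    Replicated probes contribute extra features ``<id>#k`` sharing the
    probe's predictor and random intercept but fresh background and
    residual draws.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    probes = probeset.to_dataframe()
    feats = features.set_index("probe_id").loc[probes["probe_id"]].reset_index()
    missing = set(("gc_percent", "poly_a", "poly_c", "poly_g", "poly_t", "off_target_matches"))
    missing -= set(feats.columns)
    if missing:
        raise ValueError(f"features table missing covariates: {sorted(missing)}")

    n_probes = len(probes)
    eff = config.effects

    # stream order: free energy, probe effects, dog effects, source effects
    fe = feats.get("free_energy")
    fe_vals = np.asarray(fe, dtype=float) if fe is not None else np.full(n_probes, np.nan)
    need_fe = np.isnan(fe_vals)
    drawn = rng.normal(config.free_energy_mean, config.free_energy_sd, size=int(need_fe.sum()))
    fe_vals[need_fe] = np.clip(drawn, *config.free_energy_range)
    feats = feats.assign(free_energy=fe_vals)

    probe_eff = rng.normal(0.0, config.sd_probe, size=n_probes)
    samples = _sample_sheet(config)
    n_arrays = len(samples)
    dog_eff = rng.normal(0.0, config.sd_dog, size=n_arrays)
    src_levels = {"blood": 0, "saliva": 1}
    source_eff = rng.normal(0.0, config.sd_source, size=2)

    # probe-level fixed predictor (everything except background)
    base = (
        config.beta0
        + eff["probe_gc"] * feats["gc_percent"].to_numpy()
        + eff["log_off_targets"] * np.log1p(feats["off_target_matches"].to_numpy())
        + eff["free_energy"] * fe_vals
        + eff["poly_a"] * feats["poly_a"].to_numpy()
        + eff["poly_c"] * feats["poly_c"].to_numpy()
        + eff["poly_g"] * feats["poly_g"].to_numpy()
        + eff["poly_t"] * feats["poly_t"].to_numpy()
        + eff["log_segment_length"] * np.log(probes["segment_length"].to_numpy(dtype=float))
        + eff["position"] * probes["position"].to_numpy(dtype=float)
    )
    offsets = probes["offset"].to_numpy()
    for level, contrast in config.offset_effects.items():
        base = base + contrast * (offsets == level)
    is_edge = (probes["is_edge_5p"] | probes["is_edge_3p"]).to_numpy()
    dist = probes["distance"].to_numpy(dtype=float)
    dist_term = np.where(is_edge & (dist > 0), np.log(np.where(dist > 0, dist, 1.0)), 0.0)
    base = base + eff["log_distance"] * dist_term
    base = base + probe_eff

    rep_counts = probes["replicate_count"].to_numpy(dtype=int)
    feature_ids: list[str] = []
    feature_pred: list[float] = []
    for pid, pred, rc in zip(probes["probe_id"], base, rep_counts):
        feature_ids.append(pid)
        feature_pred.append(pred)
        for k in range(2, rc + 1):
            feature_ids.append(f"{pid}#{k}")
            feature_pred.append(pred)
    pred_arr = np.array(feature_pred)
    n_feat = len(feature_ids)

    rows: list[pd.DataFrame] = []
    ceiling = float(config.saturation_ceiling)
    for j, s in enumerate(samples.itertuples(index=False)):
        is_saliva = s.dna_source == "saliva"
        bg = rng.lognormal(config.background_log_mean, config.background_log_sd, size=n_feat)
        noise_sd = config.sd_residual * (config.saliva_noise_factor if is_saliva else 1.0)
        resid = rng.normal(0.0, noise_sd, size=n_feat) if noise_sd > 0 else np.zeros(n_feat)
        eta = (
            pred_arr
            + eff["log_background"] * np.log(bg)
            + dog_eff[j]
            + source_eff[src_levels[s.dna_source]]
            + resid
        )
        if is_saliva and config.saliva_multiplier != 1.0:
            eta = eta + math.log(config.saliva_multiplier)
        signal = np.clip(np.exp(eta), 1.0, ceiling)
        rows.append(
            pd.DataFrame(
                {
                    "probe_id": feature_ids,
                    "array_id": s.array_id,
                    "control_type": "none",
                    "raw_signal": signal,
                    "background": bg,
                }
            )
        )
        rows.append(_simulate_controls(config, rng, s.array_id))
    intensity = pd.concat(rows, ignore_index=True)
    return intensity, samples, feats


def _simulate_controls(config: SimulationConfig, rng: np.random.Generator, array_id: str) -> pd.DataFrame:
    recs: list[dict] = []
    pos = rng.lognormal(math.log(config.pos_control_level), config.control_log_sd,
                        size=config.n_pos_controls)
    neg = rng.lognormal(math.log(config.neg_control_level), config.control_log_sd,
                        size=config.n_neg_controls)
    for i, v in enumerate(pos):
        recs.append({"probe_id": f"POS_{i}", "control_type": "pos", "raw_signal": v})
    for i, v in enumerate(neg):
        recs.append({"probe_id": f"NEG_{i}", "control_type": "neg", "raw_signal": v})
    # DCP sets: 2 parent replicates + 4 deletion levels x 2 replicates,
    # odd-deletion sets alternating with even-deletion sets
    for si in range(config.dcp_sets):
        parent = math.exp(rng.normal(math.log(config.dcp_parent_level), config.dcp_parent_log_sd))
        levels = [1, 3, 5, 7] if si % 2 == 0 else [2, 4, 6, 8]
        for r in range(2):
            v = parent * math.exp(rng.normal(0.0, config.dcp_noise_log_sd))
            recs.append({"probe_id": f"DCP_s{si}_d0_r{r}", "control_type": "dcp:0", "raw_signal": v})
        for d in levels:
            for r in range(2):
                v = (parent * config.dcp_retention[d] / 100.0
                     * math.exp(rng.normal(0.0, config.dcp_noise_log_sd)))
                recs.append({"probe_id": f"DCP_s{si}_d{d}_r{r}",
                             "control_type": f"dcp:{d}", "raw_signal": v})
    df = pd.DataFrame(recs)
    df["array_id"] = array_id
    bg = rng.lognormal(config.background_log_mean, config.background_log_sd, size=len(df))
    df["background"] = bg
    ceiling = float(config.saturation_ceiling)
    df["raw_signal"] = df["raw_signal"].clip(1.0, ceiling)
    return df[["probe_id", "array_id", "control_type", "raw_signal", "background"]]


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Run the full chain: genome -> segments -> probes -> features -> signals."""
    seed = config.seed if seed is None else seed
    region, masks = simulate_genome(config, seed)
    segments = segment_region(region, masks)
    probeset = tile(region, segments, config.plan())
    from .features import build_kmer_index

    index = build_kmer_index(region, k=25, canonical=True)
    features = compute_features(probeset.to_dataframe(), index=index)
    intensity, samples, features = simulate_intensities(probeset, features, config, seed)
    return SimulatedDataset(
        config=config,
        seed=seed,
        region=region,
        masks=masks,
        segments=segments,
        probeset=probeset,
        features=features,
        intensity=intensity,
        samples=samples,
    )


def make_fixture(config: SimulationConfig, seed: int, outdir: str | Path) -> SimulatedDataset:
    """Simulate and write the standard file set to ``outdir``.

    Writes: reference FASTA, masks BED, probes BED/FASTA/TSV, features
    TSV, intensity TSV, sample sheet TSV and the generating parameter
    record as JSON.
    """
    from . import io as dio

    ds = simulate_dataset(config, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dio.write_region_fasta(ds.region, outdir / "reference.fa")
    dio.write_masks_bed(ds.masks, ds.region, outdir / "masks.bed")
    dio.write_probes_bed(ds.probeset, outdir / "probes.bed")
    dio.write_probes_fasta(ds.probeset, outdir / "probes.fa")
    ds.probeset.to_dataframe().to_csv(outdir / "probes.tsv", sep="\t", index=False)
    ds.features.to_csv(outdir / "features.tsv", sep="\t", index=False)
    ds.intensity.to_csv(outdir / "intensity.tsv", sep="\t", index=False)
    ds.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    record = {"seed": seed, "config": config.to_json_dict()}
    with open(outdir / "simulation.json", "w") as fh:
        json.dump(record, fh, indent=1)
    return ds
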