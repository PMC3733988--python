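import numpy as np
import pytest

from densetile import (
    SimulationConfig,
    filter_probes,
    simulate_dataset,
)


@pytest.fixture
def toy_fasta(tmp_path):
    """Factory writing a small FASTA and returning its path."""

    def _write(records: dict[str, str], name: str = "toy.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for chrom, seq in records.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        return path

    return _write


@pytest.fixture(scope="session")
def sim_dataset():
    """One moderate simulated dataset shared across the suite."""
    cfg = SimulationConfig(region_length=30_000)
    return simulate_dataset(cfg, seed=7)


@pytest.fixture(scope="session")
def sim_filtered(sim_dataset):
    matrix, controls = sim_dataset.matrix()
    filtered, report = filter_probes(matrix, controls)
    return filtered, controls, report


def random_region_and_masks(rng: np.random.Generator, length: int = 2000):
    """A random region with random non-overlapping mask intervals."""
    from densetile import ReferenceRegion, RepeatInterval
    from densetile.reference import REPEAT_CLASSES

    seq = "".join(rng.choice(list("ACGT"), size=length))
    region = ReferenceRegion(chrom="chrR", start=0, end=length, sequence=seq)
    n_masks = int(rng.integers(0, 8))
    cuts = np.sort(rng.choice(length, size=2 * n_masks, replace=False)) if n_masks else []
    masks = []
    for i in range(0, len(cuts), 2):
        s, e = int(cuts[i]), int(cuts[i + 1])
        if s < e:
            masks.append(
                RepeatInterval(
                    start=s,
                    end=e,
                    repeat_class=str(rng.choice(REPEAT_CLASSES)),
                    name=f"r{i}",
                )
            )
    return region, masks
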