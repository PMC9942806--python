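import numpy as np
import pytest

from macsome.simulate import simulate_mac_genome, simulate_reads
from macsome.telomere import TelomereMotif, classify_read, find_runs

UNIT = "CCCTAACA"


@pytest.fixture(scope="session")
def motif():
    return TelomereMotif()


@pytest.fixture(scope="session")
def atas_scale_sim():
    """The junction-recovery study condition: 5 contigs, 200 planted
    junctions at 0.02-0.3 usage, 20,000 error-free reads with truth
    alignments.  Session-scoped; shared by unit and acceptance tests."""
    genome = simulate_mac_genome(
        n_contigs=5,
        contig_length=300_000,
        n_junctions=200,
        usage_range=(0.02, 0.3),
        seed=42,
    )
    reads = simulate_reads(genome, n_reads=20_000, error_rate=0.0, seed=43)
    return genome, reads


@pytest.fixture(scope="session")
def atas_scale_annotations(atas_scale_sim, motif):
    _, sim = atas_scale_sim
    return [
        classify_read(rid, len(seq), find_runs(seq, motif))
        for rid, seq in sim.reads
    ]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def planted_run_sequence(rng: np.random.Generator, unit: str = UNIT) -> str:
    """Random sequence with planted telomeric runs at random phases,
    orientations, unit counts (incl. partial units) and positions."""
    comp = str.maketrans("ACGT", "TGCA")
    parts = []
    for _ in range(rng.integers(1, 5)):
        parts.append(random_dna(rng, int(rng.integers(0, 120))))
        u = unit if rng.random() < 0.5 else unit.translate(comp)[::-1]
        phase = int(rng.integers(0, len(u)))
        span = int(rng.integers(4, 6 * len(u)))
        tract = (u * (span // len(u) + 3))[phase : phase + span]
        parts.append(tract)
    parts.append(random_dna(rng, int(rng.integers(0, 120))))
    return "".join(parts)
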