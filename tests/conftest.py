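import numpy as np
import pytest

from natheat.genome import GenomeAnnotation, TranscriptModel
from natheat.simulate import SimulationConfig, generate_annotation, simulate_expression


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(seed=11, n_gene_loci=60, chrom_sizes={"chr1": 500_000, "chr2": 500_000})


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """(annotation, truth, blacklist) for a 60-locus toy genome."""
    return generate_annotation(small_cfg)


@pytest.fixture(scope="session")
def small_expr(small_cfg, small_world):
    ann, truth, _ = small_world
    return simulate_expression(ann, truth, small_cfg)


def random_annotation(seed: int, n: int, chrom_len: int = 100_000, n_chroms: int = 2) -> GenomeAnnotation:
    """Unstructured random transcripts for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    ann = GenomeAnnotation(chrom_sizes={f"chr{i + 1}": chrom_len for i in range(n_chroms)})
    for i in range(n):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        start = int(rng.integers(0, chrom_len - 3000))
        length = int(rng.integers(100, 2500))
        strand = "+" if rng.random() < 0.5 else "-"
        ann.add(TranscriptModel(f"t{i:05d}", f"g{i:05d}", chrom, strand, (start, start + length)))
    return ann
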