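import numpy as np
import pytest
from hypothesis import settings

from gnevo.io_formats import AnnotatedGenome, GeneRecord
from gnevo.synthetic import SimulationConfig, generate_dataset

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_genome(
    genome_id: str = "g",
    scaffold_sizes=(30,),
    gene_length: int = 300,
    spacing: int = 50,
    proteins=None,
) -> AnnotatedGenome:
    """Small deterministic genome: genes named <genome>_s<i>_g<rank>."""
    genes = []
    for si, n in enumerate(scaffold_sizes):
        pos = 1
        for rank in range(n):
            gid = f"{genome_id}_s{si}_g{rank:03d}"
            protein = proteins.get(gid) if proteins else "M" + "A" * 10
            genes.append(
                GeneRecord(gid, f"s{si}", pos, pos + gene_length - 1, 1, rank, protein)
            )
            pos += gene_length + spacing
    return AnnotatedGenome(genome_id, genes)


@pytest.fixture(scope="session")
def planted_dataset(tmp_path_factory):
    """Default-condition synthetic dataset, written once per session."""
    out = tmp_path_factory.mktemp("planted")
    cfg = SimulationConfig(seed=11)
    return generate_dataset(cfg, out_dir=out), out


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
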