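import numpy as np
import pytest

from paleogut.damage import DamageModelParams, pmd_score
from paleogut.alignio import parse_alignments
from paleogut.simdata import SimConfig, generate_reference_set, simulate_reads


@pytest.fixture(scope="session")
def refs():
    """Six-taxon panel: three gut-family, three environmental-family genomes."""
    return generate_reference_set(n_taxa=6, length_bp=20_000, gc=0.5, seed=1)


@pytest.fixture(scope="session")
def sim(refs):
    """Mixed sample: 2000 ancient + 1000 modern reads, default damage model."""
    cfg = SimConfig(n_ancient=2000, n_modern=1000, seed=2)
    return simulate_reads(refs, cfg, DamageModelParams())


@pytest.fixture(scope="session")
def gold_sam_path(sim, tmp_path_factory):
    path = tmp_path_factory.mktemp("sim") / "gold.sam"
    sim.write_sam(path)
    return path


@pytest.fixture(scope="session")
def aligned_reads(gold_sam_path):
    return list(parse_alignments(gold_sam_path))


@pytest.fixture(scope="session")
def truth_by_id(sim):
    return {r.read_id: r for r in sim.reads}


@pytest.fixture(scope="session")
def pmds_by_id(aligned_reads):
    params = DamageModelParams()
    return {r.read_id: pmd_score(r, params).pmds for r in aligned_reads}
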