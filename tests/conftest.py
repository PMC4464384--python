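import numpy as np
import pytest

from dwbiofilm import synthetic


@pytest.fixture(scope="session")
def default_world():
    """Default five-genome community with contigs and their origin table.

    Session-scoped: genome synthesis is the slowest fixture step and the
    world is read-only for every consumer.
    """
    genomes = synthetic.default_genomes(seed=7)
    design = synthetic.default_community(genomes, seed=7)
    contigs, origin = synthetic.simulate_contigs(design, genomes)
    return {
        "genomes": genomes,
        "design": design,
        "contigs": contigs,
        "origin": origin,
        "markers": synthetic.escg_like_marker_set(),
    }


@pytest.fixture(scope="session")
def gc_separated_genomes():
    """Four small genomes of distinct genera with well-separated GC."""
    rng = np.random.default_rng(11)
    gcs = [0.30, 0.45, 0.60, 0.70]
    return [synthetic.simulate_genome(f"g{i}", 40_000, gc,
                                      synthetic._lineage(i), rng)
            for i, gc in enumerate(gcs)]
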