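import pytest

from editarm import pipeline, simgen
from editarm.transcript_db import TranscriptModel


@pytest.fixture
def toy_genome():
    """1 kb single-contig genome with fixed, inspectable sequence."""
    import numpy as np
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    return {"chr1": "".join(bases[rng.integers(0, 4, size=1000)])}


@pytest.fixture
def two_exon_transcript():
    return TranscriptModel("G1", "G1.1", "chr1", "+",
                           exons=[(100, 200), (300, 400)],
                           cds=[(100, 200), (300, 400)])


@pytest.fixture(scope="session")
def sim_reference():
    return simgen.make_reference(seed=1)


@pytest.fixture(scope="session")
def cohort_run(sim_reference):
    """The study-condition cohort: 10 samples over the default synthetic
    reference (30 edit sites, 20 het SNPs, retro-copy on, depth 50)."""
    samples = [simgen.simulate_reads(sim_reference, i) for i in range(10)]
    result = pipeline.run_cohort(sim_reference, samples)
    return sim_reference, samples, result
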