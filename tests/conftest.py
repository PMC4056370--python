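import numpy as np
import pytest

from cnvbreak.core import random_dna
from cnvbreak.simulate import (
    CNVSpec,
    generate_genome,
    generate_outgroup,
    implant_cnvs,
    simulate_reads,
)

STRAINS = [f"s{i}" for i in range(1, 10)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120922)


@pytest.fixture(scope="session")
def mixed_sim():
    """A small cohort covering every implantable signature, with reads."""
    base = generate_genome(2, [60_000, 60_000], gc=0.45, seed=1)
    specs = [
        CNVSpec("deletion", 40, "blunt"),
        CNVSpec("deletion", 60, "microhomology", mh_k=5),
        CNVSpec("deletion", 80, "complex", extras_len=8),
        CNVSpec("deletion", 100, "complex_mh", mh_k=3, extras_len=6),
        CNVSpec("insertion", 30, "filler"),
        CNVSpec("insertion", 28, "repeat_expansion", unit="CA"),
        CNVSpec("tandem_dup", 50, "blunt"),
        CNVSpec("deletion", 120, "nahr_flanks", repeat_len=60, repeat_identity=98.0),
    ]
    ref, strain_genomes, truth = implant_cnvs(base, specs, STRAINS, seed=2)
    reads = simulate_reads(strain_genomes, coverage=1.2, seed=3)
    return {
        "reference": ref,
        "strain_genomes": strain_genomes,
        "truth": truth,
        "reads": reads,
        "specs": specs,
    }


@pytest.fixture(scope="session")
def mixed_calls(mixed_sim):
    from cnvbreak.caller import cluster_and_filter, detect_split_signatures, map_reads

    ref = mixed_sim["reference"]
    alignments = map_reads(mixed_sim["reads"], ref)
    signatures = detect_split_signatures(alignments, ref)
    calls = cluster_and_filter(signatures, ref)
    return {"alignments": alignments, "signatures": signatures, "calls": calls}


@pytest.fixture(scope="session")
def outgroup_shared(mixed_sim):
    """Noise-free outgroup sharing the derived allele of every event."""
    return generate_outgroup(
        mixed_sim["reference"], mixed_sim["truth"], divergence=0.0, share=1.0, seed=5
    )


def make_seq(seed, n, gc=0.5):
    return random_dna(np.random.default_rng(seed), n, gc)
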