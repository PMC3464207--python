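import numpy as np
import pytest

from spliceindex import pipeline, simdata


@pytest.fixture(scope="session")
def recovery_sim():
    """Standard benchmark: 50 genes each with one cassette event, 10 of them
    differential (psi 0.8 -> 0.5), 4+4 replicates, log2 noise SD 0.15."""
    config = simdata.SimConfig(
        n_genes=50,
        n_cassette_events=50,
        replicates_per_genotype=4,
        psi_by_genotype=simdata.make_psi_map(50, 10),
        noise_sd_log2=0.15,
        seed=1,
    )
    return simdata.simulate_array(config)


@pytest.fixture(scope="session")
def recovery_result(recovery_sim):
    return pipeline.run_pipeline(recovery_sim)


def planted_motif_sequences(seed, n=30, length=50, motif="TGC"):
    """Uniform-random sequences, each with one planted motif occurrence."""
    rng = np.random.default_rng(seed)
    seqs = []
    for _ in range(n):
        s = list(rng.choice(list("ACGT"), size=length))
        j = int(rng.integers(0, length - len(motif)))
        s[j : j + len(motif)] = list(motif)
        seqs.append("".join(s))
    return seqs
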