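import numpy as np
import pytest

from pseudoref import simulate


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def small_world():
    """A 200 kb reference/donor pair with default divergence, shared across tests."""
    params = simulate.SimParams(ref_length=200_000, seed=42)
    ref, tracts = simulate.generate_reference(params)
    donor, truth = simulate.mutate_reference(ref, params, tracts)
    contigs, placements = simulate.shear_contigs(donor, params, truth)
    return dict(params=params, ref=ref, tracts=tracts, donor=donor, truth=truth,
                contigs=contigs, placements=placements)
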