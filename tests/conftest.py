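import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from satrep import simulate as sim
from satrep.annotation import group_by_family
from satrep.repeat_genome import build_repeat_genome


@pytest.fixture(scope="session")
def toy():
    """Toy genome + matching catalog + family consensus sequences."""
    genome, catalog, consensus = sim.make_toy_genome(seed=11)
    return genome, catalog, consensus


@pytest.fixture(scope="session")
def major_rg(toy):
    """Repeat genome for the toy major-satellite family."""
    genome, catalog, _ = toy
    groups = group_by_family(catalog)
    return build_repeat_genome(genome, groups["major_sat"])


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
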