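import numpy as np
import pytest

from panelsnp.formats import GenotypeMatrix
from panelsnp.simulate import SimConfig, simulate_population


def make_matrix(rows: dict[str, list[str | None]], loci: list[str]) -> GenotypeMatrix:
    """Build a GenotypeMatrix from rows of "A/G" tokens (None = missing)."""
    varieties = list(rows)
    calls = np.empty((len(varieties), len(loci)), dtype=object)
    for i, v in enumerate(varieties):
        for j, token in enumerate(rows[v]):
            if token is None:
                calls[i, j] = None
            else:
                a, b = token.split("/")
                calls[i, j] = (a, b) if a <= b else (b, a)
    return GenotypeMatrix(varieties, loci, calls)


def random_matrix(
    n_varieties: int, n_loci: int, seed: int, missing_rate: float = 0.05
) -> GenotypeMatrix:
    """Random biallelic genotype matrix with some missing calls."""
    rng = np.random.default_rng(seed)
    varieties = [f"v{i:03d}" for i in range(n_varieties)]
    loci = [f"L{j:03d}" for j in range(n_loci)]
    calls = np.empty((n_varieties, n_loci), dtype=object)
    pairs = [("A", "A"), ("A", "G"), ("G", "G")]
    for j in range(n_loci):
        p = rng.uniform(0.2, 0.8)
        probs = [(1 - p) ** 2, 2 * p * (1 - p), p ** 2]
        for i in range(n_varieties):
            if rng.random() < missing_rate:
                calls[i, j] = None
            else:
                calls[i, j] = pairs[rng.choice(3, p=probs)]
    return GenotypeMatrix(varieties, loci, calls)


@pytest.fixture(scope="session")
def small_truth():
    """4 subpops x 12 varieties, 60 loci: shared across tests that only need
    a plausible structured population."""
    cfg = SimConfig(subpop_sizes=(12, 12, 12, 12), n_loci=60, seed=42)
    return simulate_population(cfg)
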