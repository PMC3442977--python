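from __future__ import annotations

import numpy as np
import pytest

from tiscan import (
    MotifAlignment,
    alignment_from_counts,
    estimate_subset_probs,
    figure2_alignment,
)


@pytest.fixture(scope="session")
def fig2():
    """The 8-site correlated-column worked-example alignment (L=12)."""
    return figure2_alignment()


@pytest.fixture(scope="session")
def fig2_models(fig2):
    """Zero-pseudocount models for r = 1, 2, 3 on the worked example."""
    return [estimate_subset_probs(fig2, r, 0.0) for r in (1, 2, 3)]


def random_alignment(rng: np.random.Generator, N: int, L: int,
                     factor: str = "rand") -> MotifAlignment:
    """Uniform random alignment for oracle comparisons."""
    codes = rng.integers(0, 4, size=(N, L))
    sites = tuple("".join("ACGT"[c] for c in row) for row in codes)
    return MotifAlignment(factor, sites)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def fully_correlated_alignment():
    """Every column identical across columns: site i is a homopolymer.

    Any r-tuple of a site then has probability equal to the site's base
    frequency, so I_r = (L/r) * I_1 / L is strictly decreasing in r.
    """
    return alignment_from_counts(
        {"AAAAAA": 2, "CCCCCC": 2, "GGGGGG": 2, "TTTTTT": 2},
        factor_name="dup-columns",
    )


@pytest.fixture(scope="session")
def anticorrelated_alignment():
    """Three binary columns whose joint tuples are rarer than the marginals
    predict for the all-A site: P(AA)=0.2 < 0.25 pairwise and P(AAA)=0.04 <
    0.125 for the triple, giving a strictly increasing I_r on 'AAA'.
    """
    return alignment_from_counts(
        {
            "AAA": 4, "AAC": 16, "ACA": 16, "CAA": 16,
            "ACC": 14, "CAC": 14, "CCA": 14, "CCC": 6,
        },
        factor_name="anticorrelated",
    )


@pytest.fixture(scope="session")
def product_form_model():
    """An r-family of models whose subset tables are exact products of one
    random set of column marginals (independent columns by construction)."""
    import itertools

    rng = np.random.default_rng(7)
    L = 6
    marginals = rng.dirichlet(np.ones(4), size=L)

    def family(rmax=4):
        from tiscan import MotifProbabilityModel

        models = []
        for r in range(1, rmax + 1):
            tables = {}
            for subset in itertools.combinations(range(1, L + 1), r):
                vec = np.ones(1)
                for p in subset:
                    vec = np.kron(vec, marginals[p - 1])
                tables[subset] = vec
            models.append(
                MotifProbabilityModel("product", L, r, 0, 0.0, tables)
            )
        return models, marginals

    return family
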