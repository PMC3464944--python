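import itertools

import pytest

from plantid import design, multiplex
from plantid.panel import align_panel, generate_synthetic_panel


@pytest.fixture(scope="session")
def synthetic_panel():
    """Aligned 7-species synthetic marker panel (4 targets, 5% divergence)."""
    return align_panel(generate_synthetic_panel(
        n_species=7, n_targets=4, spacer_divergence=0.05, seed=1))


@pytest.fixture(scope="session")
def screened_candidates(synthetic_panel):
    """Screened, shortest-first candidate pairs per target species."""
    return {
        sp: design.design_pairs(synthetic_panel, sp)
        for sp in synthetic_panel.targets
    }


@pytest.fixture(scope="session")
def multiplex_panel(screened_candidates):
    """Optimal single-dye multiplex selected from the screened candidates."""
    return multiplex.select_panel(screened_candidates)


def all_nonempty_subsets(species):
    return [
        subset
        for r in range(1, len(species) + 1)
        for subset in itertools.combinations(species, r)
    ]
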