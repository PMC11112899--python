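import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

import retroplan as rp
from retroplan.search import SearchConfig

AMIDE_RETRO = "[C:1](=[O:2])[NH1:3][C:4]>>[C:1](=[O:2])[OH1].[NH2:3][C:4]"


@pytest.fixture(scope="session")
def universe():
    """Small universe shared by most search tests."""
    return rp.generate_universe(n_blocks=12, depth=3, branching=2, seed=11, n_targets=8)


@pytest.fixture(scope="session")
def universe_setup(universe):
    templates = universe.template_library()
    stock = universe.stock()
    expansion = rp.TemplateExpansion(
        templates, rp.frequency_prior(templates), top_k=1000, cutoff_cumulative=1.0
    )
    return universe, templates, stock, expansion


@pytest.fixture()
def amide_template():
    return rp.RetroTemplate(AMIDE_RETRO, "amide", n_examples=10, index=0)


def make_config(**kwargs) -> SearchConfig:
    defaults = dict(time_limit=0.0, iteration_limit=400, max_transforms=3)
    defaults.update(kwargs)
    return SearchConfig(**defaults)
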