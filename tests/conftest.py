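import numpy as np
import pytest

import genofold as gf

EXAMPLE_LINKS = ["2.3", "4.5", "3", "6.7", "5", "6", "7"]
EXAMPLE_SYMBOLS = ["*_s", "-_s", "x", "+_v", "x", "y", "x"]


@pytest.fixture
def example_chromosome() -> gf.GFChromosome:
    """The canonical 7-gene worked-example chromosome."""
    return gf.parse_chromosome(EXAMPLE_LINKS, EXAMPLE_SYMBOLS)


@pytest.fixture
def linear_chromosome() -> gf.GFChromosome:
    """The chromosome whose kernel is exactly the linear kernel <x, y>."""
    return gf.parse_chromosome(["2.3", "2", "3"], ["*_s", "x", "y"])


@pytest.fixture
def separable_dataset() -> gf.Dataset:
    """Two well-separated clusters, n=60, linearly separable by construction."""
    return gf.make_separable_clusters(n=60, d=2, margin=6.0, seed=0)


@pytest.fixture
def survey_csv(tmp_path):
    """A small synthetic survey CSV on disk."""
    table = gf.synthesize_survey(gf.GeneratorConfig(n=60, seed=3))
    path = tmp_path / "survey.csv"
    gf.write_survey_csv(table, path)
    return path
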