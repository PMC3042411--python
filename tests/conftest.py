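import numpy as np
import pytest

from ighvdup.pipeline import PipelineConfig, build_reference_region
from ighvdup.synthetic import GeneTemplate, random_seq


def make_templates(n: int = 2, length: int = 450, seed: int = 0) -> list[GeneTemplate]:
    rng = np.random.default_rng(seed)
    return [
        GeneTemplate(f"g{i + 1}", random_seq(length, rng), ((0, 46),))
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def study_region():
    """The default ~90 kb study-like region: 24,696 bp unit planted as two
    complete copies plus a 961 bp partial copy, eight gene segments."""
    return build_reference_region(PipelineConfig(master_seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
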