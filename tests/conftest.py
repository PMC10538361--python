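import numpy as np
import pytest

from setsketch.sketcher import SketchConfig, finalize_sketches, sketch_codes
from setsketch.synthetic import SyntheticPairSpec, gen_set_pair


@pytest.fixture(scope="session")
def full_config():
    return SketchConfig(m=256, full_updates=True, seed=0)


@pytest.fixture(scope="session")
def one_perm_config():
    return SketchConfig(m=256, seed=0)


@pytest.fixture(scope="session")
def finalized_pair(full_config):
    """A comparable pair of full-update sketches with true Jaccard 1/3."""
    a, b, truth = gen_set_pair(SyntheticPairSpec(n_a=2000, n_b=2000, overlap=1000, seed=11))
    finals, params = finalize_sketches(
        [sketch_codes(a, full_config), sketch_codes(b, full_config)], full_config
    )
    return finals[0], finals[1], truth


@pytest.fixture
def tmp_fasta(tmp_path):
    def _write(name, records):
        from setsketch.synthetic import write_fasta

        return write_fasta(tmp_path / name, records)

    return _write
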