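import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from cladeforge import synthetic


@pytest.fixture
def small_cfg():
    """Scaled-down simulation config for fast per-test generation."""

    def make(seed, **overrides):
        base = dict(
            n_clades=4,
            n_grouped_leaves=24,
            n_outliers=2,
            n_outgroup=4,
            n_genomes=30,
            n_markers=40,
            n_absent_markers=3,
            n_families=120,
            n_core=8,
            rec_n_families=40,
            n_operons=12,
            n_motif_seqs=12,
        )
        base.update(overrides)
        return synthetic.SimConfig(seed=seed, **base)

    return make
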