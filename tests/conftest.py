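import numpy as np
import pytest

from tethercoil import (LRP6_TM_ANCHOR, SamplerConfig, default_library,
                        fit_helix_axis, make_ps_repeat_sequence,
                        sample_conformer)
from tethercoil.geometry import random_rotation


@pytest.fixture(scope="session")
def mini_record():
    """60-residue P/S chain with the transmembrane anchor."""
    return make_ps_repeat_sequence(LRP6_TM_ANCHOR, 60, "mini")


@pytest.fixture(scope="session")
def mini_ensemble(mini_record):
    """40 sampled conformers of the mini record with their frames."""
    lib = default_library().with_helical_anchor(mini_record)
    confs = [
        sample_conformer(mini_record, lib, SamplerConfig(rng_seed=(7, i)))
        for i in range(40)
    ]
    frames = [fit_helix_axis(c, mini_record.anchor_span) for c in confs]
    return confs, frames


@pytest.fixture
def rigid_motions():
    """Deterministic list of random rotation+translation pairs."""
    rng = np.random.default_rng(11)
    return [(random_rotation(rng), rng.normal(scale=30.0, size=3))
            for _ in range(20)]
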