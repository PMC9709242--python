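"""Shared fixtures: synthetic fields are generated once per session since the
full-size assays are the expensive part of the suite."""

from __future__ import annotations

import numpy as np
import pytest

from spermaquant.core import RunConfig
from spermaquant.pipelines import run_activation_assay, segment_activation_field
from spermaquant.synth import SynthesisConfig, preset, synth_jc1_field, synth_spermatid_field


@pytest.fixture(scope="session")
def activation_preset_results():
    """Full activation pipeline on the three Pronase presets (n=200, seed 1)."""
    out = {}
    for name in ("wt-pronase", "mut-pronase", "aka36-pronase"):
        out[name] = run_activation_assay(name, config=RunConfig(seed=1))
    return out


@pytest.fixture(scope="session")
def balanced_noiseless_field():
    """A noiseless field with equal class counts plus its segmentation —
    the calibration regime for classifier-recovery checks."""
    cfg = SynthesisConfig(seed=11, n_cells=200,
                          class_mixture=(0.25, 0.25, 0.25, 0.25),
                          noise_gaussian_sd=0.0)
    image, truth = synth_spermatid_field(cfg)
    labels = segment_activation_field(image, RunConfig())
    return image, truth, labels


@pytest.fixture(scope="session")
def jc1_preset_stacks():
    """Rendered wild-type and mutant JC-1 fields with ground truth."""
    return {name: synth_jc1_field(preset(name, seed=2))
            for name in ("wt-jc1", "mut-jc1")}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
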