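"""Shared fixtures: small, fast synthetic cohort geometries."""

from __future__ import annotations

import numpy as np
import pytest

from phasetree.synthdata import CohortSpec, CouplingGraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_spec(**overrides) -> CohortSpec:
    """A reduced recording geometry for fast tests.

    15 ROIs at 256 Hz, five 2-s epochs: the full pipeline runs in tens of
    milliseconds per subject while every stage behaves as at full scale.
    """
    defaults = dict(
        n_patients=2,
        n_controls=2,
        n_rois=15,
        fs_acquisition=256.0,
        epoch_length=2.0,
        n_epochs=5,
        coupling_graph_patients=CouplingGraph("chain", 0.8),
        coupling_graph_controls=CouplingGraph("star", 0.8),
        noise_sd=1.0,
        seed=0,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


@pytest.fixture
def tiny_spec():
    return small_spec()
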