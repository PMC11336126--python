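"""Shared fixtures: small layouts, templates and simulated recordings.

Everything is generated programmatically with fixed seeds; expensive
simulations are module- or session-scoped so they are built once.
"""

import numpy as np
import pytest

from mstates.clustering import TemplateSet
from mstates.layout import make_layout
from mstates.preproc import EpochSet, Recording, average_reference, make_epochs
from mstates.synth import (
    DynamicsSpec,
    make_templates,
    simulate_labels,
    synthesize_recording,
)


@pytest.fixture(scope="session")
def layout19():
    return make_layout(19)


@pytest.fixture(scope="session")
def layout30():
    return make_layout(30)


@pytest.fixture(scope="session")
def templates19(layout19):
    return make_templates(layout19, k=4, seed=1)


@pytest.fixture(scope="session")
def dyn4():
    return DynamicsSpec()


@pytest.fixture(scope="session")
def noise_free_case(layout30, dyn4):
    """(recording, labels, templates) at effectively infinite SNR, 30 s."""
    templates = make_templates(layout30, k=4, seed=1)
    labels = simulate_labels(dyn4, n_samples=15000, sfreq=500.0, seed=3)
    rec = synthesize_recording(templates, labels, layout30, sfreq=500.0,
                               snr=1e6, seed=4)
    return rec, labels, templates


@pytest.fixture(scope="session")
def realistic_case(layout30, dyn4):
    """(recording, labels, templates) at SNR 5, 30 s — the realistic regime."""
    templates = make_templates(layout30, k=4, seed=2)
    labels = simulate_labels(dyn4, n_samples=15000, sfreq=500.0, seed=5)
    rec = synthesize_recording(templates, labels, layout30, sfreq=500.0,
                               snr=5.0, seed=6)
    return rec, labels, templates


def epochs_from_array(data: np.ndarray, sfreq: float = 500.0,
                      reference: bool = True) -> EpochSet:
    """Wrap an (n_epochs, n_channels, n_samples) array as an EpochSet."""
    data = np.asarray(data, dtype=float)
    layout = make_layout(data.shape[1])
    ep = EpochSet(epochs=data, sfreq=sfreq, layout=layout)
    return average_reference(ep) if reference else ep


def recording_from_array(data: np.ndarray, sfreq: float = 500.0) -> Recording:
    layout = make_layout(data.shape[0])
    return Recording(data=np.asarray(data, dtype=float), sfreq=sfreq, layout=layout)
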