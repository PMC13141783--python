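"""Shared fixtures for the glycofp test suite."""

from __future__ import annotations

import numpy as np
import pytest

from glycofp import (
    CohortSpec,
    GlycemiaParams,
    NeuralParams,
    UniformTrace,
    generate_cohort,
)

SESSION_SPAN_S = (-25.0 * 60.0, 90.0 * 60.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def flat_trace() -> UniformTrace:
    """A constant 100 mg/dL session-length trace."""
    n = int(SESSION_SPAN_S[1] - SESSION_SPAN_S[0]) + 1
    return UniformTrace(np.full(n, 100.0), t0=SESSION_SPAN_S[0])


@pytest.fixture
def small_cohort():
    """A compact synthetic cohort: 3 subjects, training doses only."""
    spec = CohortSpec(n_subjects=3, doses=(1.0, 2.0, 2.5), master_seed=7)
    sessions, manifest = generate_cohort(spec)
    return sessions, manifest


def make_session_trace(values: np.ndarray) -> UniformTrace:
    """Wrap values on the standard session time axis."""
    return UniformTrace(values, t0=SESSION_SPAN_S[0])


def quiet_glycemia(**overrides) -> GlycemiaParams:
    """Low-noise glucose parameters for targeted structural tests."""
    base = dict(noise_sd=0.05, spike_rate_per_min=0.0)
    base.update(overrides)
    return GlycemiaParams(**base)


def quiet_neural(**overrides) -> NeuralParams:
    """Low-noise neural parameters for targeted structural tests."""
    base = dict(noise_sd=0.01, slow_noise_sd=0.0, artifact_rate_per_min=0.0,
                bleach_amp=0.0)
    base.update(overrides)
    return NeuralParams(**base)
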