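"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from spikestate.core import SpikeTrain, make_trial_table

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def poisson_train(
    rng: np.random.Generator,
    rate_fn,
    T: float,
    rate_max: float,
    unit_id: str = "u",
) -> SpikeTrain:
    """Independent thinning oracle (deliberately separate from the package)."""
    n = rng.poisson(rate_max * T)
    t = np.sort(rng.uniform(0.0, T, n))
    r = rate_fn(t) if callable(rate_fn) else np.full(n, float(rate_fn))
    keep = rng.uniform(0.0, 1.0, n) < r / rate_max
    return SpikeTrain(unit_id, t[keep], T)


def regular_trials(
    n: int,
    duration: float = 2.0,
    gap: float = 1.0,
    stimulus_class: str = "tf_grating",
    parameter: float = 4.0,
    state: str | None = None,
    t0: float = 0.0,
) -> pd.DataFrame:
    """Evenly spaced single-condition trial table."""
    onsets = t0 + np.arange(n) * (duration + gap)
    states = None if state is None else np.full(n, state, dtype=object)
    return make_trial_table(
        onsets,
        np.full(n, duration),
        np.full(n, stimulus_class, dtype=object),
        np.full(n, parameter),
        state=states,
    )


def inverse_cdf_train(rate_fn, T: float, n: int, grid: int = 200_000) -> SpikeTrain:
    """Deterministic train whose spike density follows ``rate_fn`` exactly.

    Places n spikes at the quantiles of the normalized density (numerical
    inverse CDF) -- an oracle for the F0/F1 estimator free of Poisson noise.
    """
    t = np.linspace(0.0, T, grid)
    density = rate_fn(t)
    cdf = np.cumsum(density)
    cdf = cdf / cdf[-1]
    q = (np.arange(n) + 0.5) / n
    return SpikeTrain("det", np.interp(q, cdf, t), T)
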