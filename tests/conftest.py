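"""Shared fixtures: the reference scorer, a complete block library, oracles."""

import math

import numpy as np
import pytest

from idpdesign import (
    DesignParams,
    ScorerModel,
    build_library,
    default_model,
)


@pytest.fixture(scope="session")
def model() -> ScorerModel:
    return default_model()


@pytest.fixture(scope="session")
def params() -> DesignParams:
    return DesignParams()


@pytest.fixture(scope="session")
def library(model, params):
    """A complete 9x50 library, built once per session (seed 1)."""
    return build_library(model, params, rng=1)


def naive_profile(sequence: str, model: ScorerModel) -> np.ndarray:
    """Brute-force reference scorer: every window recomputed from scratch.

    Independent of the vectorized implementation: plain Python loops over the
    neighborhood and the smoothing window.
    """
    from idpdesign.design import AA20

    idx = [AA20.index(c) for c in sequence]
    n = len(idx)
    raw = []
    for i in range(n):
        vals = [
            model.energy_matrix[idx[i], idx[j]]
            for j in range(n)
            if model.neighborhood_min <= abs(i - j) <= model.neighborhood_max
        ]
        e = sum(vals) / len(vals) if vals else 0.0
        raw.append(1.0 / (1.0 + math.exp(model.transform_slope * (e - model.transform_midpoint))))
    half = model.smoothing_window // 2
    smoothed = []
    for i in range(n):
        window = raw[max(0, i - half): min(n, i + half + 1)]
        smoothed.append(sum(window) / len(window))
    return np.array(smoothed)
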