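"""Shared fixtures: small phantoms rendered once per session."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from flairwmh.phantom import PhantomSpec, generate_phantom

# A miniature head grid for unit tests: same anisotropy style, renders in
# ~100 ms, and its 1 mm atlas grid (64 x 64 x 48) suits the networks.
TINY_SPEC = PhantomSpec(
    shape=(32, 32, 8),
    spacing=(2.0, 2.0, 6.0),
    target_wmh_cc=1.5,
    noise_sd=4.0,
)


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    return TINY_SPEC


@pytest.fixture(scope="session")
def tiny_phantom():
    return generate_phantom(dataclasses.replace(TINY_SPEC, seed=11))


@pytest.fixture(scope="session")
def tiny_phantoms():
    """Twelve varied miniature phantoms (lesion load, site gain)."""
    rng = np.random.default_rng(5)
    out = []
    for i in range(12):
        spec = dataclasses.replace(
            TINY_SPEC,
            seed=400 + i,
            target_wmh_cc=float(rng.uniform(0.5, 3.0)),
            site_gain=float(np.exp(rng.uniform(np.log(0.5), np.log(2.0)))),
        )
        out.append(generate_phantom(spec))
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
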