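"""Shared fixtures: phantoms and their derived volumes, built once per session."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from voxdose.phantom import PhantomSpec, make_ct, make_series


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    """The canonical blur-free two-kidney phantom."""
    return PhantomSpec.default(seed=0)


@pytest.fixture(scope="session")
def blurred_spec(default_spec) -> PhantomSpec:
    """Same patient imaged with a realistic 3 mm SPECT point-spread function."""
    return dataclasses.replace(default_spec, psf_sigma_mm=3.0)


@pytest.fixture(scope="session")
def ct_and_masks(default_spec):
    return make_ct(default_spec)


@pytest.fixture(scope="session")
def default_series(default_spec):
    return make_series(default_spec)


@pytest.fixture(scope="session")
def blurred_series(blurred_spec):
    return make_series(blurred_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
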