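"""Shared fixtures: parameter sets, small meshes and assembled operators."""

from __future__ import annotations

import numpy as np
import pytest

import ultraharm as uh


@pytest.fixture(scope="session")
def prim():
    """Reference parameter set (ultrasound contrast imaging regime)."""
    return uh.TABLE_PRESET


@pytest.fixture(scope="session")
def der(prim):
    return uh.derive_params(prim)


@pytest.fixture(scope="session")
def coarse_mesh():
    """A coarse disk mesh for structural/algebraic tests."""
    return uh.generate_disk_mesh(0.2, 0.02, seed=0)


@pytest.fixture(scope="session")
def coarse_ops(coarse_mesh):
    return uh.assemble_operators(coarse_mesh)


@pytest.fixture(scope="session")
def medium_mesh():
    """Resolves the fundamental wavelength reasonably (h = 0.01)."""
    return uh.generate_disk_mesh(0.2, 0.01, seed=0)


@pytest.fixture(scope="session")
def medium_ops(medium_mesh):
    return uh.assemble_operators(medium_mesh)


@pytest.fixture(scope="session")
def source():
    return uh.SourceSpec(a=1.0e4, r_delta=0.004)


@pytest.fixture(scope="session")
def linear_der(der):
    """Derived parameters with all quadratic couplings switched off."""
    from dataclasses import replace

    return replace(der, eta=0.0, zeta=0.0, xi=0.0)


def rel(a: np.ndarray, b: np.ndarray) -> float:
    nb = np.linalg.norm(b)
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)) / (nb if nb else 1.0))
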