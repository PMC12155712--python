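"""Shared fixtures: small phantoms and acquisitions reused across modules.

Everything is generated programmatically at session scope; sizes are kept
small (64-128 transverse A-scans) so the whole suite stays fast while the
dedicated acceptance tests run the full-scale checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from octfuse import simkit
from octfuse.protocol import AcquisitionProtocol


def small_protocol(n: int = 64, n_volumes: int = 2,
                   duration: float | None = None) -> AcquisitionProtocol:
    """Isotropic protocol at the standard 12 um pitch, n x n A-scans."""
    return AcquisitionProtocol(
        fov_mm=n * 12.0 / 1000.0, ascans_per_bscan=n, bscans_per_volume=n,
        volume_duration_s=duration if duration else n * n / 128_000.0 * 1.25,
        inter_volume_gap_s=0.02, n_volumes=n_volumes)


def textured_config(n: int = 96, nz: int = 200, n_sdds: int = 12,
                    seed: int = 42, **kw) -> simkit.PhantomConfig:
    """Phantom with enough transverse texture (deposits) to register."""
    rng = np.random.default_rng(seed)
    ext = n * 12.0
    sdds = simkit.random_sdds(n_sdds, ext, rng, margin_um=80,
                              min_sep_um=140)
    kw.setdefault("undulation_amp_um", 20.0)
    return simkit.PhantomConfig(nx=n, ny=n, nz=nz, sdds=tuple(sdds),
                                seed=seed, **kw)


@pytest.fixture(scope="session")
def flat_phantom():
    """Degenerate phantom: no undulation, no drusen, no SDDs."""
    return simkit.make_phantom(simkit.PhantomConfig(nx=64, ny=64, nz=200))


@pytest.fixture(scope="session")
def proto64():
    return small_protocol(64, 2)


@pytest.fixture(scope="session")
def static_pair(flat_phantom, proto64):
    """Two orthogonal noiseless volumes of the static flat phantom."""
    return simkit.acquire(flat_phantom, proto64, None, seed=0)


@pytest.fixture(scope="session")
def textured_phantom():
    return simkit.make_phantom(textured_config(96, 200, 12, seed=42))


@pytest.fixture(scope="session")
def proto96():
    return small_protocol(96, 2, duration=0.6)


@pytest.fixture(scope="session")
def textured_pair(textured_phantom, proto96):
    """Two orthogonal speckled volumes of the static textured phantom."""
    return simkit.acquire(textured_phantom, proto96, None,
                          speckle_contrast=0.2, detector_noise_sd=0.005,
                          seed=5)
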