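"""Shared fixtures: one full default-scene pipeline run (session scoped, the
expensive object almost every integration test needs) and a coarse 10 mm
bundle for cheaper module-level tests."""

from __future__ import annotations

import numpy as np
import pytest

import ptxshim as px
from ptxshim import sar
from ptxshim.nsga2 import GAConfig

SEED = 1234


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default 8-channel loop-dipole scene (5 mm grid)."""
    return px.run_pipeline(seed=SEED, with_thermometry=False)


@pytest.fixture(scope="session")
def coarse_bundle():
    """Scene + total fields + Q sets on a 10 mm grid: cheap but fully real."""
    config = {"grid": {"spacing_mm": 10.0}}
    scene = px.build_scene(config)
    fields = px.compute_fields(scene)
    total = fields["total"]
    q = sar.point_q_matrices(total, scene.sigma, scene.rho, scene.phantom_mask)
    q10 = sar.average_q_10g(q, scene.rho, scene.grid)
    return {"config": config, "scene": scene, "fields": fields, "total": total,
            "q": q, "q10": q10}


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


def random_unit_vectors(n: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    u = rng.standard_normal((n, dim)) + 1j * rng.standard_normal((n, dim))
    return u / np.linalg.norm(u, axis=1, keepdims=True)
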