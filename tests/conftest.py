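import logging

import numpy as np
import pytest
from hypothesis import settings

from arvmap import PipelineConfig, run_pipeline
from arvmap.omnipolar import OmniVector
from arvmap.sim_atrium import DEFAULT_GEOMETRY, simulate_scenario
from arvmap.vector_map import VectorMap, partition_chamber

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

logging.getLogger("arvmap").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def geom():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def focal_session():
    """One canonical focal-source mapping session, shared across tests."""
    return simulate_scenario("focal", seed=11)


@pytest.fixture(scope="session")
def focal_result(focal_session):
    """Full pipeline output for the shared focal session."""
    return run_pipeline(focal_session, PipelineConfig())


@pytest.fixture(scope="session")
def make_vector():
    """Factory for hand-built accepted vectors."""

    def _make(
        x, y, dx, dy, certainty=0.9, vpp=1.0, beat=0, pose=0, speed=0.8
    ) -> OmniVector:
        d = np.array([dx, dy], dtype=float)
        d = d / np.hypot(*d)
        return OmniVector(
            position=np.array([x, y], dtype=float),
            direction=d,
            speed_m_s=speed,
            certainty=certainty,
            vpp_mv=vpp,
            beat_index=beat,
            pose_index=pose,
            accepted=True,
            reject_reason="none",
        )

    return _make


@pytest.fixture(scope="session")
def make_map(geom, make_vector):
    """Factory for synthetic vector maps from (position, direction) arrays."""

    def _make(positions, directions, **kw) -> VectorMap:
        vectors = [
            make_vector(p[0], p[1], d[0], d[1], pose=i, **kw)
            for i, (p, d) in enumerate(zip(positions, directions))
        ]
        return VectorMap(
            vectors=vectors,
            geometry=geom,
            partition=partition_chamber(geom, 18),
        )

    return _make


def radial_ring_points(center, radii, n_per_ring=24):
    """Points on concentric rings with outward unit directions."""
    pos, dirs = [], []
    for r in radii:
        for k in range(n_per_ring):
            a = 2 * np.pi * (k + 0.13) / n_per_ring
            pos.append([center[0] + r * np.cos(a), center[1] + r * np.sin(a)])
            dirs.append([np.cos(a), np.sin(a)])
    return np.array(pos), np.array(dirs)
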