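"""Shared fixtures for the oriscope test suite.

All randomness is seeded; the suite is deterministic end to end.
"""

import numpy as np
import pytest

from oriscope import genome_synth as gs
from oriscope import kymo_sim as ks
from oriscope import motif_peak as mp


@pytest.fixture(scope="session")
def acs_pwm():
    return mp.make_acs_like_pwm()


@pytest.fixture(scope="session")
def planted_genome(acs_pwm):
    """100-kb synthetic genome with 12 planted ACS-like motifs (score > 12)."""
    g = gs.sample_genome(100_000, seed=101)
    return gs.plant_motifs(g, acs_pwm, 12, 12.0, seed=102)


@pytest.fixture(scope="session")
def default_tether():
    return ks.TetherModel()


def make_trajectory(positions_bp, channel="red", start_line=0,
                    bp_per_pixel=250.0):
    """Build a Trajectory from base-pair positions (test helper)."""
    from oriscope.trace_pipeline import Trajectory

    positions_bp = np.asarray(positions_bp, dtype=float)
    lines = np.arange(start_line, start_line + positions_bp.size)
    return Trajectory(channel, lines, positions_bp / bp_per_pixel,
                      positions_bp, np.ones(positions_bp.size))
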