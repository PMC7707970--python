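"""Shared fixtures: reference parameter sets and constructed trajectories."""

import numpy as np
import pytest

from fhnswitch import FNParams, Trajectory, find_equilibria


@pytest.fixture(scope="session")
def params_bistable() -> FNParams:
    """Reference bistable setting: a=2, b=1.5, c=1, e=2 (wells at u = +-sqrt(2))."""
    return FNParams(a=2.0, b=1.5, c=1.0, e=2.0)


@pytest.fixture(scope="session")
def params_monostable() -> FNParams:
    """Reference monostable setting: a=2, b=1.5, c=1, e=1 (single well at 0)."""
    return FNParams(a=2.0, b=1.5, c=1.0, e=1.0)


@pytest.fixture(scope="session")
def eq_low(params_bistable):
    """The negative-branch stable equilibrium (-sqrt(2), -2 sqrt(2)/1.5)."""
    return find_equilibria(params_bistable).stable_points[0]


@pytest.fixture(scope="session")
def eq_high(params_bistable):
    return find_equilibria(params_bistable).stable_points[-1]


def square_wave_trajectory(n_plateaus, plateau_len=10.0, lo=-1.4, hi=1.4, dt=0.1, start_low=True):
    """Trajectory alternating between two plateaus, with known crossing times."""
    n_per = int(round(plateau_len / dt))
    levels = []
    level = lo if start_low else hi
    for _ in range(n_plateaus):
        levels.append(np.full(n_per, level))
        level = hi if level == lo else lo
    u = np.concatenate(levels)
    t = np.arange(u.size) * dt
    return Trajectory(times=t, u=u, v=np.zeros_like(u))


@pytest.fixture
def square_wave():
    return square_wave_trajectory
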