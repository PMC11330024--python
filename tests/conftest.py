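"""Shared fixtures.

Full simulations are the expensive part of this suite, and several tests
interrogate the same converged fields (spot counts, correlations, fusion,
sweeps).  ``sim`` is a session-scoped memoizing runner so each
(scenario, seed, grid) combination is integrated exactly once.
"""

import numpy as np
import pytest

from harlequin import (
    Grid,
    Scenario,
    SolverConfig,
    preset_scenarios,
)
from harlequin.cli_io import run_scenario


class SimRunner:
    """Memoized scenario runner shared across the test session."""

    def __init__(self):
        self._cache = {}
        self._registry = preset_scenarios()

    def run(self, scenario, seed, n=100, **solver_kwargs):
        """Run (or fetch) a converged scenario simulation.

        ``scenario`` is a preset name or a Scenario; returns
        (IntegrationResult, PatternSummary).
        """
        if isinstance(scenario, str):
            key_sc = scenario
            scenario = self._registry[scenario]
        else:
            key_sc = (scenario.name, tuple(sorted(scenario.overrides.items())))
        key = (key_sc, seed, n, tuple(sorted(solver_kwargs.items())))
        if key not in self._cache:
            grid = Grid(n=n, L=float(n))
            solver = SolverConfig(**solver_kwargs)
            result, summary, _ = run_scenario(scenario, seed, grid, solver)
            self._cache[key] = (result, summary)
        return self._cache[key]


@pytest.fixture(scope="session")
def sim():
    return SimRunner()


@pytest.fixture(scope="session")
def seeds():
    """The matched seed panel used by all multi-seed pattern assertions."""
    return [1, 2, 3, 4, 5]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
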