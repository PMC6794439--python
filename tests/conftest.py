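"""Shared fixtures: expensive simulation bundles are session-scoped so the
whole suite runs each preset once."""

from __future__ import annotations

import numpy as np
import pytest

import astroca as ac


@pytest.fixture(scope="session")
def designs_default():
    """Digital design set for the base parameter table at dt = 1 ms."""
    return ac.build_designs(dt=1e-3)


@pytest.fixture(scope="session")
def fig8_bundle():
    """Spike-driven 500 s experiment (reference + digital + report)."""
    return ac.run_experiment("fig8")


@pytest.fixture(scope="session")
def fig9_bundles():
    """The three modulation-mode step experiments keyed by preset name."""
    return {p: ac.run_experiment(p) for p in ("fig9_am", "fig9_fm", "fig9_afm")}


@pytest.fixture(scope="session")
def clamp_references():
    """500 s reference traces at the three regime-defining clamp levels."""
    return {lvl: ac.simulate_reference(ac.ip3_clamp([(500.0, lvl)]), dt_out=1e-3)
            for lvl in (0.125, 0.625, 1.2)}


@pytest.fixture(scope="session")
def oscillatory_pair(designs_default):
    """Reference and digital traces for the oscillatory 0.625 uM clamp."""
    proto = ac.ip3_clamp([(500.0, 0.625)])
    ref = ac.simulate_reference(proto, dt_out=1e-3)
    dig = ac.run_digital(proto, designs_default)
    return ref, dig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)
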