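"""Shared fixtures: simulated cohorts at the default study conditions."""

from __future__ import annotations

import numpy as np
import pytest

import gutdyn as gd


@pytest.fixture(scope="session")
def default_sim() -> gd.SimulationResult:
    """The default 12-infant, 150-OTU cohort (seed 1), shared across tests."""
    return gd.simulate_cohort(gd.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_rel(default_sim):
    """Common-scaled relative abundances for the default cohort."""
    return gd.to_relative(gd.common_scale(default_sim.cohort.counts))


@pytest.fixture(scope="session")
def default_series(default_sim, default_rel):
    """Interpolated series for the 11 early-starting infants."""
    co = default_sim.cohort
    retained, _ = gd.exclude_late_starters(co.meta)
    keep = co.meta.infant_id.isin(retained)
    return gd.interpolate_cohort(default_rel.loc[keep], co.meta)


@pytest.fixture(scope="session")
def default_profile(default_series):
    profile = gd.contemporaneous_distances(default_series)
    gd.detect_window(profile)
    return profile


@pytest.fixture(scope="session")
def small_sim() -> gd.SimulationResult:
    """A fast 4-infant, 24-OTU cohort for I/O and plumbing tests."""
    cfg = gd.SimulationConfig(
        n_infants=4,
        n_otus=24,
        sampling_rate=0.25,
        twin_pair=None,
        late_starter=None,
        seed=7,
    )
    return gd.simulate_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
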