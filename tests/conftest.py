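"""Shared fixtures: compositions, receptors and small synthetic systems."""

from __future__ import annotations

import numpy as np
import pytest

import lipidkinetics as lk


@pytest.fixture(scope="session")
def composition():
    return lk.build_default_composition()


@pytest.fixture(scope="session")
def receptor():
    return lk.build_seven_helix_receptor()


@pytest.fixture(scope="session")
def kinetic_sim(composition, receptor):
    """One lower-leaflet PIP2 site with k_off = 10/us, ~20 us of data.

    Shared by the synthetic-generator and contact-detection tests; rich
    enough (hundreds of events) for distributional checks.
    """
    site = lk.design_site(
        receptor, "TM1", "lower", "PIP2", "S1",
        k_on_per_us=1000.0, k_off_true_per_us=10.0, capture_radius_nm=1.5,
    )
    cfg = lk.SystemConfig(
        box_nm=(12.0, 12.0, 10.0), frame_stride_ns=2.0, total_time_us=20.0, seed=42
    )
    traj, ledger = lk.simulate_membrane_trajectory(
        composition, receptor, [site], cfg, n_upper=20, n_lower=120
    )
    return traj, ledger, site, cfg


@pytest.fixture(scope="session")
def quiet_membrane(composition, receptor):
    """A short site-free membrane for spatial statistics."""
    cfg = lk.SystemConfig(
        box_nm=(14.0, 14.0, 10.0), frame_stride_ns=2.0, total_time_us=0.3, seed=7
    )
    traj, _ = lk.simulate_membrane_trajectory(
        composition, receptor, [], cfg, n_upper=120, n_lower=120
    )
    return traj
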