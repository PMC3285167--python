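"""Shared fixtures: oracle scenario runs and scripted transfer trajectories.

The three steering scenarios are session-scoped because each one integrates
~10⁵–10⁶ Langevin steps; every test that needs an ensemble or PMF shares the
same run.  Scripted trajectories are built analytically (no dynamics) so the
transfer-analysis expectations are exact.
"""

import numpy as np
import pytest

import steerpmf as sp


@pytest.fixture(scope="session")
def stiffness_switch_run():
    """30 stiff-spring replicates across the k1 → e²·k1 switch (ΔF = 1 kT)."""
    return sp.run_scenario("stiffness_switch", seed_base=1)


@pytest.fixture(scope="session")
def dragged_trap_run():
    """30 replicates dragging a trap over a uniform landscape (ΔF = 0)."""
    return sp.run_scenario("dragged_trap", seed_base=1)


@pytest.fixture(scope="session")
def double_well_run():
    """30 replicates steered across the quartic double well (PMF known)."""
    return sp.run_scenario("double_well", seed_base=1)


def make_scripted_trajectory(kind: str, sampling_interval: float = 2.5):
    """Analytic five-atom trajectories exercising the pathway classifier.

    Atoms: 0 = donor acid oxygen, 1 = acid hydrogen, 2 = water oxygen,
    3 = water hydrogen, 4 = acceptor oxygen — collinear on the x-axis at
    acid 0.0, water 3.0, acceptor 6.0 Å.  Hydrogens glide smoothly between
    heavy atoms according to ``kind``:

    * ``"water_mediated"`` — the acid H transfers to the water at ~50 ps and
      the water H transfers to the acceptor 2.5 ps (one frame) later;
    * ``"direct"`` — the acid H passes the water midpoint region entirely
      and bonds to the acceptor; the water H stays put;
    * ``"none"`` — every hydrogen oscillates about its starting bond.
    """
    n_frames = 81
    times = np.arange(n_frames) * sampling_interval
    x_acid, x_water, x_acceptor = 0.0, 3.0, 6.0
    pos = np.zeros((n_frames, 5, 3))
    pos[:, 0, 0] = x_acid
    pos[:, 2, 0] = x_water
    pos[:, 4, 0] = x_acceptor

    def glide(t_switch, x_from, x_to, width=2.0):
        return x_from + (x_to - x_from) / (1.0 + np.exp(-(times - t_switch) / width))

    wiggle = 0.02 * np.sin(times)  # sub-hysteresis thermal jitter
    if kind == "water_mediated":
        pos[:, 1, 0] = glide(50.0, x_acid + 1.0, x_water - 1.0) + wiggle
        pos[:, 3, 0] = glide(52.5, x_water + 1.0, x_acceptor - 1.0) + wiggle
    elif kind == "direct":
        pos[:, 1, 0] = glide(50.0, x_acid + 1.0, x_acceptor - 1.0, width=1.0) + wiggle
        pos[:, 3, 0] = x_water + 1.0 + wiggle
    elif kind == "none":
        pos[:, 1, 0] = x_acid + 1.0 + wiggle
        pos[:, 3, 0] = x_water + 1.0 + wiggle
    else:
        raise ValueError(kind)

    return sp.Trajectory(
        times=times,
        positions=pos,
        cv_values=np.zeros(n_frames),
        restraint_energies=np.zeros(n_frames),
        metadata={"scripted": kind},
    )


SCRIPTED_ROLES = {
    "donor_acid": 0,
    "acid_hydrogen": 1,
    "water": 2,
    "water_hydrogen": 3,
    "acceptor": 4,
}


@pytest.fixture(scope="session")
def scripted_trajectories():
    return {kind: make_scripted_trajectory(kind)
            for kind in ("water_mediated", "direct", "none")}
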