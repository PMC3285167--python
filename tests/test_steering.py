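"""Steering protocol: snapshots, work accumulation, diagnostics."""

import io

import numpy as np
import pytest

import steerpmf as sp
from steerpmf.units import kt


def simple_protocol(**overrides):
    system = sp.make_system("dragged_harmonic_trap")
    restraint = sp.HarmonicPathRestraint(system.cv, k=1000.0,
                                         lambda0=1.0, lambda1=2.0)
    kwargs = dict(
        restraint=restraint, n_steps=1000, dt=0.005, n_replicates=4,
        seeds=(11, 12, 13, 14), snapshot_interval=100, integrator="baoab",
    )
    kwargs.update(overrides)
    return system, sp.SteeringProtocol(**kwargs)


class TestProtocolValidation:
    def test_duplicate_seeds_rejected(self):
        with pytest.raises(sp.ProtocolValidationError, match="distinct"):
            simple_protocol(seeds=(1, 1, 2, 3))

    def test_seed_count_must_match_replicates(self):
        with pytest.raises(sp.ProtocolValidationError):
            simple_protocol(seeds=(1, 2))

    def test_schedule_endpoints_exact(self):
        _, protocol = simple_protocol()
        lam = sp.lambda_schedule(protocol)
        assert lam[0] == protocol.restraint.lambda0
        assert lam[-1] == protocol.restraint.lambda1
        assert len(lam) == protocol.n_steps + 1

    def test_reversed_protocol_swaps_endpoints(self):
        _, protocol = simple_protocol()
        rev = protocol.reversed()
        assert rev.restraint.lambda0 == protocol.restraint.lambda1
        assert rev.restraint.lambda1 == protocol.restraint.lambda0


class TestSnapshots:
    def test_snapshot_count(self):
        system, protocol = simple_protocol()
        snaps = sp.generate_snapshots(system, protocol.restraint, 1000, 100,
                                      seed=1, dt=0.005, integrator="baoab")
        assert len(snaps) == 10

    def test_too_short_run_raises(self):
        system, protocol = simple_protocol()
        with pytest.raises(sp.InsufficientSnapshotsError):
            sp.generate_snapshots(system, protocol.restraint, 99, 100,
                                  seed=1, dt=0.005)
        with pytest.raises(sp.InsufficientSnapshotsError):
            sp.generate_snapshots(system, protocol.restraint, 500, 100,
                                  seed=1, dt=0.005, n_required=10)

    def test_snapshots_within_restraint_width(self):
        """Snapshot CVs stay within the equilibrium restraint width of λ0:
        essentially all inside 3·sqrt(kT/k) (Gaussian tail allowance), every
        one inside 6 widths."""
        system, protocol = simple_protocol()
        snaps = sp.generate_snapshots(system, protocol.restraint, 40_000, 100,
                                      seed=2, dt=0.005, integrator="baoab")
        width = np.sqrt(kt(300.0) / protocol.restraint.k)
        dev = np.abs(np.array([sp.eval_lcod(s.positions, system.cv)
                               for s in snaps]) - protocol.restraint.lambda0)
        assert np.mean(dev > 3 * width) < 0.01
        assert dev.max() < 6 * width

    def test_snapshot_cv_variance_matches_stiff_spring_width(self):
        """Restrained-run CV variance ≈ kT/k within 20% at 1e4 samples.

        Uses a softer spring with the overdamped integrator at a time step
        small enough that the Euler-Maruyama variance inflation (k·dt/2γ)
        is below 5%.
        """
        k = 50.0
        system = sp.make_system("dragged_harmonic_trap", gamma=0.1)
        restraint = sp.HarmonicPathRestraint(system.cv, k=k,
                                             lambda0=1.0, lambda1=2.0)
        snaps = sp.generate_snapshots(system, restraint, run_steps=300_000,
                                      snapshot_interval=30, seed=3, dt=0.0003)
        cvs = np.array([sp.eval_lcod(s.positions, system.cv) for s in snaps])
        assert len(cvs) == 10_000
        assert cvs.var() == pytest.approx(kt(300.0) / k, rel=0.20)


class TestRunReplicate:
    def test_null_steering_zero_work(self):
        system, protocol = simple_protocol()
        null = sp.SteeringProtocol(
            restraint=sp.HarmonicPathRestraint(system.cv, k=1000.0,
                                               lambda0=1.0, lambda1=1.0),
            n_steps=500, dt=0.005, n_replicates=1, seeds=(5,),
            snapshot_interval=100, integrator="baoab",
        )
        state = sp.LangevinState.initial(system)
        _, work, _ = sp.run_replicate(state, system, null, seed=5)
        np.testing.assert_array_equal(work, 0.0)

    def test_work_starts_at_zero_and_final_lambda_reached(self):
        system, protocol = simple_protocol()
        state = sp.LangevinState.initial(system)
        grid, work, cv = sp.run_replicate(state, system, protocol, seed=7)
        assert work[0] == 0.0
        assert grid[-1] == protocol.restraint.lambda1
        width = np.sqrt(kt(300.0) / protocol.restraint.k)
        assert abs(cv[-1] - grid[-1]) < 5 * width

    def test_determinism(self):
        system, protocol = simple_protocol()
        snaps = sp.generate_snapshots(system, protocol.restraint, 400, 100,
                                      seed=1, dt=0.005, integrator="baoab")
        e1 = sp.run_ensemble(system, protocol, snaps)
        e2 = sp.run_ensemble(system, protocol, snaps)
        np.testing.assert_array_equal(e1.works, e2.works)
        np.testing.assert_array_equal(e1.achieved_cv, e2.achieved_cv)

    def test_quasistatic_pulling_converges_to_free_energy(self, stiffness_switch_run):
        """Slow pulling on the stiffness switch recovers ΔF = 1 kT within 10%."""
        system, ensemble, pmf = stiffness_switch_run
        dF = sp.exact_free_energy(system, (ensemble.lambda_grid[0],
                                           ensemble.lambda_grid[-1]))
        assert pmf.raw_jarzynski[-1] == pytest.approx(dF, rel=0.10)


class TestRunEnsemble:
    def test_replicate_count_and_order(self, stiffness_switch_run):
        _, ensemble, _ = stiffness_switch_run
        assert ensemble.n_replicates == 30
        assert len(set(ensemble.seeds)) == 30
        assert ensemble.snapshot_indices == tuple(range(30))

    def test_final_work_dispersion_nonzero(self, stiffness_switch_run):
        _, ensemble, _ = stiffness_switch_run
        assert ensemble.final_works.std() > 0

    def test_insufficient_snapshots(self):
        system, protocol = simple_protocol()
        snaps = sp.generate_snapshots(system, protocol.restraint, 200, 100,
                                      seed=1, dt=0.005, integrator="baoab")
        with pytest.raises(sp.InsufficientSnapshotsError):
            sp.run_ensemble(system, protocol, snaps)

    def test_second_law_mean_work_bounds_free_energy(self, stiffness_switch_run,
                                                     dragged_trap_run):
        """⟨W⟩ ≥ ΔF on oracle systems (within Monte-Carlo error)."""
        for system, ensemble, _ in (stiffness_switch_run, dragged_trap_run):
            dF = sp.exact_free_energy(system, (ensemble.lambda_grid[0],
                                               ensemble.lambda_grid[-1]))
            mean_w = ensemble.final_works.mean()
            sem = ensemble.final_works.std(ddof=1) / np.sqrt(ensemble.n_replicates)
            assert mean_w >= dF - 3 * sem

    def test_crooks_consistency_forward_plus_reverse_dissipation(self):
        """On a time-symmetric system, ⟨W_f⟩ + ⟨W_r⟩ = total dissipation ≥ 0."""
        system, protocol = simple_protocol(n_steps=2000, n_replicates=8,
                                           seeds=tuple(range(21, 29)))
        snaps_f = sp.generate_snapshots(system, protocol.restraint, 800, 100,
                                        seed=1, dt=0.005, integrator="baoab")
        fwd = sp.run_ensemble(system, protocol, snaps_f)
        rev_protocol = protocol.reversed()
        # reverse pull starts from equilibrium at lambda1
        system_rev = sp.make_system("dragged_harmonic_trap",
                                    x0=protocol.restraint.lambda1)
        snaps_r = sp.generate_snapshots(system_rev, rev_protocol.restraint, 800, 100,
                                        seed=2, dt=0.005, integrator="baoab")
        rev = sp.run_ensemble(system_rev, rev_protocol, snaps_r)
        total = fwd.final_works.mean() + rev.final_works.mean()
        sem = np.hypot(fwd.final_works.std(ddof=1), rev.final_works.std(ddof=1)) / np.sqrt(8)
        assert total >= -3 * sem

    def test_tsv_round_trip(self, dragged_trap_run):
        _, ensemble, _ = dragged_trap_run
        buf = io.StringIO()
        ensemble.to_tsv(buf)
        buf.seek(0)
        back = sp.WorkEnsemble.from_tsv(buf)
        np.testing.assert_allclose(back.works, ensemble.works, atol=1e-9)
        np.testing.assert_allclose(back.lambda_grid, ensemble.lambda_grid)
        assert back.seeds == ensemble.seeds
        assert back.temperature == ensemble.temperature
        assert back.spring_k == ensemble.spring_k

    def test_work_must_start_at_zero(self):
        with pytest.raises(sp.DataValidationError):
            sp.WorkEnsemble(
                lambda_grid=np.array([0.0, 1.0]),
                works=np.array([[0.5, 1.0]]),
                achieved_cv=np.array([[0.0, 1.0]]),
                temperature=300.0, spring_k=100.0, seeds=(1,),
            )


class TestDiagnostics:
    def test_stiff_spring_tracks_target(self, stiffness_switch_run):
        """Stiff k: |lag| ≤ 4·sqrt(kT/k) in ≥95% of frames; slope ≈ 1."""
        _, ensemble, _ = stiffness_switch_run
        report = sp.steering_diagnostics(ensemble)
        assert not report.any_discontinuity
        slopes = [row.slope for row in report.replicates]
        for row in report.replicates:
            assert row.frac_large_lag <= 0.05
            # per-replicate slope noise from the finite restraint width
            assert row.slope == pytest.approx(1.0, abs=0.06)
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.01)

    def test_idealized_tracking_zero_lag_unit_slope(self):
        lam = np.linspace(1.0, 2.0, 11)
        ensemble = sp.WorkEnsemble(
            lambda_grid=lam, works=np.zeros((2, 11)),
            achieved_cv=np.vstack([lam, lam]),
            temperature=300.0, spring_k=1000.0, seeds=(1, 2),
        )
        report = sp.steering_diagnostics(ensemble)
        for row in report.replicates:
            assert row.max_lag == 0.0
            assert row.slope == pytest.approx(1.0)
            assert not (row.lag_flag or row.discontinuity_flag)

    def test_soft_spring_on_rough_landscape_raises_discontinuity_flag(self):
        """A deliberately soft spring across a deep wide double well sticks,
        then catches up in a jump larger than 10 restraint widths."""
        system = sp.make_system(
            "quartic_double_well", barrier_height=40.0, center=3.0,
            half_width=2.0, x0=1.0, gamma=0.05,
        )
        restraint = sp.HarmonicPathRestraint(system.cv, k=8.0,
                                             lambda0=1.0, lambda1=9.0)
        protocol = sp.SteeringProtocol(
            restraint=restraint, n_steps=4000, dt=0.005, n_replicates=3,
            seeds=(31, 32, 33), snapshot_interval=50, record_interval=200,
            integrator="baoab",
        )
        snaps = sp.generate_snapshots(system, restraint, 150, 50,
                                      seed=4, dt=0.005, integrator="baoab")
        ensemble = sp.run_ensemble(system, protocol, snaps)
        report = sp.steering_diagnostics(ensemble)
        assert report.any_discontinuity
        assert report.any_lag  # the stuck phase also trips the lag flag


class TestCombineReplicates:
    def test_shared_grids_pass_through(self):
        grid = np.linspace(0.0, 1.0, 5)
        w = np.array([0.0, 0.1, 0.2, 0.3, 0.4])
        ensemble = sp.combine_replicates(
            [(grid, w, grid), (grid, 2 * w, grid)], 300.0, 100.0, (1, 2)
        )
        np.testing.assert_array_equal(ensemble.works[1], 2 * w)

    def test_unequal_grids_interpolated(self):
        grid_a = np.linspace(0.0, 1.0, 5)
        grid_b = np.linspace(0.0, 1.0, 9)
        w_b = np.linspace(0.0, 0.8, 9)  # linear: interpolation is exact
        ensemble = sp.combine_replicates(
            [(grid_a, np.zeros(5), grid_a), (grid_b, w_b, grid_b)],
            300.0, 100.0, (1, 2),
        )
        np.testing.assert_allclose(ensemble.works[1], np.linspace(0.0, 0.8, 5),
                                   atol=1e-12)
        assert ensemble.lambda_grid.shape == (5,)
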