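"""Steered-dynamics protocol: snapshots, replicates, work accumulation.

The protocol mirrors standard stiff-spring steered MD practice:

1. a restrained pre-run holds the collective variable at its initial value
   λ0 and writes periodic snapshots, so all replicates start from the same
   restrained equilibrium ensemble;
2. each of N replicates starts from its own snapshot with its own PRNG seed
   and is pulled by moving the harmonic restraint centre linearly from λ0 to
   λ1 over ``n_steps`` integrator steps;
3. the external work is accumulated per step as W += (∂U/∂λ)·Δλ with
   ∂U/∂λ = −k(ξ − λ), using the midpoint rule in λ (exact for a constant
   integrand, consistent with one force evaluation per step);
4. work and achieved-CV curves are decimated to a common reporting λ grid.

Diagnostics quantify restraint lag (achieved CV behind the target) and
catch-up discontinuities — the failure mode of too-soft springs, where the
system sticks in a basin and then jumps.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import (
    DataValidationError,
    InsufficientSnapshotsError,
    IntegrationFailureError,
    ProtocolValidationError,
)
from .dynamics import LangevinState, ModelSystem, langevin_step
from .lcod import (
    HarmonicPathRestraint,
    eval_lcod,
    lcod_gradient,
    lcod_value_and_gradient,
)
from .units import kt

__all__ = [
    "SteeringProtocol",
    "WorkEnsemble",
    "lambda_schedule",
    "generate_snapshots",
    "run_replicate",
    "run_ensemble",
    "combine_replicates",
    "steering_diagnostics",
    "ReplicateDiagnostics",
    "DiagnosticsReport",
]


@dataclass(frozen=True)
class SteeringProtocol:
    """A complete steering prescription for one work ensemble.

    ``seeds`` must hold ``n_replicates`` pairwise-distinct integers.
    ``snapshot_interval`` (steps) spaces both the snapshots of the restrained
    pre-run and, by default, the reporting grid (``record_interval``).
    """

    restraint: HarmonicPathRestraint
    n_steps: int
    dt: float                       # ps
    n_replicates: int
    seeds: tuple[int, ...]
    snapshot_interval: int
    record_interval: int | None = None
    integrator: str = "overdamped"

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ProtocolValidationError("n_replicates must be >= 1")
        if len(self.seeds) != self.n_replicates:
            raise ProtocolValidationError(
                f"{self.n_replicates} replicates but {len(self.seeds)} seeds"
            )
        if len(set(self.seeds)) != len(self.seeds):
            raise ProtocolValidationError("replicate seeds must be pairwise distinct")
        if self.n_steps < 1:
            raise ProtocolValidationError("n_steps must be >= 1")
        if not self.dt > 0:
            raise ProtocolValidationError("dt must be positive")
        if self.snapshot_interval < 1:
            raise ProtocolValidationError("snapshot_interval must be >= 1")
        if self.record_interval is not None and self.record_interval < 1:
            raise ProtocolValidationError("record_interval must be >= 1")

    @property
    def effective_record_interval(self) -> int:
        r = self.snapshot_interval if self.record_interval is None else self.record_interval
        return min(r, self.n_steps)

    @property
    def duration(self) -> float:
        """Total steering time per replicate, ps."""
        return self.n_steps * self.dt

    @property
    def is_null_steering(self) -> bool:
        return self.restraint.lambda0 == self.restraint.lambda1

    def reversed(self, seeds: Sequence[int] | None = None) -> "SteeringProtocol":
        """The same protocol pulled λ1 → λ0 (for reverse-work sanity checks)."""
        rev = replace(self.restraint, lambda0=self.restraint.lambda1,
                      lambda1=self.restraint.lambda0)
        return replace(self, restraint=rev,
                       seeds=tuple(seeds) if seeds is not None else self.seeds)

    def hash(self) -> str:
        """Short stable hash of the protocol parameters (for file headers)."""
        payload = repr((
            self.restraint.spec.pairs, self.restraint.spec.coefficients,
            self.restraint.k, self.restraint.lambda0, self.restraint.lambda1,
            self.n_steps, self.dt, self.n_replicates, self.seeds,
            self.snapshot_interval, self.effective_record_interval, self.integrator,
        ))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def lambda_schedule(protocol: SteeringProtocol) -> np.ndarray:
    """The linear control-parameter schedule λ_j, j = 0..n_steps.

    Endpoints are exact: λ_0 = lambda0 and λ_{n_steps} = lambda1.
    """
    return np.linspace(protocol.restraint.lambda0, protocol.restraint.lambda1,
                       protocol.n_steps + 1)


def _record_indices(n_steps: int, interval: int) -> np.ndarray:
    idx = np.arange(0, n_steps + 1, interval)
    if idx[-1] != n_steps:
        idx = np.append(idx, n_steps)
    return idx


# ---------------------------------------------------------------------------
# Snapshot generation
# ---------------------------------------------------------------------------

def generate_snapshots(
    system: ModelSystem,
    restraint: HarmonicPathRestraint,
    run_steps: int,
    snapshot_interval: int,
    seed: int,
    dt: float,
    n_required: int | None = None,
    integrator: str = "overdamped",
) -> list[LangevinState]:
    """Equally spaced states from a run restrained at λ0.

    Integrates ``run_steps`` steps with the harmonic restraint held at
    ``restraint.lambda0`` and returns the states at steps ``interval``,
    ``2·interval``, … — ``floor(run_steps / snapshot_interval)`` snapshots.
    Raises :class:`InsufficientSnapshotsError` if fewer than ``n_required``
    (or fewer than one) would be produced.
    """
    count = run_steps // snapshot_interval
    need = 1 if n_required is None else n_required
    if count < need:
        raise InsufficientSnapshotsError(
            f"{run_steps} restrained steps at interval {snapshot_interval} yield "
            f"{count} snapshots; {need} required"
        )
    rng = np.random.default_rng(seed)
    spec, k, lam0 = restraint.spec, restraint.k, restraint.lambda0
    state = LangevinState.initial(system)
    snapshots: list[LangevinState] = []

    def restraint_forces(x):
        delta = eval_lcod(x, spec) - lam0
        return -k * delta * lcod_gradient(x, spec)

    for _ in range(run_steps):
        state = langevin_step(state, system, dt, restraint_forces, rng,
                              method=integrator)
        if state.step % snapshot_interval == 0:
            snapshots.append(state)
    return snapshots[:count]


# ---------------------------------------------------------------------------
# Replicates and ensembles
# ---------------------------------------------------------------------------

def run_replicate(
    initial_state: LangevinState,
    system: ModelSystem,
    protocol: SteeringProtocol,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Steer one replicate; returns ``(lambda_grid, work, achieved_cv)``.

    Work is accumulated every integrator step by the midpoint rule
    W += −k(ξ(x_j) − ½(λ_j + λ_{j+1}))·Δλ and reported on the decimated λ
    grid; W at λ0 is exactly zero and the final target λ1 is reached exactly
    (the last schedule point is λ1 by construction).
    """
    rng = np.random.default_rng(seed)
    spec = protocol.restraint.spec
    k = protocol.restraint.k
    lam = lambda_schedule(protocol)
    rec = _record_indices(protocol.n_steps, protocol.effective_record_interval)
    rec_set = set(int(i) for i in rec)

    x = initial_state.positions.copy()
    v = initial_state.velocities.copy()
    dt = protocol.dt
    mob = system.mobile
    kT = system.kt
    baoab = protocol.integrator == "baoab"
    if not baoab and protocol.integrator != "overdamped":
        raise ProtocolValidationError(
            f"unknown integrator {protocol.integrator!r}"
        )
    if baoab:
        m = system.masses[:, None]
        c1 = np.exp(-(system.gamma / m) * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * kT / m) if kT > 0 else np.zeros_like(c1)
    else:
        drift = dt / system.gamma
        sigma = np.sqrt(2.0 * kT * dt / system.gamma)

    work = 0.0
    works = [0.0]
    cv, grad = lcod_value_and_gradient(x, spec)
    f_sys = system.forces(x)
    cvs = [cv]
    for j in range(protocol.n_steps):
        dlam = lam[j + 1] - lam[j]
        work += -k * (cv - 0.5 * (lam[j] + lam[j + 1])) * dlam
        lam_t = lam[j + 1]
        f = f_sys - k * (cv - lam_t) * grad
        if baoab:
            v = np.where(mob, v + (0.5 * dt) * f / m, 0.0)
            x = np.where(mob, x + (0.5 * dt) * v, x)
            v = np.where(mob, c1 * v + c2 * rng.standard_normal(x.shape), 0.0)
            x = np.where(mob, x + (0.5 * dt) * v, x)
            cv, grad = lcod_value_and_gradient(x, spec)
            f_sys = system.forces(x)
            f_new = f_sys - k * (cv - lam_t) * grad
            v = np.where(mob, v + (0.5 * dt) * f_new / m, 0.0)
        else:
            noise = sigma * rng.standard_normal(x.shape) if kT > 0 else 0.0
            x = np.where(mob, x + drift * f + noise, x)
            cv, grad = lcod_value_and_gradient(x, spec)
            f_sys = system.forces(x)
        if not np.isfinite(cv):
            raise IntegrationFailureError(
                f"replicate seed {seed}: non-finite state at step {j + 1} "
                f"(system {system.name!r})"
            )
        if (j + 1) in rec_set:
            works.append(work)
            cvs.append(cv)
    return lam[rec], np.asarray(works), np.asarray(cvs)


@dataclass
class WorkEnsemble:
    """Per-replicate work-versus-λ functions on a common grid.

    ``works`` and ``achieved_cv`` have shape ``(n_replicates, n_grid)``;
    replicate order matches ``seeds`` and ``snapshot_indices``.
    """

    lambda_grid: np.ndarray
    works: np.ndarray
    achieved_cv: np.ndarray
    temperature: float
    spring_k: float
    seeds: tuple[int, ...]
    snapshot_indices: tuple[int, ...] = ()
    protocol: SteeringProtocol | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        self.works = np.atleast_2d(np.asarray(self.works, dtype=float))
        self.achieved_cv = np.atleast_2d(np.asarray(self.achieved_cv, dtype=float))
        if self.works.shape != self.achieved_cv.shape:
            raise DataValidationError("works and achieved_cv shapes differ")
        if self.works.shape[1] != len(self.lambda_grid):
            raise DataValidationError("works grid length mismatch")
        if not np.allclose(self.works[:, 0], 0.0, atol=1e-12):
            raise DataValidationError("W(lambda0) must be 0 for every replicate")
        d = np.diff(self.lambda_grid)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            if not np.all(d == 0):  # null steering keeps a constant grid
                raise DataValidationError(
                    "lambda_grid must be strictly monotone in the steering direction"
                )

    @property
    def n_replicates(self) -> int:
        return self.works.shape[0]

    @property
    def kt(self) -> float:
        return kt(self.temperature)

    @property
    def final_works(self) -> np.ndarray:
        return self.works[:, -1]

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path_or_buf) -> None:
        """Tab-separated: first column λ, then one work column and one
        achieved-CV column per replicate; header carries T, k, seeds and the
        protocol hash."""
        n = self.n_replicates
        meta = dict(self.metadata)
        meta.setdefault("temperature", self.temperature)
        meta.setdefault("spring_k", self.spring_k)
        meta.setdefault("seeds", ",".join(str(s) for s in self.seeds))
        if self.snapshot_indices:
            meta.setdefault("snapshot_indices",
                            ",".join(str(i) for i in self.snapshot_indices))
        if self.protocol is not None:
            meta.setdefault("protocol_hash", self.protocol.hash())
        lines = ["# steerpmf work ensemble"]
        for key in sorted(meta):
            lines.append(f"# {key}: {meta[key]}")
        cols = (["lambda"] + [f"W_{i}" for i in range(n)] + [f"cv_{i}" for i in range(n)])
        lines.append("\t".join(cols))
        table = np.column_stack([self.lambda_grid, self.works.T, self.achieved_cv.T])
        for row in table:
            lines.append("\t".join(format(v, ".12g") for v in row))
        text = "\n".join(lines) + "\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "WorkEnsemble":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        meta: dict = {}
        header: list[str] | None = None
        rows = []
        for line in text.splitlines():
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    key, _, value = stripped.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            if not line.strip():
                continue
            if header is None:
                header = line.split("\t")
                continue
            rows.append([float(v) for v in line.split("\t")])
        if header is None or not rows:
            raise DataValidationError("empty work-ensemble file")
        data = np.asarray(rows)
        n = sum(1 for c in header if c.startswith("W_"))
        seeds = tuple(int(s) for s in meta.get("seeds", "").split(",") if s) or tuple(range(n))
        snap = tuple(int(s) for s in meta.get("snapshot_indices", "").split(",") if s)
        return cls(
            lambda_grid=data[:, 0],
            works=data[:, 1:1 + n].T,
            achieved_cv=data[:, 1 + n:1 + 2 * n].T,
            temperature=float(meta.get("temperature", 300.0)),
            spring_k=float(meta.get("spring_k", 0.0)),
            seeds=seeds,
            snapshot_indices=snap,
            metadata=meta,
        )


def combine_replicates(
    replicates: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
    temperature: float,
    spring_k: float,
    seeds: Sequence[int],
) -> WorkEnsemble:
    """Assemble ``(grid, work, cv)`` triples into a :class:`WorkEnsemble`.

    Grids are shared by construction inside this package; if replicate grids
    differ (e.g. externally produced work files), works and achieved CVs are
    linearly interpolated onto the first replicate's grid as a robustness
    fallback.
    """
    if not replicates:
        raise DataValidationError("no replicates to combine")
    ref = np.asarray(replicates[0][0], dtype=float)
    works, cvs = [], []
    for grid, w, cv in replicates:
        grid = np.asarray(grid, dtype=float)
        if grid.shape == ref.shape and np.array_equal(grid, ref):
            works.append(np.asarray(w, dtype=float))
            cvs.append(np.asarray(cv, dtype=float))
        else:
            sign = 1.0 if (len(ref) < 2 or ref[-1] >= ref[0]) else -1.0
            works.append(np.interp(sign * ref, sign * grid, w))
            cvs.append(np.interp(sign * ref, sign * grid, cv))
    return WorkEnsemble(
        lambda_grid=ref,
        works=np.asarray(works),
        achieved_cv=np.asarray(cvs),
        temperature=temperature,
        spring_k=spring_k,
        seeds=tuple(seeds),
    )


def run_ensemble(
    system: ModelSystem,
    protocol: SteeringProtocol,
    snapshots: Sequence[LangevinState],
    snapshot_indices: Sequence[int] | None = None,
) -> WorkEnsemble:
    """Steer ``n_replicates`` replicates, one snapshot and one seed each.

    Snapshot ``i`` seeds replicate ``i`` (order preserved); requires at least
    ``n_replicates`` snapshots and pairwise-distinct seeds (enforced by the
    protocol).  Work values of non-finite magnitude abort with the replicate
    identified.
    """
    n = protocol.n_replicates
    if len(snapshots) < n:
        raise InsufficientSnapshotsError(
            f"{len(snapshots)} snapshots available but {n} replicates requested"
        )
    works = []
    cvs = []
    grid = None
    for i in range(n):
        grid_i, w, cv = run_replicate(snapshots[i], system, protocol, protocol.seeds[i])
        if not np.all(np.isfinite(w)):
            bad = int(np.flatnonzero(~np.isfinite(w))[0])
            raise DataValidationError(
                f"replicate {i} produced non-finite work at grid point {bad}"
            )
        grid = grid_i if grid is None else grid
        works.append(w)
        cvs.append(cv)
    idx = tuple(snapshot_indices) if snapshot_indices is not None else tuple(range(n))
    return WorkEnsemble(
        lambda_grid=grid,
        works=np.asarray(works),
        achieved_cv=np.asarray(cvs),
        temperature=system.temperature,
        spring_k=protocol.restraint.k,
        seeds=protocol.seeds,
        snapshot_indices=idx,
        protocol=protocol,
        metadata={"system": system.name},
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicateDiagnostics:
    """Lag and discontinuity statistics for one replicate."""

    replicate: int
    max_lag: float            # max |achieved CV − λ| over the grid, Å
    frac_large_lag: float     # fraction of frames with |lag| > 4·width
    max_jump: float           # largest inter-frame |ΔCV|, Å
    slope: float              # linear-fit slope of achieved CV vs target λ
    lag_flag: bool
    discontinuity_flag: bool


@dataclass(frozen=True)
class DiagnosticsReport:
    """Per-replicate diagnostics plus the thresholds that produced the flags.

    ``width`` is the equilibrium restraint width sqrt(kT/k); a replicate is
    flagged for discontinuity when any inter-frame CV jump exceeds
    ``jump_threshold`` = 10·width, and for lag when more than 5% of frames
    lag beyond 4·width.
    """

    replicates: tuple[ReplicateDiagnostics, ...]
    width: float
    jump_threshold: float
    lag_threshold: float

    @property
    def any_discontinuity(self) -> bool:
        return any(r.discontinuity_flag for r in self.replicates)

    @property
    def any_lag(self) -> bool:
        return any(r.lag_flag for r in self.replicates)

    @property
    def flagged(self) -> tuple[int, ...]:
        return tuple(r.replicate for r in self.replicates
                     if r.lag_flag or r.discontinuity_flag)


def steering_diagnostics(
    ensemble: WorkEnsemble,
    jump_multiple: float = 10.0,
    lag_multiple: float = 4.0,
    lag_fraction: float = 0.05,
) -> DiagnosticsReport:
    """Quantify restraint tracking quality for every replicate.

    Stiff-spring pulling should show achieved-vs-target curves that are
    straight lines of slope ≈ 1 with scatter set by the restraint width
    sqrt(kT/k) and no catch-up jumps; soft springs on rough landscapes show
    lag followed by large discontinuities.
    """
    if ensemble.spring_k <= 0:
        raise DataValidationError("ensemble spring_k must be positive for diagnostics")
    width = float(np.sqrt(ensemble.kt / ensemble.spring_k))
    jump_thr = jump_multiple * width
    lag_thr = lag_multiple * width
    lam = ensemble.lambda_grid
    rows = []
    for i in range(ensemble.n_replicates):
        cv = ensemble.achieved_cv[i]
        lag = np.abs(cv - lam)
        jumps = np.abs(np.diff(cv))
        max_jump = float(jumps.max()) if len(jumps) else 0.0
        frac = float(np.mean(lag > lag_thr))
        if np.ptp(lam) > 0:
            slope = float(np.polyfit(lam, cv, 1)[0])
        else:
            slope = 1.0  # null steering: target constant, slope undefined
        rows.append(ReplicateDiagnostics(
            replicate=i,
            max_lag=float(lag.max()),
            frac_large_lag=frac,
            max_jump=max_jump,
            slope=slope,
            lag_flag=frac > lag_fraction,
            discontinuity_flag=max_jump > jump_thr,
        ))
    return DiagnosticsReport(tuple(rows), width, jump_thr, lag_thr)
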