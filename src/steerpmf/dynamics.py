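"""Langevin toy systems with exact free-energy oracles.

This module is the synthetic-data generator of the package.  It stands in for
a full molecular-dynamics engine: a handful of analytically tractable model
potentials, integrated with Langevin dynamics at fixed temperature, generate
trajectories and nonequilibrium work ensembles that are statistically faithful
inputs for the steering and Jarzynski-estimation machinery — while admitting
deterministic Boltzmann-quadrature oracles for the free energies the
estimators are supposed to recover.

All systems live on the x-axis: atoms carry full 3-D coordinates (so the LCOD
machinery applies unchanged), but only selected x-components are mobile.  With
a frozen anchor atom at the origin and mobile atoms kept at x > 0, the LCOD
distance CV coincides with the x-coordinate and every oracle reduces to a 1-D
(or separable 2-D) quadrature.

Model systems
-------------
``dragged_harmonic_trap``
    A free particle on a uniform landscape (optionally confined by a static
    harmonic well of stiffness ``k_well`` for integrator validation).
    Dragging a harmonic restraint across it does no net reversible work:
    ΔF = 0 exactly.
``stiffness_switch``
    A transverse harmonic mode whose stiffness interpolates geometrically
    from ``k1`` to ``k2`` as the pulled coordinate crosses a switch window.
    ΔF = (kB T / 2) ln(k2/k1); with k2 = e²·k1 this is exactly 1 kT.
``quartic_double_well``
    U(x) = h·(u² − 1)² + tilt·u with u = (x − center)/half_width: two minima,
    one interior barrier of height h (at tilt = 0).  The PMF equals U up to a
    constant.
``three_atom_transfer``
    Collinear donor–H–acceptor with a double-well potential for the hydrogen:
    supports spontaneous (unforced) transfer events at moderate barriers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Sequence

import numpy as np

from .errors import (
    IntegrationFailureError,
    UnknownSystemError,
    UnsupportedOracleError,
)
from .lcod import LCODSpec, eval_lcod
from .units import kt

__all__ = [
    "ModelSystem",
    "LangevinState",
    "TrajectoryFrame",
    "Trajectory",
    "make_system",
    "langevin_step",
    "run_langevin",
    "exact_free_energy",
    "boltzmann_density",
    "SYSTEM_NAMES",
]


# ---------------------------------------------------------------------------
# Potentials
# ---------------------------------------------------------------------------

class _Quartic1D:
    """h·(u²−1)² + tilt·u acting on the x-coordinate of one atom."""

    def __init__(self, atom: int, h: float, center: float, half_width: float, tilt: float):
        self.atom = atom
        self.h = h
        self.center = center
        self.half_width = half_width
        self.tilt = tilt

    def u1d(self, q):
        u = (np.asarray(q) - self.center) / self.half_width
        return self.h * (u * u - 1.0) ** 2 + self.tilt * u

    def du1d(self, q):
        u = (np.asarray(q) - self.center) / self.half_width
        return (4.0 * self.h * u * (u * u - 1.0) + self.tilt) / self.half_width

    def energy(self, frame) -> float:
        return float(self.u1d(frame[self.atom, 0]))

    def forces(self, frame) -> np.ndarray:
        f = np.zeros_like(frame)
        f[self.atom, 0] = -self.du1d(frame[self.atom, 0])
        return f


class _HarmonicWells1D:
    """Independent harmonic wells (k_well/2)(x−x0)² on the x-coordinates of
    a set of atoms; k_well = 0 gives a uniform landscape."""

    def __init__(self, atoms: Sequence[int], k_well: float, center: float):
        self.atoms = tuple(atoms)
        self.k_well = k_well
        self.center = center

    def u1d(self, q):
        return 0.5 * self.k_well * (np.asarray(q) - self.center) ** 2

    def energy(self, frame) -> float:
        if self.k_well == 0.0:
            return 0.0
        dx = frame[list(self.atoms), 0] - self.center
        return float(0.5 * self.k_well * np.dot(dx, dx))

    def forces(self, frame) -> np.ndarray:
        f = np.zeros_like(frame)
        if self.k_well != 0.0:
            idx = list(self.atoms)
            f[idx, 0] = -self.k_well * (frame[idx, 0] - self.center)
        return f


class _StiffnessSwitch:
    """Transverse harmonic mode 0.5·k(q)·y² with geometric stiffness switch.

    q is the x-coordinate of ``pull_atom``, y the x-coordinate of
    ``transverse_atom``.  ln k(q) interpolates linearly from ln k1 to ln k2
    across the window [q_lo, q_hi]; outside the window it is clamped, so the
    free-energy difference across the window is (kT/2)·ln(k2/k1) exactly.
    """

    def __init__(self, pull_atom: int, transverse_atom: int,
                 k1: float, k2: float, q_lo: float, q_hi: float):
        self.pull_atom = pull_atom
        self.transverse_atom = transverse_atom
        self.k1 = k1
        self.k2 = k2
        self.q_lo = q_lo
        self.q_hi = q_hi
        self._log_ratio = np.log(k2 / k1)

    def stiffness(self, q):
        s = np.clip((np.asarray(q) - self.q_lo) / (self.q_hi - self.q_lo), 0.0, 1.0)
        return self.k1 * np.exp(s * self._log_ratio)

    def _dstiffness(self, q):
        inside = (q > self.q_lo) & (q < self.q_hi)
        return np.where(
            inside,
            self.stiffness(q) * self._log_ratio / (self.q_hi - self.q_lo),
            0.0,
        )

    def energy(self, frame) -> float:
        q = frame[self.pull_atom, 0]
        y = frame[self.transverse_atom, 0]
        return float(0.5 * self.stiffness(q) * y * y)

    def forces(self, frame) -> np.ndarray:
        q = frame[self.pull_atom, 0]
        y = frame[self.transverse_atom, 0]
        f = np.zeros_like(frame)
        f[self.transverse_atom, 0] = -self.stiffness(q) * y
        f[self.pull_atom, 0] = -0.5 * float(self._dstiffness(q)) * y * y
        return f


# ---------------------------------------------------------------------------
# Model systems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSystem:
    """A fully parameterized toy system ready for Langevin integration.

    ``mobile`` is a per-coordinate boolean mask; frozen coordinates never
    move and receive no thermal noise.  ``gamma`` is the overdamped drag
    coefficient in kcal·ps/(mol·Å²) (diffusion constant D = kT/γ), ``masses``
    are amu-like and only matter for the underdamped (BAOAB) integrator.
    """

    name: str
    n_atoms: int
    positions0: np.ndarray      # (n_atoms, 3)
    mobile: np.ndarray          # (n_atoms, 3) bool
    masses: np.ndarray          # (n_atoms,)
    gamma: float                # kcal ps / (mol Å²)
    temperature: float          # K
    parameters: dict
    cv: LCODSpec
    _pot: object = field(repr=False, compare=False)

    def potential_energy(self, frame) -> float:
        return self._pot.energy(np.asarray(frame, dtype=float))

    def forces(self, frame) -> np.ndarray:
        return self._pot.forces(np.asarray(frame, dtype=float))

    @property
    def kt(self) -> float:
        return kt(self.temperature)

    def with_temperature(self, temperature: float) -> "ModelSystem":
        return replace(self, temperature=float(temperature))


_COMMON_DEFAULTS = dict(temperature=300.0, gamma=0.5, mass=1.0)

_SYSTEM_DEFAULTS: dict[str, dict] = {
    "dragged_harmonic_trap": dict(
        n_particles=1, x0=1.0, k_well=0.0, well_center=1.0, **_COMMON_DEFAULTS
    ),
    "stiffness_switch": dict(
        k1=5.0, k2=5.0 * float(np.exp(2.0)), q_lo=1.0, q_hi=2.5, x0=1.0,
        **_COMMON_DEFAULTS,
    ),
    "quartic_double_well": dict(
        barrier_height=2.0, center=2.0, half_width=1.0, tilt=0.0, x0=1.0,
        **_COMMON_DEFAULTS,
    ),
    "three_atom_transfer": dict(
        barrier_height=1.5, d_da=2.8, r_bond=1.0, **_COMMON_DEFAULTS
    ),
}

SYSTEM_NAMES = tuple(_SYSTEM_DEFAULTS)


def make_system(name: str, **overrides) -> ModelSystem:
    """Construct a named model system with documented defaults.

    Any default parameter (including ``temperature``, ``gamma``, ``mass``)
    may be overridden by keyword.  Unknown system names or parameters raise
    :class:`UnknownSystemError` / ``ValueError``.
    """
    if name not in _SYSTEM_DEFAULTS:
        raise UnknownSystemError(
            f"unknown system {name!r}; available: {', '.join(SYSTEM_NAMES)}"
        )
    params = dict(_SYSTEM_DEFAULTS[name])
    for key, value in overrides.items():
        if key not in params:
            raise ValueError(f"unknown parameter {key!r} for system {name!r}")
        params[key] = value
    if not params["gamma"] > 0:
        raise ValueError("gamma must be positive")
    if not params["mass"] > 0:
        raise ValueError("mass must be positive")
    if params["temperature"] < 0:
        raise ValueError("temperature must be >= 0")

    if name == "dragged_harmonic_trap":
        m = int(params["n_particles"])
        n = 1 + m
        pos = np.zeros((n, 3))
        pos[1:, 0] = params["x0"]
        mobile = np.zeros((n, 3), bool)
        mobile[1:, 0] = True
        pot = _HarmonicWells1D(range(1, n), float(params["k_well"]), float(params["well_center"]))
        cv = LCODSpec([(0, 1)], [1.0])
    elif name == "stiffness_switch":
        n = 3  # anchor, pulled coordinate, transverse mode
        pos = np.array([[0.0, 0.0, 0.0], [params["x0"], 0.0, 0.0], [0.0, 1.0, 0.0]])
        mobile = np.zeros((n, 3), bool)
        mobile[1, 0] = True
        mobile[2, 0] = True
        if not (params["k1"] > 0 and params["k2"] > 0):
            raise ValueError("stiffness_switch requires k1, k2 > 0")
        pot = _StiffnessSwitch(1, 2, float(params["k1"]), float(params["k2"]),
                               float(params["q_lo"]), float(params["q_hi"]))
        cv = LCODSpec([(0, 1)], [1.0])
    elif name == "quartic_double_well":
        n = 2
        pos = np.array([[0.0, 0.0, 0.0], [params["x0"], 0.0, 0.0]])
        mobile = np.zeros((n, 3), bool)
        mobile[1, 0] = True
        pot = _Quartic1D(1, float(params["barrier_height"]), float(params["center"]),
                         float(params["half_width"]), float(params["tilt"]))
        cv = LCODSpec([(0, 1)], [1.0])
    else:  # three_atom_transfer
        n = 3  # donor, hydrogen, acceptor
        d_da = float(params["d_da"])
        r_bond = float(params["r_bond"])
        half_width = 0.5 * d_da - r_bond
        if not half_width > 0:
            raise ValueError("three_atom_transfer requires d_da > 2*r_bond")
        pos = np.array([[0.0, 0.0, 0.0], [r_bond, 0.0, 0.0], [d_da, 0.0, 0.0]])
        mobile = np.zeros((n, 3), bool)
        mobile[1, 0] = True
        pot = _Quartic1D(1, float(params["barrier_height"]), 0.5 * d_da, half_width, 0.0)
        # proton-transfer coordinate d(donor,H) - d(acceptor,H)
        cv = LCODSpec([(0, 1), (2, 1)], [1.0, -1.0])

    return ModelSystem(
        name=name,
        n_atoms=n,
        positions0=pos,
        mobile=mobile,
        masses=np.full(n, float(params["mass"])),
        gamma=float(params["gamma"]),
        temperature=float(params["temperature"]),
        parameters=params,
        cv=cv,
        _pot=pot,
    )


# ---------------------------------------------------------------------------
# Integrators
# ---------------------------------------------------------------------------

@dataclass
class LangevinState:
    """Instantaneous integrator state."""

    positions: np.ndarray          # (n_atoms, 3)
    velocities: np.ndarray         # (n_atoms, 3); unused by the overdamped scheme
    time: float = 0.0              # ps
    step: int = 0

    @classmethod
    def initial(cls, system: ModelSystem) -> "LangevinState":
        return cls(system.positions0.copy(), np.zeros_like(system.positions0))


def _external(external_forces, frame):
    if external_forces is None:
        return 0.0
    if callable(external_forces):
        return external_forces(frame)
    return np.asarray(external_forces, dtype=float)


def langevin_step(
    state: LangevinState,
    system: ModelSystem,
    dt: float,
    external_forces=None,
    rng: np.random.Generator | None = None,
    method: str = "overdamped",
) -> LangevinState:
    """Advance the state by one Langevin step.

    ``external_forces`` may be ``None``, a constant ``(n_atoms, 3)`` array, or
    a callable ``frame -> forces`` (required by BAOAB's second force
    evaluation).  Identical rng states give identical updates.  ``method`` is
    ``"overdamped"`` (Euler–Maruyama, the default) or ``"baoab"``.
    """
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    rng = np.random.default_rng(0) if rng is None else rng
    x = state.positions
    mob = system.mobile
    kT = system.kt

    if method == "overdamped":
        f = system.forces(x) + _external(external_forces, x)
        sigma = np.sqrt(2.0 * kT * dt / system.gamma)
        noise = sigma * rng.standard_normal(x.shape) if kT > 0 else 0.0
        x_new = np.where(mob, x + (dt / system.gamma) * f + noise, x)
        v_new = state.velocities
    elif method == "baoab":
        m = system.masses[:, None]
        gamma_rate = system.gamma / m  # collision frequency, 1/ps
        f = system.forces(x) + _external(external_forces, x)
        v = np.where(mob, state.velocities + 0.5 * dt * f / m, 0.0)
        x_half = np.where(mob, x + 0.5 * dt * v, x)
        c1 = np.exp(-gamma_rate * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * kT / m)
        noise = c2 * rng.standard_normal(x.shape) if kT > 0 else 0.0
        v = np.where(mob, c1 * v + noise, 0.0)
        x_new = np.where(mob, x_half + 0.5 * dt * v, x)
        f_new = system.forces(x_new) + _external(external_forces, x_new)
        v_new = np.where(mob, v + 0.5 * dt * f_new / m, 0.0)
    else:
        raise ValueError(f"unknown integrator method {method!r}")

    if not np.all(np.isfinite(x_new)):
        raise IntegrationFailureError(
            f"non-finite positions after step {state.step + 1} "
            f"(t = {state.time + dt:.6g} ps, system {system.name!r})"
        )
    return LangevinState(x_new, np.asarray(v_new), state.time + dt, state.step + 1)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryFrame:
    """One recorded frame of a trajectory."""

    time: float                 # ps
    positions: np.ndarray       # (n_atoms, 3), Å
    cv_value: float             # Å
    restraint_energy: float     # kcal/mol


@dataclass
class Trajectory:
    """Time-ordered frames at a fixed sampling interval, plus metadata.

    Stored as arrays (times ``(m,)``, positions ``(m, n, 3)``, cv values and
    restraint energies ``(m,)``) for vectorized analysis; :meth:`frames`
    iterates :class:`TrajectoryFrame` views.
    """

    times: np.ndarray
    positions: np.ndarray
    cv_values: np.ndarray
    restraint_energies: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
                raise ValueError("trajectory frames must be time-ordered at a fixed interval")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def sampling_interval(self) -> float:
        if len(self.times) < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def frames(self) -> Iterator[TrajectoryFrame]:
        for i in range(self.n_frames):
            yield TrajectoryFrame(
                float(self.times[i]), self.positions[i],
                float(self.cv_values[i]), float(self.restraint_energies[i]),
            )

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path_or_buf) -> None:
        """Write a tab-separated table with a ``#``-prefixed metadata header."""
        n_atoms = self.positions.shape[1]
        cols = ["time"] + [f"{ax}{i}" for i in range(n_atoms) for ax in "xyz"]
        cols += ["cv_value", "restraint_energy"]
        data = np.column_stack([
            self.times, self.positions.reshape(self.n_frames, -1),
            self.cv_values, self.restraint_energies,
        ])
        lines = ["# steerpmf trajectory"]
        for key in sorted(self.metadata):
            lines.append(f"# {key}: {self.metadata[key]}")
        lines.append("\t".join(cols))
        for row in data:
            lines.append("\t".join(format(v, ".10g") for v in row))
        text = "\n".join(lines) + "\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "Trajectory":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        meta: dict = {}
        body = []
        header_cols: list[str] | None = None
        for line in text.splitlines():
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    key, _, value = stripped.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            if not line.strip():
                continue
            if header_cols is None:
                header_cols = line.split("\t")
                continue
            body.append([float(v) for v in line.split("\t")])
        data = np.asarray(body)
        n_atoms = (data.shape[1] - 3) // 3
        return cls(
            times=data[:, 0],
            positions=data[:, 1:1 + 3 * n_atoms].reshape(-1, n_atoms, 3),
            cv_values=data[:, 1 + 3 * n_atoms],
            restraint_energies=data[:, 2 + 3 * n_atoms],
            metadata=meta,
        )

    def to_hdf5(self, path, group: str = "trajectory") -> None:
        """Optional HDF5 container with the same schema as the TSV format."""
        import h5py

        with h5py.File(path, "a") as fh:
            if group in fh:
                del fh[group]
            g = fh.create_group(group)
            g.create_dataset("times", data=self.times)
            g.create_dataset("positions", data=self.positions)
            g.create_dataset("cv_values", data=self.cv_values)
            g.create_dataset("restraint_energies", data=self.restraint_energies)
            for key, value in self.metadata.items():
                g.attrs[key] = str(value)

    @classmethod
    def from_hdf5(cls, path, group: str = "trajectory") -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as fh:
            g = fh[group]
            return cls(
                times=g["times"][()],
                positions=g["positions"][()],
                cv_values=g["cv_values"][()],
                restraint_energies=g["restraint_energies"][()],
                metadata={k: g.attrs[k] for k in g.attrs},
            )


def run_langevin(
    system: ModelSystem,
    n_steps: int,
    dt: float,
    seed: int | np.random.Generator = 0,
    restraint: Callable[[np.ndarray], tuple[float, np.ndarray]] | None = None,
    record_interval: int = 1,
    method: str = "overdamped",
) -> Trajectory:
    """Integrate ``n_steps`` of Langevin dynamics and record every
    ``record_interval`` steps (frame 0 included).

    ``restraint``, if given, is a callable ``frame -> (energy, forces)`` —
    e.g. ``lambda x: restraint_energy_force(x, r, lam)`` for a static
    harmonic restraint, or a flat-well closure.  The CV recorded per frame is
    the system's default CV.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = LangevinState.initial(system)

    def record(state):
        if restraint is not None:
            e, _ = restraint(state.positions)
        else:
            e = 0.0
        times.append(state.time)
        positions.append(state.positions.copy())
        cvs.append(eval_lcod(state.positions, system.cv))
        energies.append(e)

    times: list = []
    positions: list = []
    cvs: list = []
    energies: list = []
    record(state)
    ext = None if restraint is None else (lambda x: restraint(x)[1])
    for _ in range(n_steps):
        state = langevin_step(state, system, dt, ext, rng, method=method)
        if state.step % record_interval == 0:
            record(state)
    return Trajectory(
        times=np.asarray(times),
        positions=np.asarray(positions),
        cv_values=np.asarray(cvs),
        restraint_energies=np.asarray(energies),
        metadata={
            "system": system.name,
            "dt": dt,
            "n_steps": n_steps,
            "record_interval": record_interval,
            "temperature": system.temperature,
            "seed": seed if not isinstance(seed, np.random.Generator) else "generator",
            "integrator": method,
        },
    )


# ---------------------------------------------------------------------------
# Exact oracles
# ---------------------------------------------------------------------------

def _cv_potential_1d(system: ModelSystem):
    """The potential as a function of the CV coordinate for separable systems."""
    pot = system._pot
    if isinstance(pot, _Quartic1D):
        return pot.u1d
    if isinstance(pot, _HarmonicWells1D):
        return pot.u1d
    return None


def exact_free_energy(system: ModelSystem, cv):
    """Exact free energy along the CV by deterministic Boltzmann quadrature.

    ``cv`` is either a monotone grid (array or list) of CV values — the
    return is the PMF array referenced to zero at the first grid point — or a
    two-element *tuple* ``(a, b)`` of endpoints — the return is the scalar
    ΔF = F(b) − F(a) in kcal/mol.  Only separable systems are supported;
    anything else raises :class:`UnsupportedOracleError`.
    """
    if system.temperature <= 0:
        raise UnsupportedOracleError("free-energy oracle requires T > 0")
    kT = system.kt
    cv_arr = np.atleast_1d(np.asarray(cv, dtype=float))
    pair = isinstance(cv, tuple) and len(cv) == 2

    pot = system._pot
    u1d = _cv_potential_1d(system)
    if u1d is not None:
        # Single-coordinate marginal: F(q) = −kT ln e^{−βU(q)} + const = U(q) + const.
        f = np.asarray(u1d(cv_arr), dtype=float)
    elif isinstance(pot, _StiffnessSwitch):
        # Integrate out the transverse mode at each q on a fixed wide grid.
        k_min = min(pot.k1, pot.k2)
        width = np.sqrt(kT / k_min)
        y = np.linspace(-8.0 * width, 8.0 * width, 4001)
        k_q = pot.stiffness(cv_arr)[:, None]
        boltz = np.exp(-0.5 * k_q * y[None, :] ** 2 / kT)
        f = -kT * np.log(np.trapezoid(boltz, y, axis=1))
    else:
        raise UnsupportedOracleError(
            f"no exact free-energy oracle for system {system.name!r}"
        )
    f = f - f[0]
    if pair:
        return float(f[1])
    return f if np.ndim(cv) else float(f[0])


def boltzmann_density(system: ModelSystem, grid: np.ndarray) -> np.ndarray:
    """Normalized equilibrium density of the CV coordinate on ``grid``.

    Deterministic quadrature oracle for equilibrium-sampling tests; only
    systems whose CV coordinate has a confining 1-D potential are supported.
    """
    if system.temperature <= 0:
        raise UnsupportedOracleError("Boltzmann density requires T > 0")
    u1d = _cv_potential_1d(system)
    if u1d is None:
        raise UnsupportedOracleError(
            f"no 1-D Boltzmann-density oracle for system {system.name!r}"
        )
    grid = np.asarray(grid, dtype=float)
    u = np.asarray(u1d(grid), dtype=float)
    p = np.exp(-(u - u.min()) / system.kt)
    z = np.trapezoid(p, grid)
    if not z > 0:
        raise UnsupportedOracleError("density not normalizable on the given grid")
    return p / z
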