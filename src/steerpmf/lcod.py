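"""Linear-combination-of-distances (LCOD) collective variables and restraints.

An LCOD variable is specified by an ordered list of atom-index pairs
``(a_i, b_i)`` and an equally long list of signed real coefficients ``c_i``;
its value on a coordinate frame is

.. math::  \\xi(r) = \\sum_i c_i \\, \\lVert r_{a_i} - r_{b_i} \\rVert .

With two pairs sharing a hydrogen, coefficients ``(+1, -1)``, this is the
classic proton-transfer coordinate ``d(donor,H) - d(acceptor,H)``: negative
while the proton is donor-bound, zero at the midpoint of the donor–acceptor
separation, positive after transfer.

Steering applies a harmonic restraint ``(k/2)(\\xi - \\lambda)^2`` whose centre
λ moves along a line segment between two endpoints.  A flat-well spherical
restraint (zero inside a radius, harmonic wall outside) is provided to keep
satellite atoms — e.g. an active-site water — near a centre atom without
biasing their interior motion.

Atom indices are zero-based.  Frames are ``(n_atoms, 3)`` float arrays in Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "LCODSpec",
    "HarmonicPathRestraint",
    "FlatWellRestraint",
    "eval_lcod",
    "lcod_gradient",
    "restraint_energy_force",
    "flat_well_energy_force",
    "resolve_selection",
    "spec_from_triples",
]


@dataclass(frozen=True)
class LCODSpec:
    """An LCOD collective variable: atom pairs plus signed coefficients.

    Parameters
    ----------
    pairs
        Ordered atom-index pairs ``(a_i, b_i)``.  Atoms may repeat across
        pairs (shared-hydrogen proton-transfer coordinates rely on this).
    coefficients
        Signed dimensionless coefficients ``c_i``, one per pair.
    """

    pairs: tuple[tuple[int, int], ...]
    coefficients: tuple[float, ...]

    def __init__(self, pairs: Sequence[Sequence[int]], coefficients: Sequence[float]):
        pairs_t = tuple((int(a), int(b)) for a, b in pairs)
        coeffs_t = tuple(float(c) for c in coefficients)
        if len(pairs_t) < 1:
            raise ValueError("LCODSpec needs at least one atom pair")
        if len(pairs_t) != len(coeffs_t):
            raise ValueError(
                f"LCODSpec: {len(pairs_t)} pairs but {len(coeffs_t)} coefficients"
            )
        if any(a < 0 or b < 0 for a, b in pairs_t):
            raise IndexError("LCODSpec: atom indices must be non-negative")
        object.__setattr__(self, "pairs", pairs_t)
        object.__setattr__(self, "coefficients", coeffs_t)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def _arrays(self):
        """Cached (a_idx, b_idx, coeff) arrays for vectorized evaluation."""
        cached = self.__dict__.get("_arrays_cache")
        if cached is None:
            cached = (
                np.fromiter((a for a, _ in self.pairs), dtype=np.intp),
                np.fromiter((b for _, b in self.pairs), dtype=np.intp),
                np.asarray(self.coefficients, dtype=float),
            )
            object.__setattr__(self, "_arrays_cache", cached)
        return cached

    @property
    def max_atom(self) -> int:
        return max(max(a, b) for a, b in self.pairs)

    def negated(self) -> "LCODSpec":
        """The CV with every coefficient negated (value flips sign)."""
        return LCODSpec(self.pairs, tuple(-c for c in self.coefficients))


@dataclass(frozen=True)
class HarmonicPathRestraint:
    """Harmonic steering restraint ``(k/2)(ξ − λ)²`` on an LCOD variable.

    ``lambda0`` and ``lambda1`` are the endpoints of the linear path the
    restraint centre follows during steering; both are CV values in Å.
    """

    spec: LCODSpec
    k: float  # kcal/(mol Å²)
    lambda0: float  # Å
    lambda1: float  # Å

    def __post_init__(self):
        if not self.k > 0:
            raise ValueError(f"spring constant must be positive, got {self.k}")
        for name in ("lambda0", "lambda1"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def lambda_at(self, fraction: float) -> float:
        """Restraint centre at ``fraction`` ∈ [0, 1] along the linear path."""
        return self.lambda0 + fraction * (self.lambda1 - self.lambda0)


@dataclass(frozen=True)
class FlatWellRestraint:
    """Zero inside a sphere, harmonic outside: keeps satellites near a centre.

    Each satellite at distance ``d`` from the centre atom contributes
    ``0`` when ``d ≤ radius`` and ``(k_wall/2)(d − radius)²`` otherwise, so
    the energy is continuous and once-differentiable at the wall.
    """

    center_atom: int
    satellite_atoms: tuple[int, ...] = field(default_factory=tuple)
    radius: float = 3.0  # Å
    k_wall: float = 10.0  # kcal/(mol Å²)

    def __init__(self, center_atom, satellite_atoms, radius=3.0, k_wall=10.0):
        object.__setattr__(self, "center_atom", int(center_atom))
        object.__setattr__(self, "satellite_atoms", tuple(int(a) for a in satellite_atoms))
        object.__setattr__(self, "radius", float(radius))
        object.__setattr__(self, "k_wall", float(k_wall))
        if not self.radius > 0:
            raise ValueError(f"flat-well radius must be positive, got {radius}")
        if self.k_wall < 0:
            raise ValueError(f"k_wall must be non-negative, got {k_wall}")


def _check_frame(frame: np.ndarray, spec: LCODSpec) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[1] != 3:
        raise ValueError(f"frame must have shape (n_atoms, 3), got {frame.shape}")
    if spec.max_atom >= frame.shape[0]:
        raise IndexError(
            f"LCOD atom index {spec.max_atom} out of range for frame with "
            f"{frame.shape[0]} atoms"
        )
    return frame


def eval_lcod(frame: np.ndarray, spec: LCODSpec) -> float:
    """Evaluate Σ_i c_i ‖r(a_i) − r(b_i)‖ on one coordinate frame (Å).

    A pair with identical atoms contributes zero and triggers a warning; the
    gradient is undefined there, but the value itself is well defined.
    """
    frame = _check_frame(frame, spec)
    value = 0.0
    for (a, b), c in zip(spec.pairs, spec.coefficients):
        if a == b:
            warnings.warn(
                f"LCOD pair ({a}, {b}) has identical atoms; contributes 0",
                stacklevel=2,
            )
            continue
        value += c * float(np.linalg.norm(frame[a] - frame[b]))
    return value


def lcod_gradient(frame: np.ndarray, spec: LCODSpec) -> np.ndarray:
    """Analytic per-atom gradient ∂ξ/∂r, shape ``(n_atoms, 3)``.

    Atoms not referenced by the spec have zero gradient; atoms repeated
    across pairs accumulate contributions additively.  A pair at zero
    separation raises :class:`DegenerateGeometryError` (the distance
    gradient is undefined there).
    """
    frame = _check_frame(frame, spec)
    grad = np.zeros_like(frame)
    for (a, b), c in zip(spec.pairs, spec.coefficients):
        dvec = frame[a] - frame[b]
        d = float(np.linalg.norm(dvec))
        if d == 0.0:
            raise DegenerateGeometryError(
                f"LCOD pair ({a}, {b}) at zero separation: gradient undefined"
            )
        unit = dvec / d
        grad[a] += c * unit
        grad[b] -= c * unit
    return grad


def lcod_value_and_gradient(frame: np.ndarray, spec: LCODSpec) -> tuple[float, np.ndarray]:
    """CV value and analytic gradient in one pass (the steering hot path).

    Equivalent to ``(eval_lcod(frame, spec), lcod_gradient(frame, spec))``
    except that an identical-atom pair is an error here (the gradient is
    always needed).
    """
    a_idx, b_idx, coeffs = spec._arrays
    if spec.max_atom >= frame.shape[0]:
        raise IndexError(
            f"LCOD atom index {spec.max_atom} out of range for frame with "
            f"{frame.shape[0]} atoms"
        )
    d = frame[a_idx] - frame[b_idx]
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    if np.any(r == 0.0):
        bad = int(np.flatnonzero(r == 0.0)[0])
        raise DegenerateGeometryError(
            f"LCOD pair {spec.pairs[bad]} at zero separation: gradient undefined"
        )
    value = float(coeffs @ r)
    unit = (coeffs / r)[:, None] * d
    grad = np.zeros_like(frame)
    for i in range(len(r)):  # scatter-add; pairs may share atoms
        grad[a_idx[i]] += unit[i]
        grad[b_idx[i]] -= unit[i]
    return value, grad


def restraint_energy_force(
    frame: np.ndarray, restraint: HarmonicPathRestraint, lambda_t: float
) -> tuple[float, np.ndarray]:
    """Energy and per-atom forces of the harmonic path restraint at centre λ_t.

    Returns ``(energy, forces)`` with ``energy = (k/2)(ξ − λ_t)²`` in kcal/mol
    and ``forces = −∇energy`` in kcal/(mol Å), shape ``(n_atoms, 3)``.
    """
    if not np.isfinite(lambda_t):
        raise ValueError(f"lambda_t must be finite, got {lambda_t}")
    cv = eval_lcod(frame, restraint.spec)
    delta = cv - lambda_t
    energy = 0.5 * restraint.k * delta * delta
    grad = lcod_gradient(frame, restraint.spec)
    forces = -restraint.k * delta * grad
    return energy, forces


def flat_well_energy_force(
    frame: np.ndarray, restraint: FlatWellRestraint
) -> tuple[float, np.ndarray]:
    """Energy and forces of the flat-well spherical restraint.

    Satellites inside the radius feel nothing; outside, a harmonic wall
    pulls them back toward the centre atom.  Forces on the centre atom are
    the negatives of the satellite wall forces (Newton's third law).
    """
    frame = np.asarray(frame, dtype=float)
    energy = 0.0
    forces = np.zeros_like(frame)
    c = restraint.center_atom
    for s in restraint.satellite_atoms:
        dvec = frame[s] - frame[c]
        d = float(np.linalg.norm(dvec))
        excess = d - restraint.radius
        if excess <= 0.0:
            continue
        energy += 0.5 * restraint.k_wall * excess * excess
        # d > radius > 0, so the unit vector is well defined
        unit = dvec / d
        f_sat = -restraint.k_wall * excess * unit
        forces[s] += f_sat
        forces[c] -= f_sat
    return energy, forces


# ---------------------------------------------------------------------------
# Atom selection / configuration plumbing
# ---------------------------------------------------------------------------

def resolve_selection(structure_path: str, selection) -> int:
    """Resolve a PDB-style atom selection to a zero-based atom index.

    ``selection`` is either an integer index (returned unchanged) or a string
    ``"RESNAME RESID ATOMNAME"`` (e.g. ``"GLU 22 HE2"``) resolved against the
    first model of a PDB file via MDAnalysis.  Raises ``IndexError`` if the
    selection matches no atom or more than one atom.
    """
    if isinstance(selection, (int, np.integer)):
        return int(selection)
    parts = str(selection).split()
    if len(parts) != 3:
        raise ValueError(
            f"selection must be an index or 'RESNAME RESID ATOMNAME', got {selection!r}"
        )
    resname, resid, atomname = parts
    import MDAnalysis as mda  # deferred: only needed when PDB selections are used

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis warns about missing fields
        universe = mda.Universe(structure_path)
    group = universe.select_atoms(
        f"resname {resname} and resid {int(resid)} and name {atomname}"
    )
    if len(group) == 0:
        raise IndexError(f"selection {selection!r} matched no atom in {structure_path}")
    if len(group) > 1:
        raise IndexError(
            f"selection {selection!r} is ambiguous ({len(group)} atoms) in {structure_path}"
        )
    return int(group.ix[0])


def spec_from_triples(triples: Sequence[Sequence], structure_path: str | None = None) -> LCODSpec:
    """Build an :class:`LCODSpec` from ``[atom_a, atom_b, coefficient]`` triples.

    Atoms may be integer indices or PDB-style selection strings (the latter
    require ``structure_path``).  This is the CV block format of the pipeline
    configuration file.
    """
    pairs = []
    coeffs = []
    for triple in triples:
        if len(triple) != 3:
            raise ValueError(f"CV triple must be [atom_a, atom_b, coefficient], got {triple!r}")
        a, b, c = triple
        if structure_path is None and not all(isinstance(x, (int, np.integer)) for x in (a, b)):
            raise ValueError(
                "CV selections by name require a structure file to resolve against"
            )
        pairs.append(
            (resolve_selection(structure_path, a) if structure_path else int(a),
             resolve_selection(structure_path, b) if structure_path else int(b))
        )
        coeffs.append(float(c))
    return LCODSpec(pairs, coeffs)
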