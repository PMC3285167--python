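"""Pipeline configuration, validation and end-to-end execution.

A single YAML file of nested blocks (system / cv / protocol / analysis /
output) is the artifact of record for a run: it round-trips losslessly
through :func:`save_config` / :func:`load_validate_config`, its SHA-256 hash
is stamped into every output header, and rerunning the same configuration
reproduces the tabular outputs byte for byte.

The packaged *full-scale* preset carries the production steering
arithmetic: 30 replicates of 2 000 000 integrator steps at 0.5 fs (1 ns
each), snapshots and reporting every 2.5 ps.  It exists for protocol
validation; the desk-scale presets used in tests steer far fewer steps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigValidationError
from .dynamics import SYSTEM_NAMES, make_system, run_langevin
from .jarzynski import barrier_heights, pmf_from_ensemble
from .lcod import HarmonicPathRestraint, spec_from_triples
from .steering import SteeringProtocol, generate_snapshots, run_ensemble
from .transfer import detect_events, transfer_coordinate

__all__ = [
    "SystemConfig",
    "CVConfig",
    "ProtocolConfig",
    "AnalysisConfig",
    "OutputConfig",
    "PipelineConfig",
    "load_validate_config",
    "save_config",
    "full_scale_config",
    "scenario_config",
    "run_scenario",
    "run_pipeline",
]

logger = logging.getLogger("steerpmf")


@dataclass
class SystemConfig:
    name: str = "quartic_double_well"
    overrides: dict = field(default_factory=dict)


@dataclass
class CVConfig:
    """CV block: ``[atom_a, atom_b, coefficient]`` triples, or null to use
    the system's built-in CV.  Atoms may be PDB-style selections when
    ``structure`` names a PDB file."""

    triples: list | None = None
    structure: str | None = None


@dataclass
class ProtocolConfig:
    """Defaults are the desk-scale stiff-spring conditions: k = 1000
    kcal/(mol Å²) with the underdamped (BAOAB) integrator at dt = 5 fs,
    which is stable and accurate for restraint frequencies up to
    ω = sqrt(k/m) ≈ 32/ps (ω·dt ≈ 0.16)."""

    spring_k: float = 1000.0
    lambda0: float = 1.0
    lambda1: float = 3.0
    n_steps: int = 20000
    dt: float = 0.005
    n_replicates: int = 30
    seed_base: int = 1
    seeds: list | None = None
    snapshot_run_steps: int | None = None
    snapshot_interval: int = 200
    record_interval: int | None = None
    integrator: str = "baoab"


@dataclass
class AnalysisConfig:
    min_dwell_frames: int = 4
    hysteresis: float = 0.1
    concomitance_window: float | None = None
    transfer_roles: dict | None = None


@dataclass
class OutputConfig:
    prefix: str = "run"
    write_hdf5: bool = False


@dataclass
class PipelineConfig:
    system: SystemConfig = field(default_factory=SystemConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigValidationError(f"unknown config block(s): {sorted(unknown)}")

        def build(klass, block):
            if block is None:
                return klass()
            names = {f.name for f in dataclasses.fields(klass)}
            extra = set(block) - names
            if extra:
                raise ConfigValidationError(
                    f"unknown field(s) {sorted(extra)} in block {klass.__name__}"
                )
            return klass(**block)

        return cls(
            system=build(SystemConfig, data.get("system")),
            cv=build(CVConfig, data.get("cv")),
            protocol=build(ProtocolConfig, data.get("protocol")),
            analysis=build(AnalysisConfig, data.get("analysis")),
            output=build(OutputConfig, data.get("output")),
        )

    def hash(self) -> str:
        """Stable SHA-256 of the canonical YAML serialization (12 hex chars)."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    # -- derived objects ---------------------------------------------------

    @property
    def resolved_seeds(self) -> tuple[int, ...]:
        p = self.protocol
        if p.seeds is not None:
            return tuple(int(s) for s in p.seeds)
        return tuple(p.seed_base + 1 + i for i in range(p.n_replicates))

    @property
    def snapshot_seed(self) -> int:
        return self.protocol.seed_base

    @property
    def snapshot_run_steps(self) -> int:
        p = self.protocol
        if p.snapshot_run_steps is not None:
            return p.snapshot_run_steps
        return p.n_replicates * p.snapshot_interval

    @property
    def is_null_steering(self) -> bool:
        return self.protocol.lambda0 == self.protocol.lambda1

    def build_system(self):
        return make_system(self.system.name, **self.system.overrides)

    def build_restraint(self) -> HarmonicPathRestraint:
        system = self.build_system()
        spec = (spec_from_triples(self.cv.triples, self.cv.structure)
                if self.cv.triples is not None else system.cv)
        return HarmonicPathRestraint(
            spec=spec, k=self.protocol.spring_k,
            lambda0=self.protocol.lambda0, lambda1=self.protocol.lambda1,
        )

    def build_protocol(self) -> SteeringProtocol:
        p = self.protocol
        return SteeringProtocol(
            restraint=self.build_restraint(),
            n_steps=p.n_steps,
            dt=p.dt,
            n_replicates=p.n_replicates,
            seeds=self.resolved_seeds,
            snapshot_interval=p.snapshot_interval,
            record_interval=p.record_interval,
            integrator=p.integrator,
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> "PipelineConfig":
        p = self.protocol
        if self.system.name not in SYSTEM_NAMES:
            raise ConfigValidationError(
                f"system.name: unknown system {self.system.name!r}"
            )
        if not p.spring_k > 0:
            raise ConfigValidationError("protocol.spring_k: must be positive")
        if p.n_steps < 1:
            raise ConfigValidationError("protocol.n_steps: must be >= 1")
        if not p.dt > 0:
            raise ConfigValidationError("protocol.dt: must be positive")
        if p.n_replicates < 1:
            raise ConfigValidationError("protocol.n_replicates: must be >= 1")
        seeds = self.resolved_seeds
        if len(seeds) != p.n_replicates:
            raise ConfigValidationError(
                f"protocol.seeds: {len(seeds)} seeds for {p.n_replicates} replicates"
            )
        if len(set(seeds)) != len(seeds):
            raise ConfigValidationError("protocol.seeds: duplicate seeds")
        if p.snapshot_interval < 1:
            raise ConfigValidationError("protocol.snapshot_interval: must be >= 1")
        if self.snapshot_run_steps < p.n_replicates * p.snapshot_interval:
            raise ConfigValidationError(
                "protocol.snapshot_run_steps: too short for "
                f"{p.n_replicates} snapshots at interval {p.snapshot_interval}"
            )
        if p.integrator not in ("overdamped", "baoab"):
            raise ConfigValidationError(
                f"protocol.integrator: unknown integrator {p.integrator!r}"
            )
        if self.analysis.min_dwell_frames < 1:
            raise ConfigValidationError("analysis.min_dwell_frames: must be >= 1")
        if self.analysis.hysteresis < 0:
            raise ConfigValidationError("analysis.hysteresis: must be >= 0")
        if self.is_null_steering:
            logger.warning(
                "config %s: lambda0 == lambda1 — null steering, work will be 0",
                self.hash(),
            )
        return self


def load_validate_config(path) -> PipelineConfig:
    """Read a YAML configuration, fill defaults, and validate all
    cross-field constraints.  Violations raise
    :class:`ConfigValidationError` naming the offending field."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigValidationError("config file must contain a mapping")
    config = PipelineConfig.from_dict(data).validate()
    logger.info("loaded config %s from %s", config.hash(), path)
    return config


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def full_scale_config(system: str = "quartic_double_well") -> PipelineConfig:
    """The full-scale steering arithmetic: 30 replicates × 2 000 000 steps of
    0.5 fs (1 ns each), sampled every 2.5 ps (5000 steps)."""
    return PipelineConfig(
        system=SystemConfig(name=system),
        protocol=ProtocolConfig(
            spring_k=1000.0,
            n_steps=2_000_000,
            dt=0.0005,
            n_replicates=30,
            snapshot_run_steps=2_000_000,
            snapshot_interval=5000,
        ),
        output=OutputConfig(prefix="full_scale"),
    )


_SCENARIOS = {
    # analytic-oracle steering scenarios; ΔF targets come from
    # steerpmf.dynamics.exact_free_energy on the same systems
    "stiffness_switch": dict(
        system="stiffness_switch", lambda0=1.0, lambda1=2.5, n_steps=10000,
    ),
    "dragged_trap": dict(
        system="dragged_harmonic_trap", lambda0=1.0, lambda1=2.5, n_steps=10000,
    ),
    "double_well": dict(
        system="quartic_double_well", lambda0=1.0, lambda1=3.0, n_steps=20000,
    ),
}


def scenario_config(name: str, seed_base: int = 1) -> PipelineConfig:
    """A packaged oracle scenario: 30 stiff-spring (k = 1000) BAOAB
    replicates steered across a system with an exact free-energy answer.

    ``stiffness_switch`` recovers ΔF = kT·ln(k2/k1)/2 = 1 kT, ``dragged_trap``
    recovers ΔF = 0, and ``double_well`` recovers the full quartic PMF.
    """
    if name not in _SCENARIOS:
        raise ConfigValidationError(
            f"unknown scenario {name!r}; available: {sorted(_SCENARIOS)}"
        )
    s = _SCENARIOS[name]
    return PipelineConfig(
        system=SystemConfig(name=s["system"]),
        protocol=ProtocolConfig(
            lambda0=s["lambda0"], lambda1=s["lambda1"], n_steps=s["n_steps"],
            seed_base=seed_base,
        ),
        output=OutputConfig(prefix=name),
    ).validate()


def run_scenario(name: str, seed_base: int = 1):
    """Run a packaged scenario in memory; returns ``(system, ensemble, pmf)``."""
    from .jarzynski import pmf_from_ensemble as _pmf

    config = scenario_config(name, seed_base)
    system = config.build_system()
    protocol = config.build_protocol()
    snapshots = generate_snapshots(
        system, protocol.restraint, config.snapshot_run_steps,
        config.protocol.snapshot_interval, config.snapshot_seed,
        config.protocol.dt, n_required=protocol.n_replicates,
        integrator=config.protocol.integrator,
    )
    ensemble = run_ensemble(system, protocol, snapshots)
    return system, ensemble, _pmf(ensemble)


# ---------------------------------------------------------------------------
# Pipeline execution
# ---------------------------------------------------------------------------

def _stage_logger(outdir: Path, prefix: str) -> logging.Logger:
    log = logging.getLogger(f"steerpmf.pipeline.{prefix}")
    log.setLevel(logging.INFO)
    log.handlers.clear()
    handler = logging.FileHandler(outdir / f"{prefix}.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.propagate = False
    return log


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute snapshot → steer(×N) → pmf (→ optional transfer) stages.

    Returns a dict of output paths.  All tabular outputs carry the config
    hash and seeds in their headers and are byte-identical across reruns of
    the same configuration; timestamps go only to the stage log.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = config.output.prefix
    cfg_hash = config.hash()
    log = _stage_logger(outdir, prefix)
    outputs: dict[str, Path] = {}
    t0 = time.time()

    save_config(config, outdir / f"{prefix}.config.yaml")
    outputs["config"] = outdir / f"{prefix}.config.yaml"

    system = config.build_system()
    protocol = config.build_protocol()
    log.info("stage snapshot: config %s, system %s, seed %d",
             cfg_hash, system.name, config.snapshot_seed)
    try:
        snapshots = generate_snapshots(
            system, protocol.restraint, self_steps := config.snapshot_run_steps,
            config.protocol.snapshot_interval, config.snapshot_seed,
            config.protocol.dt, n_required=config.protocol.n_replicates,
            integrator=config.protocol.integrator,
        )
    except Exception:
        log.exception("stage snapshot failed")
        raise
    log.info("stage snapshot: %d snapshots from %d restrained steps",
             len(snapshots), self_steps)

    log.info("stage steer: %d replicates, seeds %s",
             protocol.n_replicates, protocol.seeds)
    try:
        ensemble = run_ensemble(system, protocol, snapshots)
    except Exception:
        log.exception("stage steer failed")
        raise
    ensemble.metadata["config_hash"] = cfg_hash
    work_path = outdir / f"{prefix}.work.tsv"
    ensemble.to_tsv(work_path)
    outputs["work"] = work_path

    log.info("stage pmf")
    pmf = pmf_from_ensemble(ensemble)
    pmf.metadata["config_hash"] = cfg_hash
    pmf_path = outdir / f"{prefix}.pmf.tsv"
    pmf.to_tsv(pmf_path)
    outputs["pmf"] = pmf_path
    barrier = barrier_heights(pmf)
    barrier_path = outdir / f"{prefix}.barriers.json"
    with open(barrier_path, "w") as fh:
        json.dump({
            "config_hash": cfg_hash,
            "forward_barrier_kcal_mol": barrier.forward_barrier,
            "reverse_barrier_kcal_mol": barrier.reverse_barrier,
            "barrier_position": barrier.barrier_position,
            "steering_direction": barrier.steering_direction,
        }, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["barriers"] = barrier_path
    log.info("stage pmf: forward %.3f kcal/mol, reverse %.3f kcal/mol",
             barrier.forward_barrier, barrier.reverse_barrier)

    roles = config.analysis.transfer_roles
    if roles:
        log.info("stage transfer: roles %s", roles)
        traj = run_langevin(
            system, config.protocol.n_steps, config.protocol.dt,
            seed=config.snapshot_seed,
            record_interval=config.protocol.snapshot_interval,
            method=config.protocol.integrator,
        )
        series = transfer_coordinate(
            traj, roles["donor"], roles["hydrogen"], roles["acceptor"]
        )
        events = detect_events(
            series, config.analysis.min_dwell_frames, config.analysis.hysteresis
        )
        events_path = outdir / f"{prefix}.events.tsv"
        with open(events_path, "w") as fh:
            fh.write(f"# steerpmf transfer events\n# config_hash: {cfg_hash}\n")
            fh.write("crossing_time\tcoordinate\tdirection\tpre_dwell\tpost_dwell\n")
            for e in events:
                fh.write(f"{e.crossing_time:.10g}\t{e.coordinate_id}\t"
                         f"{e.direction}\t{e.pre_dwell}\t{e.post_dwell}\n")
        outputs["events"] = events_path
        log.info("stage transfer: %d events", len(events))

    log.info("pipeline complete in %.1f s", time.time() - t0)
    return outputs
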