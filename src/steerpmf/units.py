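"""Unit conventions, shared by every module.

The package works in the conventional biomolecular-simulation unit system:

* length      — Å (angstrom)
* energy      — kcal/mol
* time        — ps
* temperature — K
* spring constants — kcal/(mol Å²)
* friction (overdamped drag coefficient γ) — kcal ps/(mol Å²)

so that the diffusion coefficient of an overdamped particle is
``D = kB*T/γ`` in Å²/ps.
"""

#: Boltzmann constant in kcal/(mol K).
KB = 0.0019872041


def kt(temperature: float) -> float:
    """Thermal energy kB*T in kcal/mol at ``temperature`` kelvin."""
    if temperature < 0:
        raise ValueError(f"temperature must be >= 0 K, got {temperature}")
    return KB * temperature
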