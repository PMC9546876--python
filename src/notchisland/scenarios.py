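"""Declarative in-silico perturbations of the island model.

Knockdowns scale production rates or fields (Dll1 KD and Jag1 KD reduce the
corresponding ligand production by 75%; E-Cadherin KD scales the ECad field
by 70% uniformly across the island, leaving the force fields untouched).
Growth-factor treatments flip the flags that activate the EGF / TGFβ2 terms
of the ODE system. Applying a scenario never mutates its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .mechanics import MechanicalFields
from .model import ModelParams


@dataclass(frozen=True)
class Scenario:
    """One simulated condition: genotype flags plus treatment flags."""

    name: str = "wt"
    dll1_kd: bool = False
    jag1_kd: bool = False
    ecad_kd: bool = False
    egf_on: bool = False
    tgf_on: bool = False
    kd_fraction_ligand: float = 0.75
    kd_fraction_ecad: float = 0.70

    def __post_init__(self):
        for name in ("kd_fraction_ligand", "kd_fraction_ecad"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {val}")


def apply_scenario(
    p: ModelParams, fields: MechanicalFields, s: Scenario
) -> tuple[ModelParams, MechanicalFields]:
    """Return (params, fields) copies with the scenario's modifications.

    betaD and/or betaJ are scaled by (1 - kd_fraction_ligand) for ligand
    knockdowns; the E-Cadherin field is scaled by (1 - kd_fraction_ecad) for
    the ECad knockdown. Treatment flags are carried by the scenario itself
    and read by the ODE right-hand side. Idempotent per flag and commutative
    across independent flags.
    """
    updates = {}
    if s.dll1_kd:
        updates["betaD"] = p.betaD * (1.0 - s.kd_fraction_ligand)
    if s.jag1_kd:
        updates["betaJ"] = p.betaJ * (1.0 - s.kd_fraction_ligand)
    p_out = replace(p, **updates) if updates else replace(p)
    fields_out = (
        fields.scaled_ecad(1.0 - s.kd_fraction_ecad)
        if s.ecad_kd
        else fields.scaled_ecad(1.0)
    )
    return p_out, fields_out


def scenario_battery() -> list[Scenario]:
    """The 12 simulated conditions: 4 genotypes x {none, EGF, TGFβ2}."""
    genotypes = [
        ("wt", {}),
        ("dll1_kd", {"dll1_kd": True}),
        ("jag1_kd", {"jag1_kd": True}),
        ("ecad_kd", {"ecad_kd": True}),
    ]
    treatments = [
        ("", {}),
        ("egf", {"egf_on": True}),
        ("tgfb2", {"tgf_on": True}),
    ]
    battery = []
    for gname, gflags in genotypes:
        for tname, tflags in treatments:
            name = gname if not tname else f"{gname}+{tname}"
            battery.append(Scenario(name=name, **gflags, **tflags))
    return battery
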