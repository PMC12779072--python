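"""Docking post-analysis: binding free energy, inhibition constants, MM/PBSA.

A rigid-receptor docking engine reports a binding free energy dG
(kcal/mol, negative favourable) and the paired inhibition constant

    Ki = exp(dG / (R T))

with R = 1.98722e-3 kcal/(mol K) and T = 298.15 K — the convention of
the AutoDock family of scoring functions.  This module converts between
the two, ranks complexes, aggregates MM/PBSA end-point free-energy
components, and summarises per-residue decompositions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ThermoConstants",
    "DockingRecord",
    "MMPBSAComponents",
    "ki_from_binding_energy",
    "binding_energy_from_ki",
    "format_ki",
    "select_best_complex",
    "mmpbsa_total",
    "residue_contribution_summary",
    "ki_consistent",
]

#: Gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.98722e-3


@dataclass(frozen=True)
class ThermoConstants:
    """Gas constant (kcal/mol/K) and temperature (K) for dG <-> Ki."""

    gas_constant: float = GAS_CONSTANT_KCAL
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not self.gas_constant > 0:
            raise ValueError(f"gas constant must be positive, got {self.gas_constant}")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


DEFAULT_CONSTANTS = ThermoConstants()


def ki_from_binding_energy(
    dg: float, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Inhibition constant Ki = exp(dG/RT) in molar units."""
    if not math.isfinite(dg):
        raise ValueError(f"binding energy must be finite, got {dg}")
    return math.exp(dg / constants.rt)


def binding_energy_from_ki(
    ki: float, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Inverse conversion dG = RT ln(Ki), kcal/mol."""
    if not ki > 0:
        raise ValueError(f"Ki must be positive, got {ki}")
    return constants.rt * math.log(ki)


_UNIT_SCALES = (("nM", 1e-9), ("μM", 1e-6), ("mM", 1e-3), ("M", 1.0))


def format_ki(ki: float) -> str:
    """Render a molar Ki with the natural unit at 2-decimal precision.

    Values below 1 uM print in nM, below 1 mM in uM, below 1 M in mM,
    otherwise in M (matching the mixed-unit style of docking reports).
    """
    if not ki > 0:
        raise ValueError(f"Ki must be positive, got {ki}")
    if ki < 1e-6:
        unit, scale = _UNIT_SCALES[0]
    elif ki < 1e-3:
        unit, scale = _UNIT_SCALES[1]
    elif ki < 1.0:
        unit, scale = _UNIT_SCALES[2]
    else:
        unit, scale = _UNIT_SCALES[3]
    return f"{ki / scale:.2f} {unit}"


@dataclass(frozen=True)
class DockingRecord:
    """One ligand-receptor docking result."""

    ligand: str
    receptor: str
    binding_energy: float  # kcal/mol, negative favourable
    n_hbonds: int = 0
    hbond_residues: tuple[str, ...] = ()
    vdw_residues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not math.isfinite(self.binding_energy):
            raise ValueError("binding energy must be finite")
        if self.n_hbonds < 0:
            raise ValueError("H-bond count must be non-negative")

    def ki(self, constants: ThermoConstants = DEFAULT_CONSTANTS) -> float:
        return ki_from_binding_energy(self.binding_energy, constants)


def select_best_complex(records: Sequence[DockingRecord]) -> DockingRecord:
    """Record with the most negative binding energy.

    Ties break deterministically on (ligand, receptor) lexicographic
    order.
    """
    if not records:
        raise ValueError("no docking records to rank")
    return min(records, key=lambda r: (r.binding_energy, r.ligand, r.receptor))


def ki_consistent(
    dg: float,
    printed_ki: float,
    tol: float = 0.02,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> bool:
    """Whether a printed Ki matches the dG conversion within ``tol``.

    The default 2% absorbs the rounding of a 2-decimal dG (+-0.005
    kcal/mol is ~0.85% in Ki) plus rounding of the printed Ki itself.
    """
    ki = ki_from_binding_energy(dg, constants)
    return abs(ki - printed_ki) / printed_ki <= tol


@dataclass(frozen=True)
class MMPBSAComponents:
    """End-point free-energy components of one complex, kcal/mol.

    The polar solvation term may come from either a Poisson-Boltzmann
    or Generalized Born model; the aggregation is agnostic.
    """

    vdw: float
    electrostatic: float
    polar_solvation: float
    nonpolar_solvation: float
    sds: Optional[Mapping[str, float]] = None

    def components(self) -> dict[str, float]:
        return {
            "vdw": self.vdw,
            "electrostatic": self.electrostatic,
            "polar_solvation": self.polar_solvation,
            "nonpolar_solvation": self.nonpolar_solvation,
        }


def mmpbsa_total(
    components: MMPBSAComponents,
) -> tuple[float, Optional[float]]:
    """Total binding free energy as the component sum, with propagated SD.

    Returns (total, sd) where sd = sqrt(sum sd_i^2) when per-component
    standard deviations are provided (reporting only), else None.
    """
    vals = components.components()
    for name, v in vals.items():
        if not math.isfinite(v):
            raise ValueError(f"component {name!r} is not finite: {v}")
    total = math.fsum(vals.values())
    sd = None
    if components.sds:
        missing = set(vals) - set(components.sds)
        if missing:
            raise ValueError(f"missing standard deviations for {sorted(missing)}")
        sd = math.sqrt(math.fsum(components.sds[k] ** 2 for k in vals))
    return total, sd


def residue_contribution_summary(
    energies: Mapping[str, float], top_n: Optional[int] = None
) -> list[tuple[str, float]]:
    """Residues ranked most-stabilising first (ascending energy).

    Ties order stably by residue label; ``top_n`` truncates the list.
    """
    if not energies:
        raise ValueError("empty per-residue energy map")
    ranked = sorted(energies.items(), key=lambda kv: (kv[1], kv[0]))
    return ranked[:top_n] if top_n is not None else ranked
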