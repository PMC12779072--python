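"""Photon attenuation parameters for compounds: MAC, LAC, HVL, MFP.

The mass attenuation coefficient of a mixture follows the additivity
(mixture) rule over elemental coefficients weighted by mass fraction;
the derived thickness parameters are

    LAC = MAC * rho          [1/cm]
    HVL = ln(2) / LAC        [cm]
    MFP = 1 / LAC            [cm]

Elemental coefficients are tabulated on energy grids and interpolated
log-log linearly, the standard scheme for photon cross sections (exact
on power laws).  No extrapolation outside a grid is ever performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .formulas import CompoundSpec, ElementComposition

__all__ = [
    "ElementXS",
    "CrossSectionTable",
    "AttenuationResult",
    "interpolate_xs",
    "mixture_mac",
    "linear_attenuation",
    "half_value_layer",
    "mean_free_path",
    "attenuation_profile",
    "infer_density",
]


@dataclass(frozen=True)
class ElementXS:
    """Energy grid of total and incoherent (Compton) mu/rho for one element.

    Energies in MeV (strictly increasing); coefficients in cm^2/g with
    0 < compton <= total at every grid point.
    """

    symbol: str
    Z: int
    energies: np.ndarray
    total: np.ndarray
    compton: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        t = np.asarray(self.total, dtype=float)
        c = np.asarray(self.compton, dtype=float)
        if not (e.ndim == 1 and e.size >= 2):
            raise ValueError(f"{self.symbol}: need >= 2 grid energies")
        if not (len(e) == len(t) == len(c)):
            raise ValueError(f"{self.symbol}: grid/coefficient length mismatch")
        if np.any(np.diff(e) <= 0):
            raise ValueError(f"{self.symbol}: energy grid must strictly increase")
        if np.any(t <= 0) or np.any(c <= 0):
            raise ValueError(f"{self.symbol}: coefficients must be positive")
        if np.any(c > t * (1 + 1e-12)):
            raise ValueError(f"{self.symbol}: compton channel exceeds total")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "total", t)
        object.__setattr__(self, "compton", c)


@dataclass(frozen=True)
class CrossSectionTable:
    """Per-element cross-section grids keyed by element symbol."""

    elements: Mapping[str, ElementXS]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("cross-section table has no elements")

    def __getitem__(self, symbol: str) -> ElementXS:
        try:
            return self.elements[symbol]
        except KeyError:
            raise KeyError(
                f"element {symbol!r} missing from cross-section table "
                f"(have {sorted(self.elements)})"
            ) from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.elements

    def symbols(self) -> list[str]:
        return sorted(self.elements)


def interpolate_xs(table: ElementXS, energy: float, channel: str = "total") -> float:
    """Log-log linear interpolation of mu/rho at ``energy`` (MeV).

    Exact at grid points; rejects energies outside the grid rather than
    extrapolating silently.
    """
    if channel == "total":
        values = table.total
    elif channel == "compton":
        values = table.compton
    else:
        raise ValueError(f"unknown channel {channel!r} (use 'total' or 'compton')")
    e = float(energy)
    grid = table.energies
    if not (grid[0] <= e <= grid[-1]):
        raise ValueError(
            f"energy {e} MeV outside grid [{grid[0]}, {grid[-1]}] for "
            f"element {table.symbol!r}"
        )
    return float(
        np.exp(np.interp(np.log(e), np.log(grid), np.log(values)))
    )


def mixture_mac(
    composition: ElementComposition,
    xs: CrossSectionTable,
    energy: float,
    channel: str = "total",
) -> float:
    """Mixture-rule MAC: sum_i W_i (mu/rho)_i(E), cm^2/g."""
    total = 0.0
    for symbol, w in composition.weight_fractions.items():
        total += w * interpolate_xs(xs[symbol], energy, channel)
    return total


def linear_attenuation(mac: float, density: float) -> float:
    """LAC = MAC * density (1/cm); both inputs must be positive."""
    if not mac > 0:
        raise ValueError(f"MAC must be positive, got {mac}")
    if not density > 0:
        raise ValueError(f"density must be positive, got {density}")
    return mac * density


def half_value_layer(lac: float) -> float:
    """HVL = ln(2)/LAC in cm (exact ln 2, not the rounded 0.693)."""
    if not lac > 0:
        raise ValueError(f"LAC must be positive, got {lac}")
    return math.log(2.0) / lac


def mean_free_path(lac: float) -> float:
    """MFP = 1/LAC in cm."""
    if not lac > 0:
        raise ValueError(f"LAC must be positive, got {lac}")
    return 1.0 / lac


@dataclass(frozen=True)
class AttenuationResult:
    """Attenuation parameters at one photon energy.

    ``lac``/``hvl``/``mfp`` are None when the compound density is
    unknown (MAC is density-independent; the others are not).
    """

    energy: float
    mac: float
    lac: Optional[float] = None
    hvl: Optional[float] = None
    mfp: Optional[float] = None


def attenuation_profile(
    compound: CompoundSpec,
    xs: CrossSectionTable,
    energies: Iterable[float],
) -> list[AttenuationResult]:
    """One :class:`AttenuationResult` per energy (MeV) for ``compound``."""
    out = []
    comp = compound.composition
    for e in energies:
        mac = mixture_mac(comp, xs, e)
        if compound.density is not None:
            lac = linear_attenuation(mac, compound.density)
            out.append(
                AttenuationResult(
                    energy=e,
                    mac=mac,
                    lac=lac,
                    hvl=half_value_layer(lac),
                    mfp=mean_free_path(lac),
                )
            )
        else:
            out.append(AttenuationResult(energy=e, mac=mac))
    return out


def infer_density(
    compound: CompoundSpec,
    xs: CrossSectionTable,
    anchor_energy: float,
    anchor_lac: float,
) -> float:
    """Back-solve rho = LAC/MAC from one known (energy, LAC) anchor.

    Useful when a published table prints LAC values but not the density
    used to obtain them: anchoring at one energy lets every other energy
    be cross-validated.
    """
    if not anchor_lac > 0:
        raise ValueError(f"anchor LAC must be positive, got {anchor_lac}")
    mac = mixture_mac(compound.composition, xs, anchor_energy)
    return anchor_lac / mac
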