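"""Equivalent atomic number and geometric-progression (G-P) buildup factors.

Scattered photons at depth inside a shield raise the transmitted
intensity above the uncollided exponential; the buildup factor B(E, x)
is that correction.  The five-parameter geometric-progression fit
represents B as

    B(E, x) = 1 + (b - 1) (K^x - 1) / (K - 1)      K != 1
    B(E, x) = 1 + (b - 1) x                        K == 1
    K(E, x) = c x^a + d [tanh(x/Xk - 2) - tanh(-2)] / [1 - tanh(-2)]

valid for penetration depths x <= 40 mean free paths.  For a compound,
the parameters are read off elemental tables at its equivalent atomic
number Zeq — the Z whose Compton-to-total attenuation ratio R matches
the compound's at that energy — via the log-ratio interpolation

    Zeq = [Z1 (log R2 - log R) + Z2 (log R - log R1)] / (log R2 - log R1).

Exposure (EBF) and energy-absorption (EABF) buildup differ only in the
parameter table used; the formalism is identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .attenuation import CrossSectionTable, mixture_mac
from .formulas import CompoundSpec, ElementComposition

__all__ = [
    "GPParams",
    "GPParameterTable",
    "ZeqResult",
    "BuildupCurve",
    "compton_total_ratio",
    "elemental_ratios",
    "equivalent_atomic_number",
    "interpolate_gp_parameters",
    "gp_K",
    "buildup_factor",
    "buildup_curve",
    "default_energy_grid",
]

#: Branch guard: below this |K - 1| the linear (K == 1) limit is used,
#: because the geometric form is numerically singular there.
K_BRANCH_TOL = 1e-8

MAX_DEPTH_MFP = 40.0

PARAM_NAMES = ("b", "c", "a", "Xk", "d")


@dataclass(frozen=True)
class GPParams:
    """One (b, c, a, Xk, d) quintuple of G-P fitting parameters."""

    b: float
    c: float
    a: float
    Xk: float
    d: float

    def astuple(self) -> tuple[float, float, float, float, float]:
        return (self.b, self.c, self.a, self.Xk, self.d)


@dataclass(frozen=True)
class GPParameterTable:
    """G-P fitting parameters on a (Z, energy) grid for one buildup kind.

    ``values`` has shape (nZ, nE, 5) with the last axis ordered
    (b, c, a, Xk, d).  Z coverage must be contiguous integers; b >= 1
    and Xk > 0 everywhere for a physically meaningful table.
    """

    kind: str  # "EBF" | "EABF"
    zs: np.ndarray
    energies: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("EBF", "EABF"):
            raise ValueError(f"kind must be 'EBF' or 'EABF', got {self.kind!r}")
        zs = np.asarray(self.zs, dtype=int)
        en = np.asarray(self.energies, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if zs.ndim != 1 or np.any(np.diff(zs) != 1):
            raise ValueError("Z coverage must be contiguous increasing integers")
        if en.ndim != 1 or np.any(np.diff(en) <= 0):
            raise ValueError("energy grid must strictly increase")
        if vals.shape != (len(zs), len(en), 5):
            raise ValueError(
                f"values shape {vals.shape} != ({len(zs)}, {len(en)}, 5)"
            )
        if np.any(vals[..., 0] < 1):
            raise ValueError("G-P parameter b must be >= 1 everywhere")
        if np.any(vals[..., 3] <= 0):
            raise ValueError("G-P parameter Xk must be positive")
        object.__setattr__(self, "zs", zs)
        object.__setattr__(self, "energies", en)
        object.__setattr__(self, "values", vals)

    def at(self, z: int, energy: float) -> GPParams:
        """Exact tabulated quintuple at integer Z, with log-linear
        interpolation along the energy axis (exact at grid energies)."""
        iz = int(np.searchsorted(self.zs, z))
        if iz >= len(self.zs) or self.zs[iz] != z:
            raise ValueError(f"Z={z} not in table range [{self.zs[0]}, {self.zs[-1]}]")
        e = float(energy)
        grid = self.energies
        if not (grid[0] <= e <= grid[-1]):
            raise ValueError(
                f"energy {e} MeV outside G-P grid [{grid[0]}, {grid[-1]}]"
            )
        row = np.empty(5)
        loge = np.log(e)
        loggrid = np.log(grid)
        for j in range(5):
            row[j] = np.interp(loge, loggrid, self.values[iz, :, j])
        return GPParams(*row)


@dataclass(frozen=True)
class ZeqResult:
    """Equivalent atomic number at one energy with its bracketing data."""

    energy: float
    R: float
    Z1: int
    Z2: int
    R1: float
    R2: float
    zeq: float


def compton_total_ratio(
    composition: ElementComposition, xs: CrossSectionTable, energy: float
) -> float:
    """Mixture Compton MAC over mixture total MAC, in (0, 1]."""
    compton = mixture_mac(composition, xs, energy, channel="compton")
    total = mixture_mac(composition, xs, energy, channel="total")
    return compton / total


def elemental_ratios(xs: CrossSectionTable, energy: float) -> dict[int, float]:
    """Compton/total ratio per element at ``energy``, keyed by Z (sorted)."""
    from .attenuation import interpolate_xs

    out: dict[int, float] = {}
    for symbol in xs.symbols():
        el = xs[symbol]
        out[el.Z] = interpolate_xs(el, energy, "compton") / interpolate_xs(
            el, energy, "total"
        )
    return dict(sorted(out.items()))


def equivalent_atomic_number(
    R: float, ratios: Mapping[int, float], energy: float = float("nan")
) -> ZeqResult:
    """Locate R between consecutive elemental ratios and log-interpolate Zeq.

    ``ratios`` maps Z -> R_Z at a single energy and must be strictly
    monotone in Z; R outside the elemental span is rejected rather than
    clamped.
    """
    if not R > 0:
        raise ValueError(f"ratio R must be positive, got {R}")
    zs = sorted(ratios)
    if len(zs) < 2:
        raise ValueError("need ratios for at least two elements")
    rs = [ratios[z] for z in zs]
    diffs = np.diff(rs)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError(
            "elemental Compton/total ratios are not monotone in Z at this "
            f"energy: {dict(zip(zs, rs))}"
        )
    lo, hi = min(rs), max(rs)
    if not (lo <= R <= hi):
        raise ValueError(
            f"R={R} outside elemental ratio span [{lo}, {hi}]; cannot "
            "interpolate Zeq (no clamping)"
        )
    # exact hit on a tabulated element
    for z, rz in zip(zs, rs):
        if R == rz:
            return ZeqResult(energy, R, z, z, rz, rz, float(z))
    for (z1, r1), (z2, r2) in zip(zip(zs, rs), zip(zs[1:], rs[1:])):
        if min(r1, r2) <= R <= max(r1, r2):
            zeq = (
                z1 * (math.log(r2) - math.log(R))
                + z2 * (math.log(R) - math.log(r1))
            ) / (math.log(r2) - math.log(r1))
            return ZeqResult(energy, R, z1, z2, r1, r2, zeq)
    raise ValueError(f"R={R} not bracketed by consecutive elemental ratios")


def interpolate_gp_parameters(
    gp: GPParameterTable, zeq: float, energy: float
) -> GPParams:
    """G-P quintuple at real-valued ``zeq`` via log-Z weighted interpolation.

    Each parameter P is interpolated between the bracketing integer-Z
    rows as

        P = [P1 (log Z2 - log zeq) + P2 (log zeq - log Z1)]
            / (log Z2 - log Z1)

    mirroring the Zeq interpolation itself; exact for integer zeq.
    """
    zs = gp.zs
    if not (zs[0] <= zeq <= zs[-1]):
        raise ValueError(
            f"zeq={zeq} outside G-P table Z range [{zs[0]}, {zs[-1]}]"
        )
    if float(zeq).is_integer():
        return gp.at(int(zeq), energy)
    z1 = int(math.floor(zeq))
    z2 = z1 + 1
    p1 = np.array(gp.at(z1, energy).astuple())
    p2 = np.array(gp.at(z2, energy).astuple())
    w = (math.log(zeq) - math.log(z1)) / (math.log(z2) - math.log(z1))
    return GPParams(*((1 - w) * p1 + w * p2))


def gp_K(params: GPParams, x: float) -> float:
    """Dose-multiplication factor K(E, x) of the G-P representation.

    Valid for 0 < x <= 40 mfp (the stated fitting domain).
    """
    if not 0 < x <= MAX_DEPTH_MFP:
        raise ValueError(f"depth x={x} mfp outside validity domain (0, 40]")
    t2 = math.tanh(-2.0)
    return params.c * x**params.a + params.d * (
        math.tanh(x / params.Xk - 2.0) - t2
    ) / (1.0 - t2)


def buildup_factor(params: GPParams, x: float) -> float:
    """Buildup factor B(E, x) for 0 <= x <= 40 mfp; B(0) = 1.

    Uses the linear branch when |K - 1| < 1e-8, which is the limit of
    the geometric branch and avoids its singularity.
    """
    if x == 0:
        return 1.0
    K = gp_K(params, x)
    b = params.b
    if abs(K - 1.0) < K_BRANCH_TOL:
        return 1.0 + (b - 1.0) * x
    return 1.0 + (b - 1.0) * (K**x - 1.0) / (K - 1.0)


def default_energy_grid(n: int = 25) -> np.ndarray:
    """Logarithmically spaced photon energies over 0.015-15 MeV."""
    return np.geomspace(0.015, 15.0, n)


@dataclass(frozen=True)
class BuildupCurve:
    """B(E, x) matrix for one compound: energies x depths, with Zeq trace."""

    kind: str
    compound_id: str
    energies: np.ndarray
    depths: np.ndarray
    zeq: np.ndarray
    B: np.ndarray  # shape (nE, nX)


def buildup_curve(
    compound: CompoundSpec,
    xs: CrossSectionTable,
    gp: GPParameterTable,
    energies: Optional[Sequence[float]] = None,
    depths: Sequence[float] = (10.0, 20.0, 40.0),
) -> BuildupCurve:
    """Full pipeline per energy: R -> Zeq -> G-P parameters -> B(x).

    Depths are in mean free paths and must lie in [0, 40].
    """
    if energies is None:
        energies = gp.energies
    en = np.asarray(list(energies), dtype=float)
    xdep = np.asarray(list(depths), dtype=float)
    if np.any(xdep < 0) or np.any(xdep > MAX_DEPTH_MFP):
        raise ValueError(
            f"depths must lie within [0, {MAX_DEPTH_MFP}] mfp, got {xdep}"
        )
    comp = compound.composition
    zeqs = np.empty(len(en))
    B = np.empty((len(en), len(xdep)))
    for i, e in enumerate(en):
        ratio = compton_total_ratio(comp, xs, e)
        zres = equivalent_atomic_number(ratio, elemental_ratios(xs, e), e)
        zeqs[i] = zres.zeq
        params = interpolate_gp_parameters(gp, zres.zeq, e)
        for j, x in enumerate(xdep):
            B[i, j] = buildup_factor(params, x)
    return BuildupCurve(
        kind=gp.kind,
        compound_id=compound.identifier,
        energies=en,
        depths=xdep,
        zeq=zeqs,
        B=B,
    )
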