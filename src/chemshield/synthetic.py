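"""Synthetic inputs with oracle-friendly closed-form structure.

Each generator emulates the *shape* its consumer assumes, not the real
physics or assay chemistry:

* elemental cross sections as smooth monotone power laws
  mu/rho = alpha_Z E^(-beta_Z) + gamma_Z with a Compton channel that is
  a Z-dependent (log-linear in Z) fraction of the total;
* G-P parameter surfaces linear in log Z at every grid energy, so the
  Z-interpolation has an exact closed-form expected value;
* docking tables with known dG drawn uniformly and the Ki column
  computed by the package's own stated conversion, then rounded to
  report precision;
* MIC matrices built as organism baseline + compound effect + normal
  noise on the log2 scale, snapped to a 2-fold ladder, with the true
  effects recorded as ground truth.

A single root seed drives independent per-generator substreams, so any
one table is reproducible bit-for-bit without regenerating the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .attenuation import CrossSectionTable, ElementXS
from .binding import (
    DockingRecord,
    ThermoConstants,
    DEFAULT_CONSTANTS,
    format_ki,
    ki_from_binding_energy,
)
from .buildup import GPParameterTable, PARAM_NAMES
from .micstats import DEFAULT_LADDER, DilutionLadder, MICMatrix

__all__ = [
    "SyntheticConfig",
    "XSLaw",
    "gen_xs_table",
    "gen_gp_table",
    "gen_docking_table",
    "gen_mic_matrix",
    "GPSurface",
    "MICGroundTruth",
    "DockingGroundTruth",
]

_STREAMS = {"xs": 0, "gp": 1, "docking": 2, "mic": 3}


@dataclass(frozen=True)
class XSLaw:
    """Closed-form elemental cross-section law.

    total(E)  = alpha * E^(-beta) + gamma         [cm^2/g, E in MeV]
    compton(E) = fraction(Z) * total(E), with
    fraction(Z) = f0 * exp(-lam * Z)   (log-linear in Z, decreasing).
    """

    alpha: float
    beta: float
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not self.beta > 0:
            raise ValueError("beta must be positive (curves must decrease)")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")

    def total(self, energy: np.ndarray | float) -> np.ndarray | float:
        return self.alpha * np.asarray(energy, dtype=float) ** (-self.beta) + self.gamma


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs for the four generators, driven by one root seed."""

    seed: int = 0
    # --- cross sections -------------------------------------------------
    elements: tuple[tuple[str, int], ...] = (("H", 1), ("C", 6), ("N", 7), ("O", 8))
    xs_laws: Optional[dict[str, XSLaw]] = None  # default: per-Z smooth laws
    energy_min: float = 0.015
    energy_max: float = 15.0
    n_energies: int = 25
    compton_f0: float = 0.98
    compton_lam: float = 0.01
    # --- G-P parameter surfaces ----------------------------------------
    gp_z_min: int = 4
    gp_z_max: int = 26
    # --- docking --------------------------------------------------------
    n_docking: int = 8
    dg_min: float = -15.0
    dg_max: float = -5.0
    # --- MIC ------------------------------------------------------------
    ladder: DilutionLadder = DEFAULT_LADDER
    n_organisms: int = 9
    n_compounds: int = 6
    compound_effects_log2: Optional[tuple[float, ...]] = None  # default zeros
    baseline_log2: float = math.log2(625.0)
    mic_noise_sd_log2: float = 0.25

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream per generator from the root seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(_STREAMS))[_STREAMS[stream]]
        )

    def energy_grid(self) -> np.ndarray:
        return np.geomspace(self.energy_min, self.energy_max, self.n_energies)

    def compton_fraction(self, z: int) -> float:
        f = self.compton_f0 * math.exp(-self.compton_lam * z)
        if not 0 < f <= 1:
            raise ValueError(f"Compton fraction {f} for Z={z} outside (0, 1]")
        return f

    def default_xs_laws(self) -> dict[str, XSLaw]:
        # gentle Z trend: heavier elements attenuate slightly more and
        # fall slightly faster with energy
        return {
            sym: XSLaw(alpha=0.08 + 0.004 * z, beta=0.30 + 0.005 * z, gamma=0.01)
            for sym, z in self.elements
        }


def gen_xs_table(config: SyntheticConfig) -> tuple[CrossSectionTable, dict[str, XSLaw]]:
    """Cross-section table sampled from the closed-form laws.

    Returns the table plus the laws themselves so tests can compare
    interpolated values against the analytic form.
    """
    laws = config.xs_laws if config.xs_laws is not None else config.default_xs_laws()
    grid = config.energy_grid()
    elements = {}
    for sym, z in config.elements:
        law = laws[sym]
        total = np.asarray(law.total(grid), dtype=float)
        frac = config.compton_fraction(z)
        elements[sym] = ElementXS(
            symbol=sym, Z=z, energies=grid, total=total, compton=frac * total
        )
    return CrossSectionTable(elements=elements), dict(laws)


@dataclass(frozen=True)
class GPSurface:
    """Closed-form G-P surface: P(Z, E) = intercept(E) + slope(E) ln Z.

    ``intercepts``/``slopes`` are arrays over the energy grid, one pair
    per parameter in (b, c, a, Xk, d) order.
    """

    energies: np.ndarray
    intercepts: np.ndarray  # shape (nE, 5)
    slopes: np.ndarray  # shape (nE, 5)

    def value(self, zeq: float, i_energy: int) -> np.ndarray:
        return self.intercepts[i_energy] + self.slopes[i_energy] * math.log(zeq)


def gen_gp_table(
    config: SyntheticConfig, kind: str = "EABF"
) -> tuple[GPParameterTable, GPSurface]:
    """G-P table whose parameters are linear in log Z at each energy.

    The per-energy intercepts and slopes vary smoothly with log E; the
    b surface stays >= 1 and Xk > 0 by construction.
    """
    grid = config.energy_grid()
    t = np.log(grid / math.sqrt(config.energy_min * config.energy_max))
    t = t / t.max()  # smooth covariate in [-1, 1]
    nE = len(grid)
    intercepts = np.empty((nE, 5))
    slopes = np.empty((nE, 5))
    # order: b, c, a, Xk, d
    # b >= 1 everywhere; c in (0, 1), a >= 0, d >= 0 so that K(E, x) is
    # increasing in depth, which makes B monotone non-decreasing in x
    intercepts[:, 0] = 1.10 + 0.05 * (1 + np.cos(math.pi * t))  # b >= 1.10
    slopes[:, 0] = 0.08 + 0.02 * t**2
    intercepts[:, 1] = 0.75 + 0.05 * np.sin(1.5 * t)
    slopes[:, 1] = 0.04 - 0.01 * t
    intercepts[:, 2] = 0.02 + 0.01 * t
    slopes[:, 2] = 0.004 + 0.002 * t
    intercepts[:, 3] = 12.0 + 2.0 * t**2
    slopes[:, 3] = 1.5 - 0.5 * t
    intercepts[:, 4] = 0.02 + 0.01 * t
    slopes[:, 4] = 0.005 + 0.002 * t
    zs = np.arange(config.gp_z_min, config.gp_z_max + 1)
    logz = np.log(zs)
    values = intercepts[None, :, :] + slopes[None, :, :] * logz[:, None, None]
    table = GPParameterTable(kind=kind, zs=zs, energies=grid, values=values)
    return table, GPSurface(energies=grid, intercepts=intercepts, slopes=slopes)


def _format_ki_sidecar(ki: float) -> str:
    """Report-style Ki text; sub-unity values keep 3 significant digits so
    the printed number stays within the 2% consistency tolerance."""
    text = format_ki(ki)
    value, unit = text.split()
    if float(value) < 1.0:
        scale = {"nM": 1e-9, "μM": 1e-6, "mM": 1e-3, "M": 1.0}[unit]
        return f"{ki / scale:.3g} {unit}"
    return text


@dataclass(frozen=True)
class DockingGroundTruth:
    """True binding energies behind a generated docking table."""

    dg: dict[tuple[str, str], float]
    printed_ki: dict[tuple[str, str], str]


def gen_docking_table(
    config: SyntheticConfig, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> tuple[list[DockingRecord], DockingGroundTruth]:
    """Docking records with uniform dG draws and report-rounded Ki.

    The Ki sidecar is formatted exactly as a report table would print
    it (2 decimals in the natural unit), so consistency checks against
    the conversion must pass within the 2% rounding tolerance.
    """
    if not (config.dg_min < config.dg_max <= 0):
        raise ValueError("dG range must be negative with dg_min < dg_max")
    rng = config.rng("docking")
    receptors = [f"R{i + 1}" for i in range(max(1, config.n_docking // 2))]
    records, dgs, kis = [], {}, {}
    for i in range(config.n_docking):
        ligand = f"L{i + 1}"
        receptor = receptors[i % len(receptors)]
        dg = round(float(rng.uniform(config.dg_min, config.dg_max)), 2)
        rec = DockingRecord(
            ligand=ligand,
            receptor=receptor,
            binding_energy=dg,
            n_hbonds=int(rng.integers(0, 7)),
        )
        records.append(rec)
        dgs[(ligand, receptor)] = dg
        kis[(ligand, receptor)] = _format_ki_sidecar(
            ki_from_binding_energy(dg, constants)
        )
    return records, DockingGroundTruth(dg=dgs, printed_ki=kis)


@dataclass(frozen=True)
class MICGroundTruth:
    """True (pre-snap) structure behind a generated MIC matrix."""

    baseline_log2: float
    compound_effects_log2: tuple[float, ...]
    organism_offsets_log2: tuple[float, ...]
    latent_log2: np.ndarray  # before ladder snapping


def gen_mic_matrix(config: SyntheticConfig) -> tuple[MICMatrix, MICGroundTruth]:
    """MIC matrix: log2 MIC = baseline + organism offset + compound effect
    + N(0, sd) noise, snapped to the nearest ladder rung (ties upward).

    Organism offsets are drawn on whole ladder steps (integers in
    log2 units, -1..1) to mimic organisms of differing susceptibility.
    """
    rng = config.rng("mic")
    effects = (
        config.compound_effects_log2
        if config.compound_effects_log2 is not None
        else tuple(0.0 for _ in range(config.n_compounds))
    )
    if len(effects) != config.n_compounds:
        raise ValueError("one log2 effect per compound required")
    offsets = tuple(float(v) for v in rng.integers(-1, 2, size=config.n_organisms))
    latent = np.empty((config.n_compounds, config.n_organisms))
    snapped = np.empty_like(latent)
    for i, eff in enumerate(effects):
        for j, off in enumerate(offsets):
            mu = config.baseline_log2 + off + eff
            val = mu + rng.normal(0.0, config.mic_noise_sd_log2)
            latent[i, j] = val
            snapped[i, j] = config.ladder.snap_log2(val)
    matrix = MICMatrix(
        compounds=tuple(f"c{i + 1}" for i in range(config.n_compounds)),
        organisms=tuple(f"org{j + 1}" for j in range(config.n_organisms)),
        classes=tuple(
            ("gram+" if j % 2 == 0 else "gram-") for j in range(config.n_organisms)
        ),
        values=snapped,
    )
    truth = MICGroundTruth(
        baseline_log2=config.baseline_log2,
        compound_effects_log2=tuple(effects),
        organism_offsets_log2=offsets,
        latent_log2=latent,
    )
    return matrix, truth
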