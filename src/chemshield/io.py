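"""CSV interfaces for compounds, cross sections, G-P tables, docking,
MM/PBSA and MIC matrices, plus loaders for the packaged reference data.

All tabular files are comma-separated UTF-8 with a header row; lines
starting with ``#`` are comments.  Units are fixed by the headers
(energies in MeV in cross-section/G-P files, keV in report output,
binding energies in kcal/mol, MIC in ug/mL).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .attenuation import AttenuationResult, CrossSectionTable, ElementXS
from .binding import DockingRecord, MMPBSAComponents
from .buildup import BuildupCurve, GPParameterTable, PARAM_NAMES
from .formulas import CompoundSpec
from .micstats import MICMatrix, PairwiseComparison

__all__ = [
    "read_compounds",
    "read_xs_table",
    "read_gp_table",
    "read_docking_table",
    "read_mmpbsa_components",
    "read_mic_matrix",
    "write_attenuation_csv",
    "write_buildup_csv",
    "write_xs_table",
    "write_gp_table",
    "write_mic_matrix",
    "load_reference_xs",
    "load_reference_compounds",
    "load_reference_lac",
    "load_reference_docking",
    "load_reference_mmpbsa",
    "load_reference_mic",
    "load_example_gp",
]

PathLike = Union[str, Path]

_KI_UNIT_SCALE = {"nM": 1e-9, "uM": 1e-6, "μM": 1e-6, "mM": 1e-3, "M": 1.0}


def _read_csv(path_or_buf, **kw) -> pd.DataFrame:
    return pd.read_csv(path_or_buf, comment="#", skip_blank_lines=True, **kw)


def read_compounds(path: PathLike) -> list[CompoundSpec]:
    """Read ``id,formula,density_g_cm3`` rows (density may be empty)."""
    df = _read_csv(path)
    required = {"id", "formula", "density_g_cm3"}
    if not required <= set(df.columns):
        raise ValueError(f"compounds file needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        density = row["density_g_cm3"]
        density = None if pd.isna(density) else float(density)
        out.append(CompoundSpec(str(row["id"]), str(row["formula"]), density))
    if not out:
        raise ValueError(f"no compounds in {path}")
    return out


def read_xs_table(path: PathLike) -> CrossSectionTable:
    """Read ``element,Z,energy_MeV,total_mu_rho_cm2_g,compton_mu_rho_cm2_g``."""
    df = _read_csv(path)
    elements = {}
    for sym, grp in df.groupby("element", sort=True):
        grp = grp.sort_values("energy_MeV")
        elements[str(sym)] = ElementXS(
            symbol=str(sym),
            Z=int(grp["Z"].iloc[0]),
            energies=grp["energy_MeV"].to_numpy(float),
            total=grp["total_mu_rho_cm2_g"].to_numpy(float),
            compton=grp["compton_mu_rho_cm2_g"].to_numpy(float),
        )
    return CrossSectionTable(elements=elements)


def write_xs_table(table: CrossSectionTable, path: PathLike) -> None:
    rows = []
    for sym in table.symbols():
        el = table[sym]
        for e, t, c in zip(el.energies, el.total, el.compton):
            rows.append((sym, el.Z, e, t, c))
    pd.DataFrame(
        rows,
        columns=[
            "element", "Z", "energy_MeV", "total_mu_rho_cm2_g",
            "compton_mu_rho_cm2_g",
        ],
    ).to_csv(path, index=False)


def read_gp_table(path: PathLike, kind: Optional[str] = None) -> GPParameterTable:
    """Read ``kind,Z,energy_MeV,b,c,a,Xk,d``; ``kind`` selects EBF/EABF
    when the file carries both."""
    df = _read_csv(path)
    kinds = sorted(df["kind"].unique())
    if kind is None:
        if len(kinds) != 1:
            raise ValueError(f"file carries kinds {kinds}; pass kind= to select")
        kind = kinds[0]
    sub = df[df["kind"] == kind]
    if sub.empty:
        raise ValueError(f"no rows of kind {kind!r} (file has {kinds})")
    zs = np.sort(sub["Z"].unique())
    energies = np.sort(sub["energy_MeV"].unique())
    values = np.empty((len(zs), len(energies), 5))
    values.fill(np.nan)
    zi = {z: i for i, z in enumerate(zs)}
    ei = {e: i for i, e in enumerate(energies)}
    for _, row in sub.iterrows():
        values[zi[row["Z"]], ei[row["energy_MeV"]], :] = [
            row[p] for p in PARAM_NAMES
        ]
    if np.any(np.isnan(values)):
        raise ValueError("G-P file does not cover the full Z x energy grid")
    return GPParameterTable(kind=str(kind), zs=zs, energies=energies, values=values)


def write_gp_table(table: GPParameterTable, path: PathLike) -> None:
    rows = []
    for i, z in enumerate(table.zs):
        for j, e in enumerate(table.energies):
            rows.append((table.kind, int(z), float(e), *table.values[i, j, :]))
    pd.DataFrame(
        rows, columns=["kind", "Z", "energy_MeV", *PARAM_NAMES]
    ).to_csv(path, index=False)


def _split_residues(cell) -> tuple[str, ...]:
    if pd.isna(cell) or not str(cell).strip():
        return ()
    return tuple(s.strip() for s in str(cell).split(";") if s.strip())


def read_docking_table(
    path: PathLike,
) -> tuple[list[DockingRecord], dict[tuple[str, str], float]]:
    """Read docking rows; returns records plus any printed Ki values
    (molar) keyed by (ligand, receptor) for consistency checking."""
    df = _read_csv(path)
    records, printed = [], {}
    for _, row in df.iterrows():
        rec = DockingRecord(
            ligand=str(row["ligand"]),
            receptor=str(row["receptor_pdb"]),
            binding_energy=float(row["binding_energy_kcal_mol"]),
            n_hbonds=int(row.get("n_hbonds", 0) or 0),
            hbond_residues=_split_residues(row.get("hbond_residues")),
            vdw_residues=_split_residues(row.get("vdw_residues")),
        )
        records.append(rec)
        if "ki_printed_value" in df.columns and not pd.isna(row["ki_printed_value"]):
            unit = str(row["ki_printed_unit"]).strip()
            if unit not in _KI_UNIT_SCALE:
                raise ValueError(f"unknown Ki unit {unit!r}")
            printed[(rec.ligand, rec.receptor)] = (
                float(row["ki_printed_value"]) * _KI_UNIT_SCALE[unit]
            )
    if not records:
        raise ValueError(f"no docking records in {path}")
    return records, printed


def read_mmpbsa_components(path: PathLike) -> dict[str, MMPBSAComponents]:
    """Read ``complex,term,value_kcal_mol,sd`` into per-complex components."""
    df = _read_csv(path)
    term_map = {
        "vdw": "vdw",
        "ele": "electrostatic",
        "polar": "polar_solvation",
        "nonpolar": "nonpolar_solvation",
    }
    out = {}
    for cplx, grp in df.groupby("complex", sort=True):
        vals, sds = {}, {}
        for _, row in grp.iterrows():
            term = str(row["term"])
            if term not in term_map:
                raise ValueError(f"unknown MM/PBSA term {term!r}")
            vals[term_map[term]] = float(row["value_kcal_mol"])
            if "sd" in grp.columns and not pd.isna(row["sd"]):
                sds[term_map[term]] = float(row["sd"])
        missing = set(term_map.values()) - set(vals)
        if missing:
            raise ValueError(f"complex {cplx!r} missing terms {sorted(missing)}")
        out[str(cplx)] = MMPBSAComponents(sds=sds or None, **vals)
    if not out:
        raise ValueError(f"no MM/PBSA rows in {path}")
    return out


def read_mic_matrix(path: PathLike) -> MICMatrix:
    """Read ``organism,class,<compound>...`` with NT for not tested."""
    df = _read_csv(path, dtype=str)
    if not {"organism", "class"} <= set(df.columns):
        raise ValueError("MIC file needs 'organism' and 'class' columns")
    compounds = [c for c in df.columns if c not in ("organism", "class")]
    if not compounds:
        raise ValueError("MIC file has no compound columns")
    values = np.full((len(compounds), len(df)), np.nan)
    for j, (_, row) in enumerate(df.iterrows()):
        for i, comp in enumerate(compounds):
            cell = str(row[comp]).strip()
            if cell.upper() in ("NT", "N.T", "NAN", ""):
                continue
            values[i, j] = float(cell)
    return MICMatrix(
        compounds=tuple(compounds),
        organisms=tuple(df["organism"].astype(str)),
        classes=tuple(df["class"].astype(str)),
        values=values,
    )


def write_mic_matrix(matrix: MICMatrix, path: PathLike) -> None:
    data = {"organism": matrix.organisms, "class": matrix.classes}
    for i, comp in enumerate(matrix.compounds):
        col = [
            "NT" if np.isnan(v) else f"{v:g}" for v in matrix.values[i, :]
        ]
        data[comp] = col
    pd.DataFrame(data).to_csv(path, index=False)


def attenuation_frame(
    compound: CompoundSpec,
    results: Sequence[AttenuationResult],
    source: str = "chemshield",
) -> pd.DataFrame:
    """Report-table layout: compound,source,energy_keV,mac,lac,hvl,mfp."""
    return pd.DataFrame(
        {
            "compound": compound.identifier,
            "source": source,
            "energy_keV": [r.energy * 1000.0 for r in results],
            "mac_cm2_g": [r.mac for r in results],
            "lac_cm1": [np.nan if r.lac is None else r.lac for r in results],
            "hvl_cm": [np.nan if r.hvl is None else r.hvl for r in results],
            "mfp_cm": [np.nan if r.mfp is None else r.mfp for r in results],
        }
    )


def write_attenuation_csv(
    frames: Sequence[pd.DataFrame], path: PathLike
) -> None:
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def buildup_frame(curve: BuildupCurve) -> pd.DataFrame:
    rows = []
    for i, e in enumerate(curve.energies):
        for j, x in enumerate(curve.depths):
            rows.append(
                (curve.compound_id, curve.kind, e, curve.zeq[i], x, curve.B[i, j])
            )
    return pd.DataFrame(
        rows,
        columns=["compound", "kind", "energy_MeV", "zeq", "depth_mfp", "B"],
    )


def write_buildup_csv(frames: Sequence[pd.DataFrame], path: PathLike) -> None:
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def tukey_frame(comparisons: Sequence[PairwiseComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair": [f"{a}-{b}" for a, b in (c.pair for c in comparisons)],
            "mean_diff": [c.mean_diff for c in comparisons],
            "q": [c.q for c in comparisons],
            "adj_p": [c.p_adj for c in comparisons],
            "significant": [c.significant for c in comparisons],
        }
    )


# ---------------------------------------------------------------------------
# Packaged reference data
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("chemshield.data").joinpath(name)


def load_reference_xs() -> CrossSectionTable:
    """H/C/N/O photon cross-section reference grid (0.015-15 MeV)."""
    with resources.as_file(_data_path("photon_xs_hcno.csv")) as p:
        return read_xs_table(p)


def load_reference_compounds() -> list[CompoundSpec]:
    """The six candidate compounds 2a-2f (densities unknown)."""
    with resources.as_file(_data_path("compounds.csv")) as p:
        return read_compounds(p)


def load_reference_lac() -> pd.DataFrame:
    """Published LAC values per compound/source/energy (1/cm, keV)."""
    with resources.as_file(_data_path("lac_table.csv")) as p:
        return _read_csv(p)


def load_reference_docking() -> tuple[list[DockingRecord], dict[tuple[str, str], float]]:
    """Docking results for 2d/2f vs four targets, with printed Ki."""
    with resources.as_file(_data_path("docking_table.csv")) as p:
        return read_docking_table(p)


def load_reference_mmpbsa() -> dict[str, MMPBSAComponents]:
    """MM/PBSA components of the 2VF5-2d complex."""
    with resources.as_file(_data_path("mmpbsa_table.csv")) as p:
        return read_mmpbsa_components(p)


def load_reference_mic() -> MICMatrix:
    """MIC matrix of 2a-2f against nine strains."""
    with resources.as_file(_data_path("mic_table.csv")) as p:
        return read_mic_matrix(p)


def load_example_gp(kind: str = "EABF") -> GPParameterTable:
    """Synthetic example G-P parameter table (see file header)."""
    with resources.as_file(_data_path("gp_example_synthetic.csv")) as p:
        return read_gp_table(p, kind=kind)
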