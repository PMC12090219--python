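"""Tidy-CSV table parsing, coordinate reading and provenance records.

All tables are long-format CSV with unit-suffixed column names (time_s,
wavelength_nm, d1_A, ...) so units never depend on a sidecar file. Every
CLI run writes a JSON provenance record (config + seed + package version)
next to its results; re-running from that record reproduces stochastic
outputs bit-identically.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

__all__ = ["parse_table", "read_coordinates", "write_provenance", "TABLE_SCHEMAS"]

# required columns (and which must be numeric) per table kind
TABLE_SCHEMAS: Dict[str, Dict[str, Sequence[str]]] = {
    "curves": {
        "required": ["time_s", "absorbance", "well", "state", "enzyme_conc_uM", "assay"],
        "numeric": ["time_s", "absorbance", "enzyme_conc_uM"],
    },
    "rates": {
        "required": ["state", "x", "y", "se"],
        "numeric": ["x", "y", "se"],
    },
    "spectra": {
        "required": ["wavelength_nm", "absorbance", "sample", "state"],
        "numeric": ["wavelength_nm", "absorbance"],
    },
    "melt": {
        "required": ["temperature_C", "signal"],
        "numeric": ["temperature_C", "signal"],
    },
    "dof": {
        "required": ["frame"],
        "numeric": ["frame"],
    },
    "events": {
        "required": ["time_s", "wavelength_nm"],
        "numeric": ["time_s", "wavelength_nm"],
    },
}

_DOF_VALUE_COLS = ("d1_A", "d2_A", "d3_A", "a1_deg")


class SchemaError(ValueError):
    pass


def parse_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a tidy CSV table.

    Raises a SchemaError naming the missing column, or a ValueError naming
    the first offending row for non-numeric cells. Unrecognized extra
    columns are kept and reported with a warning.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r} "
                         f"(know {sorted(TABLE_SCHEMAS)})")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    spec = TABLE_SCHEMAS[schema]
    for col in spec["required"]:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r} "
                              f"for schema {schema!r}")
    numeric = list(spec["numeric"])
    if schema == "dof":
        present = [c for c in _DOF_VALUE_COLS if c in df.columns]
        if not present:
            raise SchemaError(f"{path.name}: need at least one DOF column "
                              f"of {_DOF_VALUE_COLS}")
        numeric += present
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(f"{path.name}: non-numeric value "
                             f"{df[col].iloc[row]!r} in column {col!r}, "
                             f"row {row + 2} (1-based incl. header)")
        df[col] = coerced
    known = set(spec["required"]) | set(numeric) | {"replica", "cycle",
                                                    "irradiation_time_s"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        warnings.warn(f"{path.name}: ignoring unrecognized columns {extra}",
                      stacklevel=2)
    return df


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def _atom_key(chain: str, resseq: int, atom: str) -> str:
    return f"{chain}/{resseq}/{atom}"


def _read_pdb_frames(path: Path) -> List[Dict[str, np.ndarray]]:
    from Bio.PDB import PDBParser
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate minimal fixture PDBs
        structure = PDBParser(QUIET=True).get_structure("traj", str(path))
    frames = []
    for model in structure:
        atoms: Dict[str, np.ndarray] = {}
        for chain in model:
            for residue in chain:
                for atom in residue:
                    # first altloc wins; Bio.PDB orders altlocs A first
                    key = _atom_key(chain.id, residue.id[1], atom.get_name())
                    atoms.setdefault(key, np.asarray(atom.get_coord(), float))
        frames.append(atoms)
    if not frames:
        raise ValueError(f"{path.name}: no MODEL frames found")
    return frames


def _read_xyz_frames(path: Path) -> List[Dict[str, np.ndarray]]:
    lines = path.read_text().splitlines()
    frames: List[Dict[str, np.ndarray]] = []
    i, frame_idx = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path.name}: bad atom count at frame "
                             f"{frame_idx}") from exc
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path.name}: truncated frame {frame_idx}")
        atoms = {}
        for j, line in enumerate(block):
            parts = line.split()
            atoms[f"{j}/{parts[0]}"] = np.array([float(p) for p in parts[1:4]])
        if frames and len(atoms) != len(frames[0]):
            raise ValueError(f"{path.name}: frame {frame_idx} has "
                             f"{len(atoms)} atoms, expected {len(frames[0])}")
        frames.append(atoms)
        i += 2 + n
        frame_idx += 1
    if not frames:
        raise ValueError(f"{path.name}: empty XYZ file")
    return frames


def read_coordinates(path) -> List[Dict[str, np.ndarray]]:
    """Read per-frame atom positions (Å) from a multi-MODEL PDB or XYZ file.

    Returns one ``{atom_key: xyz}`` mapping per frame. PDB keys are
    ``chain/resseq/atom_name``; XYZ keys are ``index/element``.
    """
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        return _read_pdb_frames(path)
    if path.suffix.lower() == ".xyz":
        return _read_xyz_frames(path)
    raise ValueError(f"unsupported coordinate format: {path.suffix!r}")


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def write_provenance(out_dir, command: str, config: Dict) -> Path:
    """Write the machine-readable run record next to the results."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {"command": command, "config": config, "version": __version__}
    path = out_dir / f"{command}_provenance.json"
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return path
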