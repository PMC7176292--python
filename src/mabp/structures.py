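"""PDB structure I/O for atom selections and representative poses.

Parsing and writing are delegated to biotite; this module adds the
package-facing conveniences: a tabular atom view with 0-based indices
(PDB serials stay 1-based in the file), a highest-occupancy altloc
policy, and pre-validation that reports malformed coordinate records
with their line numbers.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)


def _validate_coordinate_records(path) -> None:
    bad: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                bad.append(lineno)
                continue
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                bad.append(lineno)
    if bad:
        shown = ", ".join(str(n) for n in bad[:10])
        raise ValueError(
            f"{path}: malformed ATOM/HETATM records at line(s) {shown}"
            + (" ..." if len(bad) > 10 else "")
        )


def read_structure(path) -> pd.DataFrame:
    """Read PDB ATOM/HETATM records into an atom table.

    Columns: ``index`` (0-based), ``serial`` (1-based PDB serial), ``name``,
    ``resname``, ``chain``, ``resid``, ``x``, ``y``, ``z`` (Å), ``element``,
    ``hetero``. When alternate locations are present only the
    highest-occupancy altloc of each atom is kept (logged).
    """
    _validate_coordinate_records(path)
    pdb = PDBFile.read(path)
    n_raw = sum(
        1 for ln in pdb.lines if ln.startswith(("ATOM", "HETATM"))
    )
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    if atoms.array_length() < n_raw:
        logger.info(
            "%s: kept highest-occupancy altloc (%d of %d coordinate records)",
            path,
            atoms.array_length(),
            n_raw,
        )
    n = atoms.array_length()
    return pd.DataFrame(
        {
            "index": np.arange(n),
            "serial": np.arange(1, n + 1),
            "name": atoms.atom_name,
            "resname": atoms.res_name,
            "chain": atoms.chain_id,
            "resid": atoms.res_id,
            "x": atoms.coord[:, 0].astype(float),
            "y": atoms.coord[:, 1].astype(float),
            "z": atoms.coord[:, 2].astype(float),
            "element": atoms.element,
            "hetero": atoms.hetero,
        }
    )


def write_structure(path, table: pd.DataFrame, coords: np.ndarray | None = None) -> None:
    """Write an atom table (optionally with replacement coordinates) as PDB."""
    n = len(table)
    atoms = struc.AtomArray(n)
    atoms.atom_name = table["name"].to_numpy(dtype="U6")
    atoms.res_name = table["resname"].to_numpy(dtype="U5")
    atoms.chain_id = table["chain"].to_numpy(dtype="U4")
    atoms.res_id = table["resid"].to_numpy(dtype=int)
    atoms.element = table["element"].to_numpy(dtype="U2")
    atoms.hetero = table["hetero"].to_numpy(dtype=bool)
    xyz = (
        np.column_stack([table["x"], table["y"], table["z"]])
        if coords is None
        else np.asarray(coords, dtype=float)
    )
    atoms.coord = xyz.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(path)


def write_pose_pdb(path, coords: np.ndarray, names=None, resname: str = "LIG") -> None:
    """Write a single ligand pose (n, 3) as a minimal HETATM-only PDB."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    names = list(names) if names is not None else [f"C{i + 1}" for i in range(n)]
    atoms = struc.AtomArray(n)
    atoms.atom_name = np.array(names, dtype="U6")
    atoms.res_name = np.full(n, resname, dtype="U5")
    atoms.chain_id = np.full(n, "L", dtype="U4")
    atoms.res_id = np.ones(n, dtype=int)
    atoms.element = np.array([nm[0] for nm in names], dtype="U2")
    atoms.hetero = np.ones(n, dtype=bool)
    atoms.coord = coords.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(path)
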