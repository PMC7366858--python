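"""Structure/trajectory output and report export.

PDB files carry one CA atom per protein residue (numbering 1-185) plus
HETATM records for the nucleotide beads (residue GDP/GTP), Mg²⁺ and
the farnesyl bead.  Multi-model PDB holds ensembles; DCD output (with
a PDB topology) is available through mdtraj.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Union

import numpy as np
import pandas as pd

from .engine import EnsembleRecord
from .model import (Conformation, Topology, N_PROTEIN, RESID_FARNESYL,
                    RESID_MG, RESID_NUCLEOTIDE)

logger = logging.getLogger(__name__)

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

_NUC_ATOM_NAMES = ("BAS", "PA", "PB", "PG")


def _atom_array(topology: Topology, coords: np.ndarray):
    import biotite.structure as struc

    n = topology.n_beads
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    chain = np.full(n, "A", dtype="U4")
    res_id = topology.residue_index.astype(int)
    res_name = np.empty(n, dtype="U5")
    atom_name = np.empty(n, dtype="U6")
    element = np.full(n, "C", dtype="U2")
    hetero = np.zeros(n, dtype=bool)
    nuc_count = 0
    for i in range(n):
        rid = res_id[i]
        if rid <= N_PROTEIN:
            res_name[i] = _AA3[topology.sequence[rid - 1]]
            atom_name[i] = "CA"
        elif rid == RESID_NUCLEOTIDE:
            res_name[i] = topology.state_tag
            atom_name[i] = _NUC_ATOM_NAMES[nuc_count]
            element[i] = "P" if nuc_count else "C"
            nuc_count += 1
            hetero[i] = True
        elif rid == RESID_MG:
            res_name[i] = "MG"
            atom_name[i] = "MG"
            element[i] = "MG"
            hetero[i] = True
        elif rid == RESID_FARNESYL:
            res_name[i] = "FAR"
            atom_name[i] = "FAR"
            hetero[i] = True
    arr.chain_id = chain
    arr.res_id = res_id
    arr.res_name = res_name
    arr.atom_name = atom_name
    arr.element = element
    arr.hetero = hetero
    return arr


def write_structure(topology: Topology, data, path: Union[str, Path],
                    fmt: str = "pdb") -> Path:
    """Write a Conformation or an EnsembleRecord.

    fmt='pdb' writes a (multi-model) PDB; fmt='dcd' writes a DCD
    trajectory plus a sibling '<stem>_top.pdb' topology file.
    """
    path = Path(path)
    if isinstance(data, Conformation):
        frames = np.asarray(data.coordinates)[None, :, :]
    elif isinstance(data, EnsembleRecord):
        frames = np.asarray(data.coordinates)
    else:
        frames = np.asarray(data)
        if frames.ndim == 2:
            frames = frames[None]
    if fmt == "pdb":
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        stack = struc.stack([_atom_array(topology, f) for f in frames])
        f = pdb.PDBFile()
        f.set_structure(stack)
        f.write(str(path))
        return path
    if fmt == "dcd":
        import mdtraj as md

        top_path = path.with_name(path.stem + "_top.pdb")
        write_structure(topology, frames[0], top_path, fmt="pdb")
        traj = md.Trajectory(frames / 10.0, md.load(str(top_path)).topology)
        traj.save_dcd(str(path))
        return path
    raise ValueError(f"unknown format {fmt!r}")


def export_reports(outputs: Dict[str, object], out_dir: Union[str, Path]
                   ) -> Dict[str, Path]:
    """Write analysis outputs: one CSV per table, one JSON per mapping.

    ``outputs`` maps a base name to a DataFrame (CSV) or a JSON-able
    mapping (JSON).  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    for name, obj in outputs.items():
        if isinstance(obj, pd.DataFrame):
            p = out_dir / f"{name}.csv"
            obj.to_csv(p, index=False)
        else:
            p = out_dir / f"{name}.json"
            with open(p, "w") as fh:
                json.dump(obj, fh, indent=2, default=_json_default)
        written[name] = p
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
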