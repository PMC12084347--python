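"""File IO: trajectory formats, peak lists, curves, and images.

Synthetic fixtures are written as PDB (topology) plus multi-frame XYZ with
the box edge on each comment line; real trajectories (PDB/DCD/XTC) are read
through MDAnalysis.  Tabular data go through CSV/TSV; images through 16-bit
TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = [
    "write_pdb",
    "write_xyz",
    "read_xyz",
    "load_trajectory",
    "write_tiff",
    "read_image",
    "write_truth_json",
]

DEFAULT_COSOLVENT_RESNAMES = ("HD6", "HD2", "HEX", "PDO", "BDO")


def write_pdb(traj: Trajectory, path) -> None:
    """Write frame 0 as a PDB topology (residue names, element columns)."""
    top = traj.topology
    coords = traj.coords[0]
    with open(path, "w") as fh:
        box = traj.box[0]
        fh.write(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        for k, row in enumerate(top.itertuples(index=False)):
            if row.molecule_kind == "protein":
                resname = {"HD6": "HD6"}.get(row.residue_type, row.residue_type)
                resname = (resname + "LY")[:3] if len(resname) == 1 else resname[:3]
                resid = int(row.residue_index)
            else:
                resname = str(row.residue_type)[:3]
                resid = int(row.molecule_id) % 10000
            x, y, z = coords[k]
            fh.write(
                f"ATOM  {(k + 1) % 100000:5d} {row.atom_name:<4.4s} {resname:>3.3s} A"
                f"{resid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {row.element:>2.2s}\n"
            )
        fh.write("END\n")


def write_xyz(traj: Trajectory, path) -> None:
    """Multi-frame XYZ in Angstrom with 'box a b c' on each comment line."""
    top = traj.topology
    elements = top["element"].to_numpy()
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            a, b, c = traj.box[f]
            fh.write(f"box {a:.6f} {b:.6f} {c:.6f}\n")
            for el, (x, y, z) in zip(elements, traj.coords[f]):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a multi-frame XYZ written by :func:`write_xyz`.

    Returns (coords (F, A, 3), box (F, 3)); raises if the comment line does
    not carry the box record.
    """
    frames, boxes = [], []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline().split()
            if len(comment) < 4 or comment[0] != "box":
                raise ValueError("XYZ comment line missing 'box a b c' record")
            boxes.append([float(v) for v in comment[1:4]])
            xyz = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                xyz[i] = [float(v) for v in parts[1:4]]
            frames.append(xyz)
    return np.stack(frames), np.asarray(boxes)


def load_trajectory(
    topology_path,
    trajectory_path=None,
    cosolvent_resnames: Sequence[str] = DEFAULT_COSOLVENT_RESNAMES,
    replica_id: int = 0,
) -> Trajectory:
    """Load a trajectory via MDAnalysis (PDB topology; DCD/XTC/PDB coords).

    Our own XYZ convention (box on the comment line) is handled natively;
    other coordinate formats go through MDAnalysis, which converts nm-based
    formats to Angstrom.  Heavy atoms are those with element != H; cosolvent
    molecules are recognized by residue name.
    """
    import MDAnalysis as mda

    topology_path = str(topology_path)
    if trajectory_path is not None and str(trajectory_path).endswith(".xyz"):
        u = mda.Universe(topology_path)
        coords, box = read_xyz(trajectory_path)
    else:
        u = (
            mda.Universe(topology_path, str(trajectory_path))
            if trajectory_path
            else mda.Universe(topology_path)
        )
        coords = np.stack([ts.positions.copy() for ts in u.trajectory])
        box = np.stack([ts.dimensions[:3].copy() for ts in u.trajectory])

    atoms = u.atoms
    try:
        elements = np.array([e if e else g[0] for e, g in
                             zip(atoms.elements, atoms.names)])
    except mda.exceptions.NoDataError:
        elements = np.array([mda.topology.guessers.guess_atom_element(n)
                             for n in atoms.names])
    resnames = atoms.resnames
    is_cosolvent = np.isin(resnames, list(cosolvent_resnames))
    try:
        masses = atoms.masses
    except mda.exceptions.NoDataError:
        masses = np.where(elements == "H", 1.008, 12.011)

    # 1-based contiguous residue indices within the protein molecule
    prot_resids = {}
    residue_index = np.zeros(len(atoms), dtype=int)
    molecule_id = np.zeros(len(atoms), dtype=int)
    for k, atom in enumerate(atoms):
        if is_cosolvent[k]:
            molecule_id[k] = atom.resid
        else:
            key = (atom.segid, atom.resid)
            prot_resids.setdefault(key, len(prot_resids) + 1)
            residue_index[k] = prot_resids[key]

    backbone_names = {"N", "CA", "C", "O", "H", "HA", "HN", "OXT", "BB"}
    topology = pd.DataFrame(
        {
            "residue_index": residue_index,
            "residue_type": [
                rn if cs else _one_letter(rn)
                for rn, cs in zip(resnames, is_cosolvent)
            ],
            "atom_name": atoms.names,
            "element": elements,
            "mass": masses,
            "heavy": elements != "H",
            "sidechain": [
                (not cs) and (nm not in backbone_names)
                for nm, cs in zip(atoms.names, is_cosolvent)
            ],
            "molecule_id": molecule_id,
            "molecule_kind": np.where(is_cosolvent, "cosolvent", "protein"),
        }
    )
    return Trajectory(
        topology=topology, coords=coords, box=box, replica_id=replica_id
    )


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _one_letter(resname: str) -> str:
    resname = resname.upper()
    if resname in _THREE_TO_ONE:
        return _THREE_TO_ONE[resname]
    if len(resname) == 3 and resname[1:] == "LY":  # our pseudo-residue names
        return resname[0]
    return resname


def write_tiff(image: np.ndarray, path) -> None:
    """Write a grayscale image as 16-bit TIFF."""
    import tifffile

    tifffile.imwrite(
        str(path),
        np.round(np.clip(np.asarray(image), 0, 65535)).astype(np.uint16),
    )


def read_image(path) -> np.ndarray:
    """Read a grayscale TIFF/PNG image as a float array."""
    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        import tifffile

        return tifffile.imread(p).astype(float)
    from skimage.io import imread

    img = imread(p)
    if img.ndim == 3:
        raise ValueError("expected a single-channel image")
    return img.astype(float)


def write_truth_json(truth: dict, path) -> None:
    """Serialize a ground-truth record (arrays become lists) as JSON."""
    def _clean(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in v.items()}
        return v

    Path(path).write_text(json.dumps({k: _clean(v) for k, v in truth.items()}, indent=1))
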