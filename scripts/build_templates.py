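"""Regenerate the packaged amino-acid templates under src/ticseq/data/templates.

Each template is a single residue with N-terminal hydrogens and a C-terminal
OH cap, taken from idealised small-molecule geometry (biotite's component
dictionary), then oriented for the channel frame: backbone N->C direction
along +z, backbone (N, CA, C) centroid at the origin, and the CA->CB
direction (CA->HA2 for glycine) in the x-z plane with positive x.

Usage: python scripts/build_templates.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import biotite.structure.info as info

RESIDUES = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

OUT = Path(__file__).resolve().parents[1] / "src" / "ticseq" / "data" / "templates"


def orient(names, coords):
    idx = {n: i for i, n in enumerate(names)}
    n_, ca, c = coords[idx["N"]], coords[idx["CA"]], coords[idx["C"]]
    origin = (n_ + ca + c) / 3.0
    coords = coords - origin
    ez = coords[idx["C"]] - coords[idx["N"]]
    ez = ez / np.linalg.norm(ez)
    ref_name = "CB" if "CB" in idx else ("HA2" if "HA2" in idx else "O")
    ref = coords[idx[ref_name]] - coords[idx["CA"]]
    ex = ref - np.dot(ref, ez) * ez
    ex = ex / np.linalg.norm(ex)
    ey = np.cross(ez, ex)
    R = np.stack([ex, ey, ez])  # rows are the new basis
    return coords @ R.T


def write_pdb(path, res_code, names, elements, coords):
    lines = []
    for i, (name, el, xyz) in enumerate(zip(names, elements, coords), start=1):
        pdb_name = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            f"ATOM  {i:5d} {pdb_name}{'':1s}{res_code:>3s} A{1:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {el:>2s}  "
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for code in RESIDUES:
        res = info.residue(code)
        names = list(res.atom_name)
        elements = [e.capitalize() for e in res.element]
        coords = orient(names, np.asarray(res.coord, dtype=float))
        write_pdb(OUT / f"{code}.pdb", code, names, elements, coords)
        print(f"{code}: {len(names)} atoms")
    return 0


if __name__ == "__main__":
    sys.exit(main())
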