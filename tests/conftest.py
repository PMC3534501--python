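"""Shared fixtures: tiny in-memory PDB/mmCIF/DSSP texts and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from domaincut._types import CalphaSet, Residue


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    x: float,
    y: float,
    z: float,
    element: str = "C",
    altloc: str = " ",
    icode: str = " ",
) -> str:
    return (
        f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}{resnum:4d}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def make_ca_pdb(records: list[tuple[str, int, float, float, float]]) -> str:
    """CA-only PDB text from (chain, resnum, x, y, z) tuples."""
    lines = []
    serial = 1
    prev_chain = None
    for chain, num, x, y, z in records:
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        lines.append(pdb_atom_line(serial, "CA", "ALA", chain, num, x, y, z))
        serial += 1
        prev_chain = chain
    lines += ["TER", "END", ""]
    return "\n".join(lines)


def dssp_line(serial: int, resnum: int, chain: str, aa: str, ss: str, sheet: str = " ") -> str:
    line = f"{serial:5d}{resnum:5d} {chain} {aa}  {ss}"
    return line.ljust(33) + sheet

def make_dssp(rows: list[tuple[int, str, str, str]], sheets: list[str] | None = None) -> str:
    """Classic DSSP text from (resnum, chain, aa, ss_code) rows."""
    header = [
        "==== Secondary Structure Definition by the program DSSP ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    TCO",
    ]
    body = [
        dssp_line(i + 1, num, chain, aa, ss, (sheets or [" "] * len(rows))[i])
        for i, (num, chain, aa, ss) in enumerate(rows)
    ]
    return "\n".join(header + body) + "\n"


def calphas_from_coords(coords: np.ndarray, chain: str = "A", start: int = 1) -> CalphaSet:
    coords = np.asarray(coords, dtype=float)
    residues = [Residue(chain, start + i) for i in range(len(coords))]
    return CalphaSet(residues, coords)


THREE_RESIDUE_PDB = make_ca_pdb(
    [("A", 1, 0.0, 0.0, 0.0), ("A", 2, 3.8, 0.0, 0.0), ("A", 3, 7.6, 0.0, 0.0)]
)

THREE_RESIDUE_MMCIF = """\
data_test
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 C CA . ALA A 1 1 ? 0.000 0.000 0.000 1.00 0.00 1 A 1
ATOM 2 C CA . ALA A 1 2 ? 3.800 0.000 0.000 1.00 0.00 2 A 1
ATOM 3 C CA . ALA A 1 3 ? 7.600 0.000 0.000 1.00 0.00 3 A 1
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_RESIDUE_PDB)
    return p


@pytest.fixture
def three_residue_mmcif(tmp_path):
    p = tmp_path / "three.cif"
    p.write_text(THREE_RESIDUE_MMCIF)
    return p


@pytest.fixture
def two_chain_pdb(tmp_path):
    text = make_ca_pdb(
        [
            ("A", 1, 0.0, 0.0, 0.0),
            ("A", 2, 3.8, 0.0, 0.0),
            ("B", 1, 20.0, 0.0, 0.0),
            ("B", 2, 23.8, 0.0, 0.0),
            ("B", 3, 27.6, 0.0, 0.0),
        ]
    )
    p = tmp_path / "two_chain.pdb"
    p.write_text(text)
    return p


@pytest.fixture
def two_model_pdb(tmp_path):
    body1 = make_ca_pdb([("A", 1, 0, 0, 0), ("A", 2, 3.8, 0, 0), ("A", 3, 7.6, 0, 0)])
    body2 = make_ca_pdb([("A", 1, 1, 0, 0), ("A", 2, 4.8, 0, 0), ("A", 3, 8.6, 0, 0)])
    text = (
        "MODEL        1\n"
        + body1.replace("END\n", "ENDMDL\n")
        + "MODEL        2\n"
        + body2.replace("END\n", "ENDMDL\n")
        + "END\n"
    )
    p = tmp_path / "two_model.pdb"
    p.write_text(text)
    return p
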