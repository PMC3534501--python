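"""Reading protein structures and extracting alpha-carbon traces.

PDB and mmCIF files are parsed with gemmi. Only the first model is used;
waters and pure heteroatom residues are dropped; alternate locations other
than '' / 'A' are ignored. Non-standard amino acids that carry a Calpha
(e.g. MSE) are retained. Author residue numbering, with insertion codes,
is the public coordinate system.
"""

from __future__ import annotations

import logging
import os

import gemmi
import numpy as np

from ._types import CalphaSet, Residue

logger = logging.getLogger(__name__)

__all__ = [
    "StructureError",
    "load_structure",
    "extract_calphas",
    "write_calphas_pdb",
]


class StructureError(ValueError):
    pass


def load_structure(path: str | os.PathLike, fmt: str = "auto") -> gemmi.Structure:
    """Read a PDB or mmCIF file and return its first model only.

    Parameters
    ----------
    path : file path
    fmt : {"pdb", "mmcif", "auto"}
        "auto" dispatches on the file extension (.cif/.mmcif -> mmCIF).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise StructureError(f"no such file: {path}")
    if fmt == "auto":
        fmt = "mmcif" if path.lower().endswith((".cif", ".mmcif", ".cif.gz")) else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(path)
        elif fmt == "mmcif":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"failed to parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models found")
    while len(st) > 1:  # keep model 1 only
        del st[1]
    st.setup_entities()
    if _count_protein_residues(st) == 0:
        raise StructureError(f"{path}: no protein residues with coordinates")
    return st


def _is_protein_residue(res: gemmi.Residue) -> bool:
    if res.is_water():
        return False
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_amino_acid():
        return True
    # unknown residue names: require a peptide-like backbone
    names = {a.name for a in res}
    return {"N", "CA", "C"}.issubset(names)


def _get_ca(res: gemmi.Residue) -> gemmi.Atom | None:
    for atom in res:
        if atom.name == "CA" and atom.element.name == "C" and atom.altloc in ("\0", "", "A"):
            return atom
    return None


def _count_protein_residues(st: gemmi.Structure) -> int:
    return sum(
        1 for chain in st[0] for res in chain if _is_protein_residue(res)
    )


def extract_calphas(
    structure: gemmi.Structure, chains: list[str] | None = None
) -> CalphaSet:
    """Collect the ordered Calpha trace of the selected chains.

    Residues without a Calpha are omitted with a warning. Raises if a
    requested chain does not exist or no Calpha survives.
    """
    model = structure[0]
    available = [ch.name for ch in model]
    if chains is not None:
        missing = [c for c in chains if c not in available]
        if missing:
            raise StructureError(
                f"chain(s) {missing} not found; available: {available}"
            )
    residues: list[Residue] = []
    coords: list[list[float]] = []
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for res in chain:
            if not _is_protein_residue(res):
                continue
            ca = _get_ca(res)
            if ca is None:
                logger.warning(
                    "residue %s %s%s in chain %s has no Calpha; omitted",
                    res.name,
                    res.seqid.num,
                    res.seqid.icode.strip(),
                    chain.name,
                )
                continue
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    insertion_code=res.seqid.icode.strip(),
                    name=res.name,
                )
            )
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
    if not residues:
        raise StructureError("no Calpha atoms found in the selected chains")
    return CalphaSet(residues, np.array(coords))


def write_calphas_pdb(calphas: CalphaSet, path: str | os.PathLike) -> None:
    """Write a Calpha-only PDB file (ATOM records, one CA per residue)."""
    st = gemmi.Structure()
    st.add_model(gemmi.Model("1"))
    model = st[0]
    for (chain_id, lo, hi) in calphas.chain_ranges():
        chain = gemmi.Chain(chain_id)
        for i in range(lo, hi):
            r = calphas.residues[i]
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.seq_number, r.insertion_code or " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*calphas.coords[i])
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.setup_entities()
    st.write_pdb(os.fspath(path))
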