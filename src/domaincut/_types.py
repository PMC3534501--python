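"""Shared container types for domain assignment.

The coordinate system exposed to users is (chain id, author residue number,
insertion code); internal indices are 0-based and contiguous over the
alpha-carbon trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Residue:
    """One residue of a protein chain, identified by author numbering."""

    chain_id: str
    seq_number: int
    insertion_code: str = ""
    name: str = "ALA"


class CalphaSet:
    """Ordered alpha-carbon trace over one or more chains.

    Residues are stored chain-major in file order; every residue has a
    finite 3D Calpha coordinate in Angstroms.
    """

    def __init__(self, residues: list[Residue], coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if len(residues) != len(coords):
            raise ValueError("residues and coords length mismatch")
        if len(residues) == 0:
            raise ValueError("CalphaSet must contain at least one residue")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite Calpha coordinate")
        self.residues = list(residues)
        self.coords = coords
        self.chain_starts = [0] + [
            i
            for i in range(1, len(residues))
            if residues[i].chain_id != residues[i - 1].chain_id
        ]
        seen: set[tuple[str, int, str]] = set()
        for r in self.residues:
            key = (r.chain_id, r.seq_number, r.insertion_code)
            if key in seen:
                raise ValueError(f"duplicate residue identity {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain ids in order of first appearance."""
        out: list[str] = []
        for r in self.residues:
            if not out or out[-1] != r.chain_id:
                out.append(r.chain_id)
        return out

    def chain_ranges(self) -> list[tuple[str, int, int]]:
        """(chain_id, start_index, end_index_exclusive) per chain."""
        bounds = self.chain_starts + [len(self)]
        return [
            (self.residues[bounds[i]].chain_id, bounds[i], bounds[i + 1])
            for i in range(len(self.chain_starts))
        ]

    def subset(self, indices: list[int]) -> "CalphaSet":
        return CalphaSet([self.residues[i] for i in indices], self.coords[indices])


@dataclass
class DomainAssignment:
    """Per-residue domain labels (1..k) over a CalphaSet."""

    calphas: CalphaSet
    labels: np.ndarray  # int array, values 1..k

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.calphas):
            raise ValueError("labels length must match CalphaSet")
        if self.labels.min() < 1:
            raise ValueError("domain labels are 1-based")

    @property
    def n_domains(self) -> int:
        return len(set(self.labels.tolist()))

    def segments(self) -> list[tuple[int, str, str, str]]:
        """Contiguous same-domain segments as (domain, chain, first, last).

        First/last are author residue identifiers (number plus insertion
        code) so the segments round-trip through the TSV interchange format.
        """
        segs = []
        res = self.calphas.residues
        start = 0
        for i in range(1, len(res) + 1):
            if (
                i == len(res)
                or res[i].chain_id != res[start].chain_id
                or self.labels[i] != self.labels[start]
            ):
                segs.append(
                    (
                        int(self.labels[start]),
                        res[start].chain_id,
                        _res_id(res[start]),
                        _res_id(res[i - 1]),
                    )
                )
                start = i
        return segs

    def renumbered(self) -> "DomainAssignment":
        """Relabel domains 1..k in order of first appearance."""
        mapping: dict[int, int] = {}
        for lab in self.labels:
            if int(lab) not in mapping:
                mapping[int(lab)] = len(mapping) + 1
        return DomainAssignment(
            self.calphas, np.array([mapping[int(x)] for x in self.labels])
        )


def _res_id(r: Residue) -> str:
    return f"{r.seq_number}{r.insertion_code}"
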