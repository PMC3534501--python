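"""Secondary-structure annotations and the vector representation of elements.

Per-residue labels come from DSSP output (classic tabular format, the
mmCIF-style variant, or a plain 3-column TSV). Each maximal helix/strand
run becomes an SSElement: a line segment through the run's centre of mass,
directed along the principal axis of the member Calpha coordinates and
oriented N->C.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np

from ._types import CalphaSet

logger = logging.getLogger(__name__)

__all__ = [
    "SSAnnotation",
    "SSElement",
    "GeometryError",
    "AnnotationMismatchError",
    "parse_dssp",
    "parse_label_table",
    "extract_elements",
    "element_vector",
    "element_distance",
]

HELIX = "helix"
STRAND = "strand"
COIL = "coil"

#: DSSP summary codes mapped to the three-state alphabet. 3_10 (G) and pi
#: (I) helices behave like alpha helices geometrically and are folded in.
_DSSP_MAP = {"H": HELIX, "G": HELIX, "I": HELIX, "E": STRAND}

#: Calpha-Calpha distance above which consecutive residues are treated as a
#: chain break (peptide-bonded CA pairs sit near 3.8 A).
CHAIN_BREAK_DISTANCE = 4.5


class GeometryError(ValueError):
    pass


class AnnotationMismatchError(ValueError):
    pass


@dataclass
class SSAnnotation:
    """Three-state labels aligned to a CalphaSet, plus optional sheet ids."""

    labels: list[str]  # values in {helix, strand, coil}
    sheet_ids: list[str | None]  # DSSP sheet letter for strand residues

    def __post_init__(self):
        bad = set(self.labels) - {HELIX, STRAND, COIL}
        if bad:
            raise ValueError(f"unknown labels {bad}")
        if len(self.sheet_ids) != len(self.labels):
            raise ValueError("sheet_ids length mismatch")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SSElement:
    """A helix or strand as a directed 3D line segment.

    ``c`` is the centre of mass of the member Calphas, ``v`` the unit
    principal-axis direction oriented so v . (r2 - r1) >= 0, and the
    endpoints are the projections of the first/last member Calpha onto the
    axis line: start = c + ((r1 - c) . v) v, end = c + ((r2 - c) . v) v.
    """

    kind: str
    member_indices: list[int]
    c: np.ndarray
    v: np.ndarray
    start_point: np.ndarray
    end_point: np.ndarray
    r1: np.ndarray
    r2: np.ndarray

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.start_point + self.end_point)


def _three_state(code: str) -> str:
    return _DSSP_MAP.get(code, COIL)


def parse_dssp(path: str | os.PathLike, calphas: CalphaSet) -> SSAnnotation:
    """Read a DSSP output file and align its labels to ``calphas``.

    Classic (.dssp) and mmCIF-style outputs are auto-detected. Residues of
    the CalphaSet absent from the file default to coil; a chain entirely
    absent triggers a warning. Raises AnnotationMismatchError when no
    residue matches at all.
    """
    path = os.fspath(path)
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().startswith("data_") or "_dssp_struct_summary" in text:
        records = _parse_dssp_mmcif(text)
    else:
        records = _parse_dssp_classic(text)
    return _align(records, calphas)


def _parse_dssp_classic(text: str) -> dict[tuple[str, int, str], tuple[str, str | None]]:
    """Fixed-column classic DSSP: residue lines follow the '#  RESIDUE' header."""
    records: dict[tuple[str, int, str], tuple[str, str | None]] = {}
    in_table = False
    for line in text.splitlines():
        if not in_table:
            if line.lstrip().startswith("#  RESIDUE"):
                in_table = True
            continue
        if len(line) < 17 or line[13] == "!":  # chain break marker
            continue
        try:
            num = int(line[5:10])
        except ValueError:
            continue
        icode = line[10].strip()
        chain = line[11].strip()
        ss = line[16]
        sheet = line[33].strip() or None if len(line) > 33 else None
        records[(chain, num, icode)] = (_three_state(ss), sheet)
    return records


def _parse_dssp_mmcif(text: str) -> dict[tuple[str, int, str], tuple[str, str | None]]:
    import gemmi

    doc = gemmi.cif.read_string(text)
    block = doc.sole_block()
    table = block.find(
        "_dssp_struct_summary.",
        ["label_asym_id", "label_seq_id", "secondary_structure"],
    )
    if len(table) == 0:
        raise AnnotationMismatchError("no _dssp_struct_summary loop found")
    records: dict[tuple[str, int, str], tuple[str, str | None]] = {}
    for row in table:
        chain = row[0]
        try:
            num = int(row[1])
        except ValueError:
            continue
        code = row[2].strip(".?")
        records[(chain, num, "")] = (_three_state(code[:1] if code else " "), None)
    return records


def parse_label_table(path: str | os.PathLike, calphas: CalphaSet) -> SSAnnotation:
    """Read a 3-column TSV (chain, residue, label in {H, E, C}).

    An annotation escape hatch for labels from any source; residue is the
    author number with optional insertion code suffix.
    """
    records: dict[tuple[str, int, str], tuple[str, str | None]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            chain, resid, code = parts
            num, icode = _split_resid(resid)
            records[(chain, num, icode)] = (_three_state(code.upper()), None)
    return _align(records, calphas)


def _split_resid(resid: str) -> tuple[int, str]:
    if resid and resid[-1].isalpha():
        return int(resid[:-1]), resid[-1]
    return int(resid), ""


def _align(
    records: dict[tuple[str, int, str], tuple[str, str | None]], calphas: CalphaSet
) -> SSAnnotation:
    labels: list[str] = []
    sheets: list[str | None] = []
    hits = 0
    missing_chains: set[str] = set()
    for r in calphas.residues:
        key = (r.chain_id, r.seq_number, r.insertion_code)
        if key in records:
            lab, sheet = records[key]
            hits += 1
        else:
            lab, sheet = COIL, None
            missing_chains.add(r.chain_id)
        labels.append(lab)
        sheets.append(sheet)
    if hits == 0:
        raise AnnotationMismatchError(
            "no residue of the structure was found in the annotation file"
        )
    present_chains = {key[0] for key in records}
    for ch in sorted(missing_chains - present_chains):
        logger.warning("chain %s absent from annotation; treated as all-coil", ch)
    return SSAnnotation(labels=labels, sheet_ids=sheets)


def element_vector(
    coords: np.ndarray, r1: np.ndarray, r2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Principal-axis vector of a set of Calpha coordinates.

    Returns (c, v, start_point, end_point): the centroid, the unit
    eigenvector of the 3x3 coordinate covariance with the largest
    eigenvalue (sign-fixed so v . (r2 - r1) >= 0), and the projections of
    r1/r2 onto the axis line through c.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 3:
        raise GeometryError("need at least 3 points to fit an element vector")
    c = coords.mean(axis=0)
    centered = coords - c
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 1e-12:
        raise GeometryError("degenerate element: all points coincide")
    if evals[-1] - evals[-2] <= 1e-12 * max(evals[-1], 1.0):
        # tie between the two largest axes: pick deterministically
        logger.warning("degenerate principal axis; breaking tie by |x| then |y|")
        cands = evecs[:, -2:]
        order = np.lexsort((-np.abs(cands[1]), -np.abs(cands[0])))
        v = cands[:, order[0]]
    else:
        v = evecs[:, -1]
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if float(v @ (r2 - r1)) < 0:
        v = -v
    v = v / np.linalg.norm(v)
    start = c + (float((r1 - c) @ v)) * v
    end = c + (float((r2 - c) @ v)) * v
    return c, v, start, end


def extract_elements(
    ann: SSAnnotation, calphas: CalphaSet, min_len: int = 3
) -> list[SSElement]:
    """Build SSElements from maximal same-label helix/strand runs.

    Runs are split at chain boundaries and at chain breaks (consecutive
    Calpha-Calpha distance > 4.5 A or a gap in author numbering); runs
    shorter than ``min_len`` are demoted to coil.
    """
    if len(ann) != len(calphas):
        raise AnnotationMismatchError("annotation length does not match CalphaSet")
    elements: list[SSElement] = []
    runs: list[tuple[str, list[int]]] = []
    cur_kind: str | None = None
    cur: list[int] = []
    res = calphas.residues
    coords = calphas.coords
    for i in range(len(calphas)):
        lab = ann.labels[i]
        broke = False
        if cur:
            j = cur[-1]
            same_chain = res[i].chain_id == res[j].chain_id
            diff = res[i].seq_number - res[j].seq_number
            gap = not (0 <= diff <= 1)  # 0 allows insertion-code series
            far = np.linalg.norm(coords[i] - coords[j]) > CHAIN_BREAK_DISTANCE
            broke = not same_chain or gap or far
        if lab == cur_kind and not broke:
            cur.append(i)
        else:
            if cur_kind in (HELIX, STRAND):
                runs.append((cur_kind, cur))
            cur_kind, cur = lab, [i]
    if cur_kind in (HELIX, STRAND):
        runs.append((cur_kind, cur))
    for kind, members in runs:
        if len(members) < min_len:
            continue
        pts = coords[members]
        r1, r2 = coords[members[0]], coords[members[-1]]
        try:
            c, v, start, end = element_vector(pts, r1, r2)
        except GeometryError:
            logger.warning("degenerate element at indices %s skipped", members)
            continue
        elements.append(
            SSElement(
                kind=kind,
                member_indices=list(members),
                c=c,
                v=v,
                start_point=start,
                end_point=end,
                r1=r1,
                r2=r2,
            )
        )
    return elements


def element_distance(e1: SSElement, e2: SSElement, metric: str = "midpoint") -> float:
    """Distance in Angstroms between two elements.

    ``midpoint``: Euclidean distance between segment midpoints.
    ``closest``: minimum distance between the 3D segments [start, end].
    """
    if metric == "midpoint":
        return float(np.linalg.norm(e1.midpoint - e2.midpoint))
    if metric == "closest":
        return segment_distance(
            e1.start_point, e1.end_point, e2.start_point, e2.end_point
        )
    raise ValueError(f"unknown metric {metric!r}")


def segment_distance(
    p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray
) -> float:
    """Minimum distance between segments [p1,q1] and [p2,q2].

    Standard clamped closest-point computation on the two parameter lines
    (Ericson, Real-Time Collision Detection, sec. 5.1.9).
    """
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    eps = 1e-14
    if a <= eps and e <= eps:
        return float(np.linalg.norm(r))
    if a <= eps:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = float(d1 @ r)
        if e <= eps:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > eps else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.linalg.norm(closest1 - closest2))
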