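"""Synthetic pseudo-protein structures with known domain ground truth.

Each domain is a self-avoiding 3.8 A-step random walk confined to a sphere,
mimicking the density of a compact globular fold; domain centres sit on a
line with controllable separation, so recovery can be studied as a
function of inter-domain distance. Ideal helix/strand generators support
geometry tests of the secondary-structure vector fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._types import CalphaSet, DomainAssignment, Residue
from .evaluation import ReferenceAssignment

__all__ = [
    "GlobuleSpec",
    "GenerationError",
    "make_globule_structure",
    "make_ideal_helix",
    "make_ideal_strand",
]

#: Virtual Calpha-Calpha bond length along the walk, in Angstroms.
BOND_LENGTH = 3.8
#: Minimum allowed distance between non-bonded walk points; keeps burial
#: counts in the realistic range rather than letting points pile up.
MIN_NONBONDED = 3.0
_STEP_RETRIES = 300
_WALK_RESTARTS = 60


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GlobuleSpec:
    n_domains: int = 2
    residues_per_domain: int = 60
    center_separation: float = 40.0
    packing_radius: float = 10.0
    min_contact_spacing: float = MIN_NONBONDED
    n_chains: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_domains < 1 or self.residues_per_domain < 1 or self.n_chains < 1:
            raise ValueError("counts must be positive")
        if self.center_separation < 0 or self.packing_radius <= 0:
            raise ValueError("bad geometry parameters")
        if self.n_chains > self.n_domains * self.residues_per_domain:
            raise ValueError("more chains than residues")


def _confined_walk(
    rng: np.random.Generator, n: int, center: np.ndarray, radius: float, spacing: float
) -> np.ndarray:
    """Self-avoiding random walk of n points inside a sphere."""
    for _ in range(_WALK_RESTARTS):
        pts = np.empty((n, 3))
        pts[0] = center + _random_in_sphere(rng, radius * 0.5)
        ok = True
        for i in range(1, n):
            placed = False
            for _ in range(_STEP_RETRIES):
                step = _random_unit(rng) * BOND_LENGTH
                cand = pts[i - 1] + step
                if np.linalg.norm(cand - center) > radius:
                    continue
                if i >= 2:
                    d = np.linalg.norm(pts[: i - 1] - cand, axis=1)
                    if d.min() < spacing:
                        continue
                pts[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return pts
    raise GenerationError(
        f"could not pack {n} residues into a {radius} A sphere "
        f"after {_WALK_RESTARTS} restarts"
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    return _random_unit(rng) * radius * rng.uniform() ** (1 / 3)


def make_globule_structure(
    spec: GlobuleSpec,
) -> tuple[CalphaSet, ReferenceAssignment]:
    """Generate a multi-globule pseudo-structure plus its ground truth.

    Domain centres are placed on the x axis, ``center_separation`` apart.
    Residues are numbered sequentially per chain with chain ids 'A', 'B',
    ... so the structures flow through all I/O paths. Deterministic for a
    given seed.
    """
    rng = np.random.default_rng(spec.seed)
    coords_list = []
    truth = []
    for d in range(spec.n_domains):
        center = np.array([d * spec.center_separation, 0.0, 0.0])
        pts = _confined_walk(
            rng,
            spec.residues_per_domain,
            center,
            spec.packing_radius,
            spec.min_contact_spacing,
        )
        coords_list.append(pts)
        truth.extend([d + 1] * spec.residues_per_domain)
    coords = np.vstack(coords_list)
    total = len(coords)
    base, extra = divmod(total, spec.n_chains)
    residues = []
    pos = 0
    for c in range(spec.n_chains):
        size = base + (1 if c < extra else 0)
        chain_id = chr(ord("A") + c)
        residues += [Residue(chain_id, i + 1) for i in range(size)]
        pos += size
    calphas = CalphaSet(residues, coords)
    ref = ReferenceAssignment.from_assignment(
        DomainAssignment(calphas, np.array(truth))
    )
    return calphas, ref


def make_ideal_helix(
    n_res: int,
    axis: np.ndarray = (1.0, 0.0, 0.0),
    rise: float = 1.5,
    radius: float = 2.3,
    turn_deg: float = 100.0,
) -> np.ndarray:
    """Canonical alpha-helical Calpha spiral about ``axis``.

    Defaults are the textbook alpha-helix parameters: 1.5 A rise and 100
    degrees of turn per residue at 2.3 A radius. The first residue sits at
    the origin-side end.
    """
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis must be non-zero")
    axis = axis / norm
    u = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(u) < 1e-8:
        u = np.cross(axis, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)
    t = np.arange(n_res)
    ang = np.deg2rad(turn_deg) * t
    return (
        t[:, None] * rise * axis
        + radius * np.cos(ang)[:, None] * u
        + radius * np.sin(ang)[:, None] * w
    )


def make_ideal_strand(
    n_res: int, axis: np.ndarray = (1.0, 0.0, 0.0), rise: float = 3.3
) -> np.ndarray:
    """Extended-strand Calpha trace: collinear points ``rise`` apart."""
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis must be non-zero")
    return np.arange(n_res)[:, None] * rise * (axis / norm)
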