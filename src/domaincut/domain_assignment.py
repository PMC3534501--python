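"""The two end-to-end domain assignment pipelines.

CA pipeline: classify each Calpha as buried (>= 9 neighbours within 7 A)
or exposed, cluster the buried ones on Euclidean Calpha distances with
average linkage, cut the dendrogram with the m/s gap rule, attach each
exposed residue to the cluster of its nearest buried Calpha, and clean up
(delete clusters under 10% of the largest; absorb short sequence segments
under 20 residues).

SS pipeline: represent each helix/strand as a vector, cluster the vectors
(midpoint or closest-approach distances), cut, dissolve clusters of one or
two elements, and place domain cut points midway along the sequence
between consecutive elements in different clusters.

Both accept multi-chain inputs and partition all residues of all chains
jointly, so domains spanning chains (genetic domains) fall out naturally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._types import CalphaSet, DomainAssignment
from .hierarchical_clustering import CutParams, agglomerate, cut_dendrogram
from .secondary_structure import (
    SSAnnotation,
    SSElement,
    element_distance,
    extract_elements,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CAParams",
    "SSParams",
    "InsufficientSecondaryStructureError",
    "classify_burial",
    "build_ca_distance_matrix",
    "assign_domains_ca",
    "cleanup_assignment",
    "assign_domains_ss",
]


class InsufficientSecondaryStructureError(ValueError):
    """Too few secondary-structure elements for the SS algorithm.

    The CA algorithm has no such requirement and is the fallback.
    """


@dataclass(frozen=True)
class CAParams:
    """Parameters of the alpha-carbon pipeline (distances in Angstroms)."""

    burial_radius: float = 7.0
    burial_count: int = 9
    cut: CutParams = field(default_factory=CutParams)
    constraint_distance: float = 4.0
    use_sse_constraint: bool = True
    use_sheet_constraint: bool = False
    min_cluster_fraction: float = 0.10
    min_segment_len: int = 20

    def __post_init__(self):
        if not 0 < self.min_cluster_fraction < 1:
            raise ValueError("min_cluster_fraction must be in (0, 1)")
        if min(self.burial_radius, self.burial_count, self.constraint_distance,
               self.min_segment_len) <= 0:
            raise ValueError("parameters must be positive")


@dataclass(frozen=True)
class SSParams:
    """Parameters of the secondary-structure pipeline."""

    metric: str = "midpoint"  # or "closest"
    linkage: str = "average"  # or "complete"
    cut: CutParams = field(default_factory=CutParams)
    constraint_distance: float = 4.0
    use_adjacency_constraint: bool = True
    min_cluster_elements: int = 3  # clusters with fewer elements dissolve
    min_elements_required: int = 3
    min_element_len: int = 3


def classify_burial(calphas: CalphaSet, params: CAParams | None = None) -> np.ndarray:
    """Boolean buried flag per residue.

    Residue i is buried iff at least ``burial_count`` other Calphas lie
    within ``burial_radius`` of it; neighbours are counted across all
    chains.
    """
    params = params or CAParams()
    tree = cKDTree(calphas.coords)
    counts = tree.query_ball_point(
        calphas.coords, r=params.burial_radius, return_length=True
    )
    return counts - 1 >= params.burial_count  # exclude self


def build_ca_distance_matrix(
    calphas: CalphaSet,
    buried_mask: np.ndarray,
    elements: list[SSElement] | None = None,
    sheets: list[str | None] | None = None,
    params: CAParams | None = None,
) -> np.ndarray:
    """Pairwise Euclidean matrix over the buried Calphas.

    With the secondary-structure constraint on, buried pairs inside the
    same element are overridden to ``constraint_distance`` (4 A, roughly
    adjacent-Calpha spacing) so boundaries avoid mid-element cuts; the
    optional sheet constraint does the same for pairs in the same beta
    sheet.
    """
    params = params or CAParams()
    buried_idx = np.where(buried_mask)[0]
    if len(buried_idx) < 2:
        raise ValueError("need at least 2 buried residues to build a matrix")
    pts = calphas.coords[buried_idx]
    dm = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    pos_of = {int(g): i for i, g in enumerate(buried_idx)}
    if params.use_sse_constraint and elements:
        for el in elements:
            inside = [pos_of[i] for i in el.member_indices if i in pos_of]
            if len(inside) >= 2:
                ix = np.ix_(inside, inside)
                dm[ix] = params.constraint_distance
    if params.use_sheet_constraint and sheets is not None:
        by_sheet: dict[str, list[int]] = {}
        for i in buried_idx:
            sheet = sheets[int(i)]
            if sheet:
                by_sheet.setdefault(sheet, []).append(pos_of[int(i)])
        for members in by_sheet.values():
            if len(members) >= 2:
                ix = np.ix_(members, members)
                dm[ix] = params.constraint_distance
    np.fill_diagonal(dm, 0.0)
    return dm


def assign_domains_ca(
    calphas: CalphaSet,
    ann: SSAnnotation | None = None,
    params: CAParams | None = None,
) -> DomainAssignment:
    """Run the full alpha-carbon pipeline.

    The secondary-structure annotation is optional; without it the 4 A
    intra-element constraint is simply unavailable.
    """
    params = params or CAParams()
    buried = classify_burial(calphas, params)
    n_buried = int(buried.sum())
    if n_buried < 2:
        logger.warning(
            "only %d buried residue(s); returning a single domain", n_buried
        )
        return DomainAssignment(calphas, np.ones(len(calphas), dtype=int))
    elements = None
    sheets = None
    if ann is not None:
        elements = extract_elements(ann, calphas)
        sheets = ann.sheet_ids
    dm = build_ca_distance_matrix(calphas, buried, elements, sheets, params)
    tree = agglomerate(dm, linkage="average")
    cut = cut_dendrogram(tree, params.cut)
    buried_idx = np.where(buried)[0]
    labels = np.zeros(len(calphas), dtype=int)
    labels[buried_idx] = cut.labels(len(buried_idx))
    # exposed residues join the cluster of the nearest buried Calpha
    # (Euclidean; ties resolved toward the lower residue index)
    exposed_idx = np.where(~buried)[0]
    if len(exposed_idx):
        d = np.linalg.norm(
            calphas.coords[exposed_idx][:, None, :]
            - calphas.coords[buried_idx][None, :, :],
            axis=-1,
        )
        nearest = np.argmin(d, axis=1)  # argmin takes the first minimum
        labels[exposed_idx] = labels[buried_idx[nearest]]
    assignment = DomainAssignment(calphas, labels).renumbered()
    return cleanup_assignment(assignment, params)


def cleanup_assignment(
    assignment: DomainAssignment, params: CAParams | None = None
) -> DomainAssignment:
    """Post-process an assignment: drop small clusters, absorb short segments.

    (1) Every domain smaller than ``min_cluster_fraction`` of the largest
    is deleted; its residues rejoin the domain of the nearest retained
    residue's Calpha. (2) Each chain is scanned left to right, absorbing
    any maximal same-domain segment shorter than ``min_segment_len`` that
    is flanked on both sides by one same other domain, or that touches a
    chain end; the scan repeats until a full pass changes nothing. Domains
    are renumbered 1..k in order of first appearance.
    """
    params = params or CAParams()
    calphas = assignment.calphas
    labels = assignment.labels.copy()
    # (1) small-cluster deletion
    counts = {int(d): int((labels == d).sum()) for d in np.unique(labels)}
    largest = max(counts.values())
    keep = {d for d, c in counts.items() if c >= params.min_cluster_fraction * largest}
    if len(keep) < len(counts):
        kept_idx = np.where(np.isin(labels, list(keep)))[0]
        orphan_idx = np.where(~np.isin(labels, list(keep)))[0]
        d = np.linalg.norm(
            calphas.coords[orphan_idx][:, None, :]
            - calphas.coords[kept_idx][None, :, :],
            axis=-1,
        )
        labels[orphan_idx] = labels[kept_idx[np.argmin(d, axis=1)]]
    # (2) short-segment absorption, per chain, to a fixed point
    for (_, lo, hi) in calphas.chain_ranges():
        changed = True
        while changed:
            changed = False
            segs = _segments(labels, lo, hi)
            for si, (start, end, dom) in enumerate(segs):
                if end - start >= params.min_segment_len:
                    continue
                left = segs[si - 1][2] if si > 0 else None
                right = segs[si + 1][2] if si < len(segs) - 1 else None
                new = None
                if left is None and right is None:
                    continue  # segment spans the whole chain
                if left is None:
                    new = right
                elif right is None:
                    new = left
                elif left == right:
                    new = left
                if new is not None and new != dom:
                    labels[start:end] = new
                    changed = True
                    break
    return DomainAssignment(calphas, labels).renumbered()


def _segments(labels: np.ndarray, lo: int, hi: int) -> list[tuple[int, int, int]]:
    """Maximal same-label runs in labels[lo:hi] as (start, end, label)."""
    out = []
    start = lo
    for i in range(lo + 1, hi + 1):
        if i == hi or labels[i] != labels[start]:
            out.append((start, i, int(labels[start])))
            start = i
    return out


def assign_domains_ss(
    calphas: CalphaSet,
    ann: SSAnnotation,
    params: SSParams | None = None,
) -> DomainAssignment:
    """Run the full secondary-structure pipeline."""
    params = params or SSParams()
    elements = extract_elements(ann, calphas, min_len=params.min_element_len)
    if len(elements) < params.min_elements_required:
        raise InsufficientSecondaryStructureError(
            f"only {len(elements)} secondary-structure element(s) found "
            f"(need {params.min_elements_required}); use the CA algorithm instead"
        )
    n = len(elements)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = element_distance(
                elements[i], elements[j], metric=params.metric
            )
    if params.use_adjacency_constraint:
        res = calphas.residues
        for i in range(n - 1):
            a, b = elements[i], elements[i + 1]
            if res[a.member_indices[0]].chain_id == res[b.member_indices[0]].chain_id:
                dm[i, i + 1] = dm[i + 1, i] = params.constraint_distance
    tree = agglomerate(dm, linkage=params.linkage)
    cut = cut_dendrogram(tree, params.cut)
    el_label = cut.labels(n)
    el_label = _dissolve_small_clusters(el_label, dm, params.min_cluster_elements)
    labels = _labels_from_element_clusters(calphas, elements, el_label)
    return DomainAssignment(calphas, labels).renumbered()


def _dissolve_small_clusters(
    el_label: np.ndarray, dm: np.ndarray, min_elements: int
) -> np.ndarray:
    """Reassign elements of clusters below ``min_elements`` to the retained
    cluster with the smallest average distance; if nothing is retained,
    merge everything into one cluster."""
    el_label = el_label.copy()
    counts = {int(d): int((el_label == d).sum()) for d in np.unique(el_label)}
    keep = [d for d, c in counts.items() if c >= min_elements]
    if not keep:
        return np.ones_like(el_label)
    if len(keep) == len(counts):
        return el_label
    orphan = np.where(~np.isin(el_label, keep))[0]
    for i in orphan:
        avg = [dm[i, el_label == d].mean() for d in keep]
        el_label[i] = keep[int(np.argmin(avg))]
    return el_label


def _labels_from_element_clusters(
    calphas: CalphaSet, elements: list[SSElement], el_label: np.ndarray
) -> np.ndarray:
    """Residue labels from element clusters via midway sequence cut points.

    Within each chain, a cut is placed after residue
    floor((last_of_prev + first_of_next) / 2) whenever consecutive elements
    belong to different clusters; the blocks between cuts inherit the
    cluster of their elements. Residues of a chain with no element attach
    to the spatially nearest element's cluster.
    """
    labels = np.zeros(len(calphas), dtype=int)
    res = calphas.residues
    chain_of_el = [res[el.member_indices[0]].chain_id for el in elements]
    midpoints = np.array([el.midpoint for el in elements])
    for (chain_id, lo, hi) in calphas.chain_ranges():
        els = [i for i, ch in enumerate(chain_of_el) if ch == chain_id]
        if not els:
            d = np.linalg.norm(
                calphas.coords[lo:hi][:, None, :] - midpoints[None, :, :], axis=-1
            )
            labels[lo:hi] = el_label[np.argmin(d, axis=1)]
            continue
        cuts = []  # cut after this internal index
        for a, b in zip(els, els[1:]):
            if el_label[a] != el_label[b]:
                cuts.append(
                    (elements[a].member_indices[-1] + elements[b].member_indices[0])
                    // 2
                )
        block_start = lo
        boundaries = cuts + [hi - 1]
        el_iter = 0
        for cut_after in boundaries:
            # first element whose start lies in this block
            while el_iter < len(els) and elements[els[el_iter]].member_indices[0] <= cut_after:
                block_dom = el_label[els[el_iter]]
                el_iter += 1
            labels[block_start : cut_after + 1] = block_dom
            block_start = cut_after + 1
    return labels
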