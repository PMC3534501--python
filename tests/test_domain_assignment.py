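"""The CA and SS assignment pipelines: burial, constraints, cleanup."""

import numpy as np
import pytest

from domaincut import (
    CAParams,
    CutParams,
    DomainAssignment,
    GlobuleSpec,
    InsufficientSecondaryStructureError,
    SSParams,
    assign_domains_ca,
    assign_domains_ss,
    classify_burial,
    cleanup_assignment,
    make_globule_structure,
    make_ideal_helix,
    overlap_score,
)
from domaincut._types import CalphaSet, Residue
from domaincut.domain_assignment import build_ca_distance_matrix
from domaincut.secondary_structure import HELIX, SSAnnotation

from conftest import calphas_from_coords


def fibonacci_sphere(n, radius):
    """n roughly equidistributed points on a sphere."""
    i = np.arange(n)
    phi = np.arccos(1 - 2 * (i + 0.5) / n)
    theta = np.pi * (1 + 5**0.5) * i
    return radius * np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


class TestClassifyBurial:
    def test_isolated_point_exposed(self):
        cal = calphas_from_coords([[0, 0, 0], [100, 0, 0]])
        assert not classify_burial(cal).any()

    def test_point_ringed_by_nine_within_7A_is_buried(self):
        coords = np.vstack([[0, 0, 0], fibonacci_sphere(9, 6.0)])
        cal = calphas_from_coords(coords)
        buried = classify_burial(cal)
        assert buried[0]  # centre has exactly 9 neighbours within 7 A
        assert not buried[1:].any()  # ring points see centre + few others

    def test_eight_neighbours_not_enough(self):
        coords = np.vstack([[0, 0, 0], fibonacci_sphere(8, 6.0)])
        assert not classify_burial(calphas_from_coords(coords))[0]

    def test_matches_brute_force_on_dense_globule(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(-12, 12, size=(200, 3))
        cal = calphas_from_coords(coords)
        fast = classify_burial(cal)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        brute = (d <= 7.0).sum(axis=1) - 1 >= 9
        np.testing.assert_array_equal(fast, brute)

    def test_neighbours_counted_across_chains(self):
        coords = np.vstack([[0, 0, 0], fibonacci_sphere(9, 6.0)])
        residues = [Residue("A", 1)] + [Residue("B", i + 1) for i in range(9)]
        cal = CalphaSet(residues, coords)
        assert classify_burial(cal)[0]


class TestCaDistanceMatrix:
    def make_two_buried(self):
        # two dense mini-clumps 17 A apart; centres are buried
        a = np.vstack([[0, 0, 0], fibonacci_sphere(9, 5.0)])
        b = a + np.array([17.0, 0, 0])
        return calphas_from_coords(np.vstack([a, b]))

    def test_euclidean_entries(self):
        cal = self.make_two_buried()
        buried = classify_burial(cal)
        dm = build_ca_distance_matrix(cal, buried)
        assert buried.sum() == 2
        assert dm[0, 1] == pytest.approx(17.0)

    def test_sse_constraint_overrides_to_4A(self):
        cal = self.make_two_buried()
        buried = classify_burial(cal)
        # pretend both buried residues sit in one helix
        from domaincut.secondary_structure import SSElement

        el = SSElement(
            kind=HELIX,
            member_indices=[0, 10],
            c=np.zeros(3),
            v=np.array([1.0, 0, 0]),
            start_point=np.zeros(3),
            end_point=np.array([17.0, 0, 0]),
            r1=np.zeros(3),
            r2=np.array([17.0, 0, 0]),
        )
        on = build_ca_distance_matrix(cal, buried, elements=[el])
        assert on[0, 1] == pytest.approx(4.0)
        off = build_ca_distance_matrix(
            cal, buried, elements=[el], params=CAParams(use_sse_constraint=False)
        )
        assert off[0, 1] == pytest.approx(17.0)
        diff = np.argwhere(on != off)
        assert {tuple(x) for x in diff} == {(0, 1), (1, 0)}

    def test_sheet_constraint(self):
        cal = self.make_two_buried()
        buried = classify_burial(cal)
        sheets = ["A"] + [None] * 9 + ["A"] + [None] * 9
        dm = build_ca_distance_matrix(
            cal, buried, sheets=sheets, params=CAParams(use_sheet_constraint=True)
        )
        assert dm[0, 1] == pytest.approx(4.0)

    def test_too_few_buried_raises(self):
        cal = calphas_from_coords([[0, 0, 0], [50, 0, 0]])
        with pytest.raises(ValueError, match="buried"):
            build_ca_distance_matrix(cal, classify_burial(cal))


class TestAssignDomainsCA:
    def test_two_globules_recovered(self):
        for seed in range(5):
            cal, ref = make_globule_structure(GlobuleSpec(seed=seed))
            a = assign_domains_ca(cal)
            r = overlap_score(a, ref)
            assert r.n_pred == 2
            assert r.overlap == 1.0

    def test_single_globule_one_domain(self):
        cal, _ = make_globule_structure(GlobuleSpec(n_domains=1, seed=8))
        assert assign_domains_ca(cal).n_domains == 1

    def test_no_buried_residues_single_domain_warning(self, caplog):
        cal = calphas_from_coords(np.arange(30).reshape(10, 3) * 5.0)
        with caplog.at_level("WARNING"):
            a = assign_domains_ca(cal)
        assert a.n_domains == 1
        assert any("buried" in r.message for r in caplog.records)

    def test_multi_chain_partition_covers_both_chains(self):
        cal, ref = make_globule_structure(GlobuleSpec(n_chains=2, seed=4))
        a = assign_domains_ca(cal)
        assert len(a.labels) == len(cal)
        assert a.n_domains == 2
        assert overlap_score(a, ref).overlap == 1.0

    def test_rigid_body_invariance(self):
        cal, _ = make_globule_structure(GlobuleSpec(seed=12))
        a1 = assign_domains_ca(cal)
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        moved = CalphaSet(cal.residues, cal.coords @ q.T + np.array([11.0, -3.0, 40.0]))
        a2 = assign_domains_ca(moved)
        np.testing.assert_array_equal(a1.labels, a2.labels)

    def test_determinism(self):
        cal, _ = make_globule_structure(GlobuleSpec(seed=21))
        np.testing.assert_array_equal(
            assign_domains_ca(cal).labels, assign_domains_ca(cal).labels
        )

    def test_separation_monotonicity(self):
        ks = []
        for sep in [0.0, 15.0, 25.0, 40.0, 60.0]:
            cal, _ = make_globule_structure(GlobuleSpec(center_separation=sep, seed=2))
            ks.append(assign_domains_ca(cal).n_domains)
        assert all(a <= b for a, b in zip(ks, ks[1:]))
        assert ks[0] == 1 and ks[-1] == 2


class TestCleanup:
    def make_assignment(self, pattern, coords=None):
        labels = np.array(pattern)
        if coords is None:
            coords = np.zeros((len(labels), 3))
            coords[:, 0] = np.arange(len(labels)) * 3.8
        return DomainAssignment(calphas_from_coords(coords), labels)

    def test_small_cluster_deleted(self):
        a = self.make_assignment([1] * 100 + [2] * 5)
        out = cleanup_assignment(a)
        assert out.n_domains == 1

    def test_ten_percent_boundary_kept(self):
        # 10 residues is exactly 10% of 100: not "less than", so retained;
        # but a 10-residue run at a chain end is then absorbed, so place it
        # far away as its own chain to isolate the deletion rule
        residues = [Residue("A", i + 1) for i in range(100)] + [
            Residue("B", i + 1) for i in range(10)
        ]
        coords = np.zeros((110, 3))
        coords[:, 0] = np.arange(110) * 3.8
        a = DomainAssignment(CalphaSet(residues, coords), np.array([1] * 100 + [2] * 10))
        out = cleanup_assignment(a)
        assert out.n_domains == 2

    def test_enclosed_short_segment_absorbed(self):
        out = cleanup_assignment(self.make_assignment([1] * 30 + [2] * 10 + [1] * 30))
        assert out.n_domains == 1

    def test_20_residue_segment_kept(self):
        out = cleanup_assignment(self.make_assignment([1] * 30 + [2] * 25 + [1] * 30))
        assert out.n_domains == 2
        assert (out.labels == out.labels[30]).sum() == 25

    def test_chain_end_segment_absorbed(self):
        out = cleanup_assignment(self.make_assignment([2] * 10 + [1] * 60))
        assert out.n_domains == 1

    def test_differently_flanked_segment_untouched(self):
        pattern = [1] * 40 + [3] * 10 + [2] * 40
        # domain 3 is only 10 residues but >= 10% of largest requires 4:
        # 10 >= 4 so it survives deletion; flanks differ so no absorption
        out = cleanup_assignment(self.make_assignment(pattern))
        assert out.n_domains == 3

    def test_cascading_absorption_reaches_fixed_point(self):
        # absorbing the enclosed 3-run fuses the flanking 2-runs into a
        # 25-residue segment, which the re-scan must then leave alone
        pattern = [1] * 30 + [2] * 10 + [3] * 5 + [2] * 10 + [1] * 30
        out = cleanup_assignment(
            self.make_assignment(pattern), CAParams(min_cluster_fraction=0.01)
        )
        assert out.n_domains == 2
        assert (out.labels[30:55] == out.labels[30]).all()

    def test_chain_start_segment_absorbed_into_follower(self):
        # a short run touching the chain start is consumed by its single
        # neighbour even when a same-domain run exists further along
        pattern = [1] * 15 + [2] * 5 + [1] * 15 + [3] * 50
        out = cleanup_assignment(
            self.make_assignment(pattern), CAParams(min_cluster_fraction=0.01)
        )
        # leading 1-run joins domain 2; the second 1-run has differing
        # flanks (2 and 3) and stays, so three domains remain
        assert out.n_domains == 3
        assert (out.labels[:20] == out.labels[0]).all()

    def test_segments_reconstruct_labels(self):
        cal, _ = make_globule_structure(GlobuleSpec(seed=9))
        a = assign_domains_ca(cal)
        rebuilt = np.zeros(len(cal), dtype=int)
        for dom, chain, start, end in a.segments():
            ids = [
                i
                for i, r in enumerate(cal.residues)
                if r.chain_id == chain
                and int(start) <= r.seq_number <= int(end)
            ]
            rebuilt[ids] = dom
        np.testing.assert_array_equal(rebuilt, a.labels)


def helix_bundle(center, n_helices=4, n_res=10):
    offsets = [(0, 0), (6, 0), (0, 6), (6, 6)][:n_helices]
    return np.vstack(
        [
            make_ideal_helix(n_res, axis=(0, 0, 1)) + np.array([center[0] + dx, center[1] + dy, center[2]])
            for dx, dy in offsets
        ]
    )


class TestAssignDomainsSS:
    def make_two_bundles(self, sep=40.0):
        coords = np.vstack([helix_bundle((0, 0, 0)), helix_bundle((sep, 0, 0))])
        cal = calphas_from_coords(coords)
        ann = SSAnnotation([HELIX] * len(coords), [None] * len(coords))
        return cal, ann

    def test_two_bundles_two_domains_cut_between(self):
        cal, ann = self.make_two_bundles()
        a = assign_domains_ss(cal, ann)
        assert a.n_domains == 2
        boundary = np.where(np.diff(a.labels) != 0)[0]
        assert list(boundary) == [39]  # midway between residue runs 31-40, 41-50

    def test_too_few_elements_raises(self):
        coords = np.vstack(
            [make_ideal_helix(10), make_ideal_helix(10) + np.array([0, 20.0, 0])]
        )
        cal = calphas_from_coords(coords)
        ann = SSAnnotation([HELIX] * 20, [None] * 20)
        with pytest.raises(InsufficientSecondaryStructureError):
            assign_domains_ss(cal, ann)

    def test_small_cluster_dissolved(self):
        # geometry tuned so the cut yields three clusters, one holding
        # only two helices: that cluster dissolves and two domains remain
        pair = np.vstack(
            [
                make_ideal_helix(10, axis=(0, 0, 1)) + np.array([17.0, 40.0, 0]),
                make_ideal_helix(10, axis=(0, 0, 1)) + np.array([23.0, 40.0, 0]),
            ]
        )
        coords = np.vstack([helix_bundle((0, 0, 0)), helix_bundle((40, 0, 0)), pair])
        cal = calphas_from_coords(coords)
        ann = SSAnnotation([HELIX] * len(coords), [None] * len(coords))
        params = SSParams(use_adjacency_constraint=False, cut=CutParams(m=22, s=5))
        # confirm the raw cut really produced a 2-element cluster
        from domaincut import agglomerate, cut_dendrogram, element_distance, extract_elements

        els = extract_elements(ann, cal)
        n = len(els)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = element_distance(els[i], els[j], "midpoint")
        cs = cut_dendrogram(agglomerate(dm), params.cut)
        assert sorted(len(c) for c in cs.clusters) == [2, 4, 4]
        a = assign_domains_ss(cal, ann, params)
        assert a.n_domains == 2

    def test_rigid_body_invariance(self):
        cal, ann = self.make_two_bundles()
        a1 = assign_domains_ss(cal, ann)
        rng = np.random.default_rng(6)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        moved = CalphaSet(cal.residues, cal.coords @ q.T + np.array([5.0, 5.0, 5.0]))
        a2 = assign_domains_ss(moved, ann)
        np.testing.assert_array_equal(a1.labels, a2.labels)

    def test_every_residue_assigned(self):
        cal, ann = self.make_two_bundles()
        a = assign_domains_ss(cal, ann)
        assert len(a.labels) == len(cal)
        assert a.labels.min() >= 1
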