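"""Pair enumeration, clustering, non-redundancy, template libraries."""

import numpy as np
import pytest

from ddiscape import (
    build_template_library,
    cluster_domains,
    enumerate_pairs,
    pairwise_identity,
    representative_for_protein,
    select_nonredundant_pairs,
)
from ddiscape.datasets import DomainPairRecord, SequenceCluster
from ddiscape.structures import ChainStructure, Residue, ResidueID, Atom
from ddiscape.synthetic import make_sequence_family, random_sequence
from oracle_utils import naive_nonredundant, toy_interface


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACDEFGHIKL" * 5, "ACDEFGHIKL" * 5) == 100.0

    def test_controlled_mutation(self):
        fam = make_sequence_family(100, 2, 0.40, seed=8)
        assert pairwise_identity(fam[0], fam[1]) == pytest.approx(40.0, abs=2.0)

    def test_unrelated_sequences_low_identity(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            s1, s2 = random_sequence(100, rng), random_sequence(100, rng)
            assert pairwise_identity(s1, s2) < 30.0

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACD")


class TestClusterDomains:
    def test_identical_domains_single_cluster(self):
        doms = [(f"P{i}_A", 1, "ACDEFGHIKL" * 6) for i in range(4)]
        clusters = cluster_domains(doms)
        assert len(clusters) == 1 and len(clusters[0].members) == 4

    def test_two_families_two_clusters(self):
        f1 = make_sequence_family(80, 3, 0.8, seed=1)
        f2 = make_sequence_family(80, 3, 0.8, seed=2)
        doms = [(f"A{i}_A", 1, s) for i, s in enumerate(f1)]
        doms += [(f"B{i}_A", 1, s) for i, s in enumerate(f2)]
        clusters = cluster_domains(doms)
        assert len(clusters) == 2
        sides = [{m[0][0] for m in c.members} for c in clusters]
        assert sides[0].isdisjoint(sides[1])

    def test_threshold_boundary_inclusive(self):
        rep = "ACDEFGHIKL" * 10  # length 100
        exact40 = rep[:40] + "W" * 60  # 40 identities over length 100
        assert pairwise_identity(rep, exact40) == 40.0
        clusters = cluster_domains([("P1_A", 1, rep), ("P2_A", 1, exact40)])
        assert len(clusters) == 1
        below = rep[:39] + "W" * 61
        clusters = cluster_domains([("P1_A", 1, rep), ("P2_A", 1, below)])
        assert len(clusters) == 2

    def test_partition_and_identity_invariant(self):
        rng = np.random.default_rng(3)
        doms = [(f"P{i}_A", 1, random_sequence(60, rng)) for i in range(8)]
        clusters = cluster_domains(doms)
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted((e, n) for e, n, _ in doms)
        seq_of = {(e, n): s for e, n, s in doms}
        for c in clusters:
            rep = seq_of[c.representative]
            for m in c.members:
                assert pairwise_identity(rep, seq_of[m]) >= 40.0 or m == c.representative


def _record(entry, na, nb, resolution, length=50, seed=0):
    rng = np.random.default_rng(seed)
    pts_a = rng.uniform(0, 10, (10, 3))
    pts_b = pts_a + [0, 3.0, 0]
    iface = toy_interface(pts_a, pts_b, [(i, i) for i in range(10)],
                          pair_id=f"{entry}.{na}|{entry}.{nb}")
    dom_a, dom_b = iface.domain_a, iface.domain_b
    dom_a.definition.entry_id = entry
    dom_b.definition.entry_id = entry
    dom_a.definition.domain_number = na
    dom_b.definition.domain_number = nb
    for dom in (dom_a, dom_b):
        dom.residues = dom.residues[:1] * 1 + dom.residues[1:]
        for r, aa in zip(dom.residues, random_sequence(len(dom.residues), rng)):
            r.aa = aa
    # pad residues to the requested length for total_length ordering
    extra = length - dom_a.length
    if extra > 0:
        pad_seq = random_sequence(extra, rng)
        for k in range(extra):
            ca = Atom("CA", "C", np.array([900.0 + k, 0, 0]))
            dom_a.residues.append(
                Residue("A", ResidueID(900 + k), pad_seq[k], [ca], ca))
    return DomainPairRecord(
        entry_id=entry, domain_a=dom_a, domain_b=dom_b, pair_class="CC-2",
        interface=iface, resolution=resolution,
    )


class TestSelectNonredundant:
    def _clusters(self, assignments):
        """assignments: {cluster_id: [(entry, domain_number), ...]}"""
        return [
            SequenceCluster(cluster_id=cid, members=mem, representative=mem[0])
            for cid, mem in sorted(assignments.items())
        ]

    def test_resolution_picks_representative(self):
        r1 = _record("P1_A", 1, 2, resolution=1.8)
        r2 = _record("P2_A", 1, 2, resolution=2.4)
        clusters = self._clusters({
            1: [("P1_A", 1), ("P2_A", 1)],
            2: [("P1_A", 2), ("P2_A", 2)],
        })
        sel = select_nonredundant_pairs(clusters, [r1, r2])
        assert [s.entry_id for s in sel] == ["P1_A"]

    def test_single_common_entry_selected(self):
        r1 = _record("P1_A", 1, 2, resolution=2.0)
        clusters = self._clusters({1: [("P1_A", 1)], 2: [("P1_A", 2)]})
        assert select_nonredundant_pairs(clusters, [r1]) == [r1]

    def test_reversed_domain_order_keeps_both(self):
        # P1 has the cluster-1 domain first; P2 has the cluster-2 domain
        # first: two orientations, both must survive
        r1 = _record("P1_A", 1, 2, resolution=1.8)
        r2 = _record("P2_A", 2, 1, resolution=2.4)
        clusters = self._clusters({
            1: [("P1_A", 1), ("P2_A", 1)],
            2: [("P1_A", 2), ("P2_A", 2)],
        })
        sel = select_nonredundant_pairs(clusters, [r1, r2])
        assert {s.entry_id for s in sel} == {"P1_A", "P2_A"}

    def test_unclustered_record_error(self):
        r1 = _record("P1_A", 1, 2, resolution=2.0)
        clusters = self._clusters({1: [("P1_A", 1)], 2: [("XX_A", 2)]})
        with pytest.raises(ValueError):
            select_nonredundant_pairs(clusters, [r1])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for trial in range(20):
            n_entries = int(rng.integers(3, 9))
            n_clusters = int(rng.integers(2, 7))
            records, assignments = [], {c: [] for c in range(1, n_clusters + 1)}
            for e in range(n_entries):
                entry = f"E{trial}{e}_A"
                na, nb = 1, 2
                if rng.random() < 0.3:
                    na, nb = 2, 1
                rec = _record(entry, na, nb,
                              resolution=float(rng.uniform(1.5, 2.5)),
                              length=int(rng.integers(40, 80)),
                              seed=trial * 100 + e)
                records.append(rec)
                ca = int(rng.integers(1, n_clusters + 1))
                cb = int(rng.integers(1, n_clusters + 1))
                assignments[ca].append((entry, na))
                if cb == ca:
                    cb = ca % n_clusters + 1
                assignments[cb].append((entry, nb))
            clusters = [
                SequenceCluster(cluster_id=c, members=m, representative=m[0])
                for c, m in assignments.items() if m
            ]
            ours = select_nonredundant_pairs(clusters, records)
            oracle = naive_nonredundant(clusters, records)
            assert [r.pair_id for r in ours] == [r.pair_id for r in oracle]


class TestEnumeratePairs:
    def test_multidomain_combinatorics(self, corpus):
        chain = corpus["chains"]["MUL1_A"]
        ccm = enumerate_pairs([chain], "CC-M")
        cum = enumerate_pairs([chain], "CU-M")
        # adjacent pairs placed in contact by construction
        assert len(ccm) == 2
        assert len(ccm) <= len(cum) <= 3
        assert {r.pair_id for r in ccm} <= {r.pair_id for r in cum}

    def test_two_domain_entries_in_cc2(self, corpus):
        chains = [c for c in corpus["chains"].values()]
        recs = enumerate_pairs(chains, "CC-2")
        assert all(r.interface.L >= 20 for r in recs)
        entries = {r.entry_id for r in recs}
        assert "SRC1_A" in entries and "MUL1_A" not in entries

    def test_resolution_filter_excludes_poor_structures(self, corpus):
        chains = list(corpus["chains"].values())
        recs = enumerate_pairs(chains, "CC-2")
        assert not any(r.entry_id.startswith("LOW") for r in recs)
        relaxed = enumerate_pairs(chains, "CC-2", resolution_max=3.0)
        assert any(r.entry_id.startswith("LOW") for r in relaxed)

    def test_discontinuous_entry_in_cd2(self, corpus):
        chains = list(corpus["chains"].values())
        recs = enumerate_pairs(chains, "CD-2")
        assert {r.entry_id for r in recs} == {"DIS1_A"}
        rec = recs[0]
        # discontinuous domain represented by its major-segment sequence
        disc = rec.domain_a
        assert len(rec.seq_a) < disc.length

    def test_small_interface_excluded_everywhere(self):
        a = np.column_stack([np.arange(5) * 4.0, np.zeros(5), np.zeros(5)])
        iface = toy_interface(a, a + [0, 4.0, 0], [(i, i) for i in range(5)])
        chain = ChainStructure(
            "TS_A",
            iface.domain_a.residues + iface.domain_b.residues,
            resolution=2.0,
        )
        chain.domains = [iface.domain_a, iface.domain_b]
        assert enumerate_pairs([chain], "CC-2") == []


class TestRepresentativeSelection:
    def _chain(self, entry, resolution, n):
        res = [Residue("A", ResidueID(i), "A",
                       [Atom("CA", "C", np.array([3.8 * i, 0, 0]))], None)
               for i in range(1, n + 1)]
        return ChainStructure(entry, res, resolution=resolution)

    def test_resolution_first(self):
        best = representative_for_protein(
            [self._chain("P1_A", 2.0, 300), self._chain("P2_A", 2.4, 500)])
        assert best.entry_id == "P1_A"

    def test_length_breaks_resolution_tie(self):
        best = representative_for_protein(
            [self._chain("P1_A", 2.0, 300), self._chain("P2_A", 2.0, 500)])
        assert best.entry_id == "P2_A"

    def test_single_candidate(self):
        c = self._chain("P1_A", 2.0, 100)
        assert representative_for_protein([c]) is c


class TestTemplateLibrary:
    def test_fold_rule_excludes_shared_topology(self):
        q = _record("Q1_A", 1, 2, 2.0, seed=1)
        p = _record("P1_A", 1, 2, 2.0, seed=2)
        p.domain_a.definition.fold_label = q.domain_a.definition.fold_label
        lib = build_template_library(q, [p], tm_fn=None)
        assert lib.templates == []
        assert lib.filters_applied["trace"][p.pair_id] == "fold"

    def test_tm_rule_excludes_similar_structure(self):
        q = _record("Q1_A", 1, 2, 2.0, seed=3)
        p = _record("P1_A", 1, 2, 2.0, seed=4)
        lib = build_template_library(q, [p], tm_fn=lambda a, b: 0.45)
        assert lib.templates == []
        assert lib.filters_applied["trace"][p.pair_id] == "tm_score"
        lib = build_template_library(q, [p], tm_fn=lambda a, b: 0.39)
        assert lib.templates == [p]

    def test_sequence_rule_excludes_homologs(self):
        q = _record("Q1_A", 1, 2, 2.0, seed=5)
        p = _record("P1_A", 1, 2, 2.0, seed=6)
        p.seq_a = q.seq_a
        lib = build_template_library(q, [p], tm_fn=None)
        assert lib.filters_applied["trace"][p.pair_id] == "sequence"

    def test_query_entry_never_in_library(self):
        q = _record("Q1_A", 1, 2, 2.0, seed=7)
        twin = _record("Q1_A", 2, 1, 2.0, seed=8)
        lib = build_template_library(q, [twin], tm_fn=None)
        assert lib.templates == []
        assert lib.filters_applied["trace"][twin.pair_id] == "self"

    def test_passing_member_traced(self):
        q = _record("Q1_A", 1, 2, 2.0, seed=9)
        p = _record("P1_A", 1, 2, 2.0, seed=10)
        lib = build_template_library(q, [p], tm_fn=lambda a, b: 0.1)
        assert lib.templates == [p]
        assert lib.filters_applied["trace"][p.pair_id] == "pass"
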