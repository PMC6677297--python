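"""Chain/domain model: parsing, delineation, continuity and linker rules."""

import numpy as np
import pytest

from ddiscape import (
    ChainStructure,
    DomainDefinition,
    Segment,
    apply_domain_definitions,
    build_interface,
    classify_continuity,
    is_consecutive_pair,
    linker_length,
    parse_structure,
    select_major_segment,
    write_pdb,
)
from ddiscape.structures import Atom, Residue, ResidueID
from ddiscape.synthetic import SyntheticSpec, make_domain_pair

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.759   7.095  -4.969  1.00  0.00           C
TER
END
"""


def _chain_with_domains(spans, gap=None, n=120):
    """Chain of n CA-only residues numbered 1..n (optionally skipping a
    numbered gap), with single-segment domain definitions over ``spans``."""
    residues = []
    for i in range(1, n + 1):
        if gap and gap[0] <= i <= gap[1]:
            continue
        ca = Atom("CA", "C", np.array([3.8 * i, 0.0, 0.0]))
        residues.append(Residue("A", ResidueID(i), "A", [ca], ca))
    missing = [Segment("A", *gap)] if gap else []
    chain = ChainStructure("T1_A", residues, missing_ranges=missing)
    defs = [
        DomainDefinition("T1_A", k + 1, [Segment("A", a, b)], f"fold{k}", 2.0)
        for k, (a, b) in enumerate(spans)
    ]
    return apply_domain_definitions(chain, defs)


class TestParseStructure:
    def test_single_residue(self):
        chain = parse_structure(MINIMAL_PDB, "A")
        assert chain.length == 1
        assert chain.residues[0].aa == "A"
        assert chain.residues[0].ca is not None

    def test_unknown_chain_raises(self):
        with pytest.raises(KeyError):
            parse_structure(MINIMAL_PDB, "B")

    def test_roundtrip_preserves_counts(self):
        entry = make_domain_pair(SyntheticSpec(seed=3))
        chain = entry.chain
        reparsed = parse_structure(write_pdb(chain), "A")
        assert reparsed.length == chain.length
        assert sum(len(r.atoms) for r in reparsed.residues) == sum(
            len(r.atoms) for r in chain.residues
        )
        assert [r.seq_index.number for r in reparsed.residues] == [
            r.seq_index.number for r in chain.residues
        ]

    def test_numbering_gap_becomes_missing_range(self):
        entry = make_domain_pair(SyntheticSpec(seed=3))
        text = write_pdb(entry.chain)
        # drop REMARK 465 so the gap must be inferred from numbering alone
        bare = "\n".join(l for l in text.splitlines() if not l.startswith("REMARK"))
        chain = parse_structure(bare, "A")
        gaps = [(s.start, s.end) for s in chain.missing_ranges]
        truth_gaps = [(s.start, s.end) for s in entry.chain.missing_ranges]
        assert gaps == truth_gaps

    def test_hydrogens_flagged_non_heavy(self):
        pdb = MINIMAL_PDB.replace(
            "TER",
            "ATOM      4  H   ALA A   1      11.000   6.000  -6.000  1.00  0.00           H\nTER",
        )
        chain = parse_structure(pdb, "A")
        flags = {a.name: a.is_heavy for a in chain.residues[0].atoms}
        assert flags["H"] is False and flags["CA"] is True


class TestDomainDefinitions:
    def test_whole_chain_single_domain(self):
        chain = _chain_with_domains([(1, 120)])
        assert len(chain.domains) == 1
        assert chain.domains[0].length == chain.length

    def test_two_disjoint_domains_ordered(self):
        chain = _chain_with_domains([(61, 120), (1, 60)])
        assert [d.definition.domain_number for d in chain.domains] == [2, 1]
        assert chain.domains[0].residues[0].seq_index.number == 1

    def test_two_segment_definition_is_discontinuous(self):
        chain = ChainStructure(
            "T2_A",
            [Residue("A", ResidueID(i), "A",
                     [Atom("CA", "C", np.array([3.8 * i, 0, 0]))],
                     None) for i in range(1, 51)],
        )
        d = DomainDefinition("T2_A", 1, [Segment("A", 1, 20), Segment("A", 40, 50)],
                             "f", 2.0)
        chain = apply_domain_definitions(chain, [d])
        assert classify_continuity(chain.domains[0]) == "discontinuous"
        assert chain.domains[0].length == 31

    def test_empty_segment_raises(self):
        chain = _chain_with_domains([(1, 120)])
        bad = DomainDefinition("T1_A", 9, [Segment("A", 500, 600)], "f", 2.0)
        with pytest.raises(ValueError, match="09"):
            apply_domain_definitions(chain, [bad])

    def test_idempotent(self):
        chain = _chain_with_domains([(1, 60), (61, 120)])
        again = apply_domain_definitions(chain, [d.definition for d in chain.domains])
        assert [d.domain_id for d in again.domains] == [
            d.domain_id for d in chain.domains
        ]


class TestContinuityAndLinkers:
    @pytest.mark.parametrize("n_segments,expected", [
        (1, "continuous"), (2, "discontinuous"), (3, "discontinuous"),
    ])
    def test_continuity_by_segment_count(self, n_segments, expected):
        segs = [Segment("A", 1 + 10 * k, 5 + 10 * k) for k in range(n_segments)]
        chain = ChainStructure(
            "T3_A",
            [Residue("A", ResidueID(i), "A",
                     [Atom("CA", "C", np.array([3.8 * i, 0, 0]))], None)
             for i in range(1, 40)],
        )
        d = DomainDefinition("T3_A", 1, segs, "f", 2.0)
        chain = apply_domain_definitions(chain, [d])
        assert classify_continuity(chain.domains[0]) == expected

    @pytest.mark.parametrize("spans,expected", [
        ([(1, 60), (61, 120)], 0),
        ([(1, 55), (61, 120)], 5),
    ])
    def test_linker_length_resolved(self, spans, expected):
        chain = _chain_with_domains(spans)
        assert linker_length(chain, *chain.domains) == expected
        assert linker_length(chain, chain.domains[1], chain.domains[0]) == expected

    def test_linker_counts_missing_by_numbering(self):
        chain = _chain_with_domains([(1, 50), (61, 120)], gap=(51, 60))
        assert linker_length(chain, *chain.domains) == 10

    def test_overlapping_domains_error(self):
        chain = _chain_with_domains([(1, 60), (50, 120)])
        with pytest.raises(ValueError, match="overlap"):
            linker_length(chain, *chain.domains)

    def test_resolved_long_linker_is_consecutive(self):
        chain = _chain_with_domains([(1, 50), (71, 120)], n=120)
        # remove the numbering gap: renumber via fully resolved 20-res linker
        chain2 = _chain_with_domains([(1, 50), (71, 120)])
        assert is_consecutive_pair(chain2, *chain2.domains) is True

    @pytest.mark.parametrize("gap_len,expected", [(13, True), (14, False)])
    def test_missing_linker_cutoff_boundary(self, gap_len, expected):
        chain = _chain_with_domains([(1, 50), (51 + gap_len, 140)],
                                    gap=(51, 50 + gap_len), n=140)
        assert is_consecutive_pair(chain, *chain.domains) is expected

    def test_intervening_domain_blocks_consecutive(self):
        chain = _chain_with_domains([(1, 40), (45, 80), (85, 120)])
        a, b, c = chain.domains
        assert is_consecutive_pair(chain, a, c) is False
        assert is_consecutive_pair(chain, a, b) is True


class TestMajorSegment:
    def _discontinuous_pair(self, main_len, tail_len, iface_contrib=25,
                            split_tail=False):
        """Domain A = main segment plus one or two tail segments; B contacts
        A's main segment over roughly ``iface_contrib`` residues."""
        res = []
        for i in range(1, main_len + 1):
            ca = Atom("CA", "C", np.array([1.0 * i, 0.0, 0.0]))
            res.append(Residue("A", ResidueID(i), "A", [ca], ca))
        b_start = main_len + 10
        for k in range(60):
            i = b_start + k
            y = 2.0 if k < iface_contrib else 50.0
            ca = Atom("CA", "C", np.array([1.0 * k, y, 0.0]))
            res.append(Residue("A", ResidueID(i), "A", [ca], ca))
        t_start = b_start + 70
        for k in range(tail_len):
            i = t_start + k
            ca = Atom("CA", "C", np.array([1.0 * k, -50.0, 0.0]))
            res.append(Residue("A", ResidueID(i), "A", [ca], ca))
        chain = ChainStructure("T4_A", res)
        if split_tail:
            half = tail_len // 2
            tail_segs = [
                Segment("A", t_start, t_start + half - 1),
                Segment("A", t_start + half, t_start + tail_len - 1),
            ]
        else:
            tail_segs = [Segment("A", t_start, t_start + tail_len - 1)]
        d_a = DomainDefinition(
            "T4_A", 1, [Segment("A", 1, main_len)] + tail_segs, "fa", 2.0)
        d_b = DomainDefinition(
            "T4_A", 2, [Segment("A", b_start, b_start + 59)], "fb", 2.0)
        chain = apply_domain_definitions(chain, [d_a, d_b])
        dom_a, dom_b = chain.domains
        iface = build_interface(dom_a, dom_b)
        return dom_a, iface

    def test_accepted_when_all_rules_pass(self):
        dom, iface = self._discontinuous_pair(120, 30)
        seg = select_major_segment(dom, iface)
        assert seg is not None and (seg.start, seg.end) == (1, 120)

    def test_rejected_below_min_length(self):
        dom, iface = self._discontinuous_pair(99, 30)
        assert select_major_segment(dom, iface) is None

    def test_rejected_below_coverage(self):
        # longest segment 150 of a 334-residue domain: 45% coverage
        dom, iface = self._discontinuous_pair(150, 184, split_tail=True)
        assert select_major_segment(dom, iface) is None

    def test_rejected_below_interface_contribution(self):
        dom, iface = self._discontinuous_pair(120, 30, iface_contrib=15)
        assert select_major_segment(dom, iface) is None

    def test_continuous_domain_rejected_by_precondition(self):
        chain = _chain_with_domains([(1, 60), (61, 120)])
        iface = build_interface(*chain.domains)
        with pytest.raises(ValueError):
            select_major_segment(chain.domains[0], iface)
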