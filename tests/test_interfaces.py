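"""Contact maps, interface residue sets, planarity."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ddiscape import (
    build_interface,
    heavy_atom_contacts,
    interface_planarity,
    is_interacting_pair,
)
from ddiscape.structures import (
    Atom,
    DomainDefinition,
    DomainInstance,
    Residue,
    ResidueID,
    Segment,
)
from oracle_utils import toy_interface


def _domain(atom_specs, entry="X1_A", number=1):
    """Domain from [(residue atoms as (name, element, xyz)), ...]."""
    residues = []
    for k, atoms in enumerate(atom_specs):
        alist = [Atom(n, e, np.array(c, float)) for n, e, c in atoms]
        ca = next((a for a in alist if a.name == "CA"), None)
        residues.append(Residue("A", ResidueID(100 * number + k), "A", alist, ca))
    d = DomainDefinition(entry, number,
                         [Segment("A", 100 * number, 100 * number + len(atom_specs))],
                         f"f{number}", 2.0)
    return DomainInstance(definition=d, residues=residues)


class TestContacts:
    @pytest.mark.parametrize("dist,expect_contact", [(4.4, True), (4.5, True),
                                                     (4.6, False)])
    def test_cutoff_boundary(self, dist, expect_contact):
        a = _domain([[("CA", "C", (0, 0, 0))]], number=1)
        b = _domain([[("CA", "C", (dist, 0, 0))]], number=2)
        contacts = heavy_atom_contacts(a, b)
        assert bool(contacts) is expect_contact

    def test_hydrogens_do_not_count(self):
        a = _domain([[("CA", "C", (0, 0, 0)), ("H", "H", (4.0, 0, 0))]], number=1)
        b = _domain([[("CA", "C", (8.0, 0, 0)), ("H", "H", (5.0, 0, 0))]], number=2)
        assert heavy_atom_contacts(a, b) == []

    def test_matches_all_pairs_double_loop(self):
        rng = np.random.default_rng(0)
        a = _domain([[("CA", "C", rng.uniform(0, 12, 3))] for _ in range(15)],
                    number=1)
        b = _domain([[("CA", "C", rng.uniform(3, 15, 3))] for _ in range(15)],
                    number=2)
        fast = {(c.res_a, c.res_b): c.min_heavy_distance
                for c in heavy_atom_contacts(a, b)}
        slow = {}
        for i, ra in enumerate(a.residues):
            for j, rb in enumerate(b.residues):
                dmin = min(
                    np.linalg.norm(x.coord - y.coord)
                    for x in ra.atoms for y in rb.atoms
                )
                if dmin <= 4.5:
                    slow[(i, j)] = dmin
        assert fast.keys() == slow.keys()
        for k in fast:
            assert fast[k] == pytest.approx(slow[k])

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(1)
        a = _domain([[("CA", "C", rng.uniform(0, 10, 3))] for _ in range(12)],
                    number=1)
        b = _domain([[("CA", "C", rng.uniform(2, 12, 3))] for _ in range(12)],
                    number=2)
        prev = set()
        for cutoff in (3.0, 4.0, 4.5, 6.0):
            cur = {(c.res_a, c.res_b) for c in heavy_atom_contacts(a, b, cutoff)}
            assert prev <= cur
            prev = cur

    def test_empty_domain_error(self):
        a = _domain([[("CA", "C", (0, 0, 0))]], number=1)
        b = DomainInstance(
            definition=DomainDefinition("X1_A", 2, [Segment("A", 1, 2)], "f", 2.0),
            residues=[],
        )
        with pytest.raises(ValueError):
            heavy_atom_contacts(a, b)


class TestBuildInterface:
    def test_distinct_contact_pairs_give_L(self):
        # 12 contacting residue pairs, all residues distinct: L = 24
        a = _domain([[("CA", "C", (4.0 * i, 0, 0))] for i in range(12)], number=1)
        b = _domain([[("CA", "C", (4.0 * i, 4.0, 0))] for i in range(12)], number=2)
        iface = build_interface(a, b)
        assert iface.L == 24 and len(iface.contacts) == 12

    def test_far_domains_empty_interface(self):
        a = _domain([[("CA", "C", (0, 0, 0))]], number=1)
        b = _domain([[("CA", "C", (100, 0, 0))]], number=2)
        iface = build_interface(a, b)
        assert iface.L == 0 and iface.is_empty

    def test_per_residue_contact_count(self):
        a = _domain([[("CA", "C", (0, 0, 0))]], number=1)
        b = _domain([[("CA", "C", (3.0, 0, 0))], [("CA", "C", (0, 3.0, 0))],
                     [("CA", "C", (0, 0, 3.0))]], number=2)
        iface = build_interface(a, b)
        assert iface.per_residue_contact_counts[("a", 0)] == 3

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a = _domain([[("CA", "C", rng.uniform(0, 10, 3))] for _ in range(10)],
                    number=1)
        b = _domain([[("CA", "C", rng.uniform(2, 12, 3))] for _ in range(10)],
                    number=2)
        ab = build_interface(a, b)
        ba = build_interface(b, a)
        assert ab.L == ba.L
        assert {(c.res_a, c.res_b) for c in ab.contacts} == {
            (c.res_b, c.res_a) for c in ba.contacts
        }

    def test_rigid_invariance(self):
        rng = np.random.default_rng(3)
        coords_a = [rng.uniform(0, 10, 3) for _ in range(10)]
        coords_b = [rng.uniform(2, 12, 3) for _ in range(10)]
        rot = Rotation.random(random_state=rng).as_matrix()
        shift = rng.uniform(-30, 30, 3)
        a1 = _domain([[("CA", "C", c)] for c in coords_a], number=1)
        b1 = _domain([[("CA", "C", c)] for c in coords_b], number=2)
        a2 = _domain([[("CA", "C", rot @ c + shift)] for c in coords_a], number=1)
        b2 = _domain([[("CA", "C", rot @ c + shift)] for c in coords_b], number=2)
        i1, i2 = build_interface(a1, b1), build_interface(a2, b2)
        assert i1.contact_pairs == i2.contact_pairs and i1.L == i2.L


class TestInteractingRule:
    @pytest.mark.parametrize("n_pairs,expected", [(10, True), (9, False)])
    def test_20_residue_boundary(self, n_pairs, expected):
        # n_pairs distinct contacting pairs -> L = 2 * n_pairs
        a = _domain([[("CA", "C", (4.0 * i, 0, 0))] for i in range(n_pairs)],
                    number=1)
        b = _domain([[("CA", "C", (4.0 * i, 4.0, 0))] for i in range(n_pairs)],
                    number=2)
        assert is_interacting_pair(build_interface(a, b)) is expected

    def test_empty_interface_not_interacting(self):
        a = _domain([[("CA", "C", (0, 0, 0))]], number=1)
        b = _domain([[("CA", "C", (100, 0, 0))]], number=2)
        assert is_interacting_pair(build_interface(a, b)) is False


class TestPlanarity:
    def test_coplanar_zero(self):
        rng = np.random.default_rng(4)
        pts = np.column_stack([rng.uniform(0, 10, 8), rng.uniform(0, 10, 8),
                               np.zeros(8)])
        iface = toy_interface(pts[:4], pts[4:], [(i, i) for i in range(4)])
        assert interface_planarity(iface) == pytest.approx(0.0, abs=1e-9)

    def test_alternating_offsets_rms_one(self):
        # saddle: ±1 Å offsets arranged so the optimal plane is z = 0
        # (symmetric cross-moments vanish), hence RMS deviation is exactly 1
        pts = np.array([[10, 10, 1.0], [-10, -10, 1.0],
                        [10, -10, -1.0], [-10, 10, -1.0]])
        iface = toy_interface(pts[:2], pts[2:], [(i, i) for i in range(2)])
        assert interface_planarity(iface) == pytest.approx(1.0, abs=1e-9)

    def test_matches_numeric_minimization(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 3, size=(12, 3)) * np.array([3, 2, 0.5])
        iface = toy_interface(pts[:6], pts[6:], [(i, i) for i in range(6)])
        ours = interface_planarity(iface)

        def rms(params):
            theta, phi, offset = params
            n = np.array([np.sin(theta) * np.cos(phi),
                          np.sin(theta) * np.sin(phi), np.cos(theta)])
            return np.sqrt(np.mean((pts @ n - offset) ** 2))

        best = min(
            minimize(rms, x0, method="Nelder-Mead").fun
            for x0 in [(0.1, 0.1, 0.0), (1.0, 2.0, 1.0), (2.0, 4.0, -1.0)]
        )
        assert ours == pytest.approx(best, abs=1e-4)

    def test_too_few_residues_error(self):
        pts = np.array([[0, 0, 0.0], [5, 0, 0]])
        iface = toy_interface(pts[:1], pts[1:], [(0, 0)])
        with pytest.raises(ValueError):
            interface_planarity(iface)
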