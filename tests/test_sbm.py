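"""Go-topology construction and the engineered variants."""

import dataclasses

import numpy as np
import pytest

from cago.dynamics import forces, potential_energy
from cago.sbm import (
    SBMTopology,
    build_dual_model,
    build_wt_model,
    circular_permute,
    delete_interface,
)
from cago.structure_io import (
    CAlphaStructure,
    Contact,
    ContactMap,
    DomainPartition,
    classify_contacts,
    compute_contact_map,
)
from conftest import random_compact_chain


class TestBuildWTModel:
    def test_native_energy_is_minus_contact_sum(self, small_topology, small_cmap):
        e, br = potential_energy(small_topology, small_topology.native_coords)
        assert e == pytest.approx(-small_cmap.epsilons().sum(), abs=1e-6)
        assert br["bonds"] == pytest.approx(0.0, abs=1e-9)
        assert br["angles"] == pytest.approx(0.0, abs=1e-9)
        assert br["dihedrals"] == pytest.approx(0.0, abs=1e-9)

    def test_stretched_contact_well_decays(self):
        xyz = np.column_stack([3.8 * np.arange(5), np.zeros(5), np.zeros(5)])
        s = CAlphaStructure(np.arange(1, 6), xyz)
        cmap = ContactMap((Contact(1, 5, 15.2),), 5)
        topo = build_wt_model(s, cmap)
        e_native, _ = potential_energy(topo, xyz)
        assert e_native == pytest.approx(-1.0, abs=1e-6)
        stretched = xyz.copy()
        stretched[:, 0] *= 3.0  # (1,5) distance now 3 sigma
        _, br = potential_energy(topo, stretched)
        assert -0.01 < br["contacts"] < 0.0

    def test_mismatched_contact_map_rejected(self, small_structure):
        bad = ContactMap((Contact(1, 30, 6.0),), 30)
        with pytest.raises(ValueError):
            build_wt_model(small_structure, bad)

    def test_json_round_trip(self, small_topology):
        back = SBMTopology.from_json(small_topology.to_json())
        np.testing.assert_allclose(back.native_coords, small_topology.native_coords)
        np.testing.assert_allclose(back.dih_phi0, small_topology.dih_phi0)
        assert back.contacts == small_topology.contacts


class TestDeleteInterface:
    def _toy_topology(self):
        """Residue 5 loses an interface contact; (2,5) must absorb it."""
        xyz = random_compact_chain(9, seed=11)
        s = CAlphaStructure(np.arange(1, 10), xyz)
        contacts = (
            Contact(2, 5, float(np.linalg.norm(xyz[1] - xyz[4])), 1.0, "intra:A"),
            Contact(5, 9, float(np.linalg.norm(xyz[4] - xyz[8])), 1.0, "interface:A-B"),
        )
        return build_wt_model(s, ContactMap(contacts, 9))

    def test_two_contact_system_solves_sum_equations(self):
        topo = delete_interface(self._toy_topology(), "interface:A-B")
        assert len(topo.contacts) == 1
        c = topo.contacts.contacts[0]
        # residue 5's WT sum was 2 and (2,5) is its only remaining contact
        assert c.epsilon == pytest.approx(2.0, abs=1e-6)
        # residue 9 lost its only contact -> warning recorded
        assert any("no remaining contacts" in p for p in topo.provenance)

    def test_missing_label_rejected(self, small_topology):
        with pytest.raises(ValueError, match="no contacts labelled"):
            delete_interface(small_topology, "interface:X-Y")

    def test_per_residue_sum_conservation(self):
        """Affected residues keep their WT stabilization to 1e-6 and
        contacts not incident to an interface residue are untouched.

        Every interface residue retains intra-domain contacts to residues
        away from the interface, so the per-residue sum constraints are
        feasible (each deficit has somewhere to go)."""
        xyz = random_compact_chain(20, seed=21)
        s = CAlphaStructure(np.arange(1, 21), xyz)
        label = "interface:A-B"
        contacts = []
        for i, j in [(1, 4), (2, 5), (3, 6), (4, 7), (5, 8), (6, 9), (7, 10),
                     (4, 8), (5, 9), (6, 10)]:
            contacts.append(Contact(i, j, 6.0, 1.0, "intra:A"))
        for i, j in [(11, 14), (12, 15), (13, 16), (14, 17), (15, 18),
                     (16, 19), (17, 20), (14, 18), (15, 19)]:
            contacts.append(Contact(i, j, 6.0, 1.0, "intra:B"))
        for i, j in [(8, 13), (9, 14), (10, 15)]:
            contacts.append(Contact(i, j, 6.0, 1.3, label))
        cmap = ContactMap(tuple(contacts), 20)
        topo = build_wt_model(s, cmap)
        out = delete_interface(topo, label)

        def sums(cm):
            d = {}
            for c in cm.contacts:
                d[c.i] = d.get(c.i, 0.0) + c.epsilon
                d[c.j] = d.get(c.j, 0.0) + c.epsilon
            return d

        wt, mut = sums(cmap), sums(out.contacts)
        affected = {r for c in cmap.contacts if c.label == label for r in (c.i, c.j)}
        survivors_of = {
            r for c in out.contacts.contacts for r in (c.i, c.j) if r in affected
        }
        for r in survivors_of:
            assert mut[r] == pytest.approx(wt[r], abs=1e-6)
        untouched = {
            (c.i, c.j): c.epsilon
            for c in cmap.contacts
            if c.i not in affected and c.j not in affected
        }
        for c in out.contacts.contacts:
            if (c.i, c.j) in untouched:
                assert c.epsilon == untouched[(c.i, c.j)]


class TestCircularPermute:
    def test_identity_cut(self, small_structure, small_cmap):
        s2, m2, imap = circular_permute(small_structure, small_cmap,
                                        cut_after=20, linker_length=0)
        assert imap == {i: i for i in range(1, 21)}
        assert m2 == small_cmap

    def test_renumbering_matches_explicit_rebuild(self):
        xyz = random_compact_chain(12, seed=17)
        s = CAlphaStructure(np.arange(1, 13), xyz)
        cmap = compute_contact_map(s)
        s2, m2, imap = circular_permute(s, cmap, cut_after=5, linker_length=2)
        assert len(s2) == 14
        for i in range(6, 13):
            assert imap[i] == i - 5
        for i in range(1, 6):
            assert imap[i] == i + 9
        # coordinates follow the beads
        for old, new in imap.items():
            np.testing.assert_allclose(s2.coords[new - 1], xyz[old - 1])
        # every WT contact maps to exactly one CP contact, sigma/eps kept
        old_pairs = {
            tuple(sorted((imap[c.i], imap[c.j]))): (c.sigma, c.epsilon)
            for c in cmap.contacts
        }
        new_pairs = {(c.i, c.j): (c.sigma, c.epsilon) for c in m2.contacts}
        assert old_pairs == new_pairs

    def test_contact_count_conserved_with_linker(self, small_structure, small_cmap):
        _, m2, _ = circular_permute(small_structure, small_cmap,
                                    cut_after=8, linker_length=4)
        assert len(m2) == len(small_cmap)
        assert m2.n_residues == 24

    def test_complementary_cut_recovers_contact_multiset(self, small_structure,
                                                         small_cmap):
        n = len(small_structure)
        cut = 7
        s2, m2, _ = circular_permute(small_structure, small_cmap, cut, 0)
        s3, m3, _ = circular_permute(s2, m2, n - cut, 0)
        assert sorted((c.i, c.j, round(c.sigma, 9)) for c in m3.contacts) == sorted(
            (c.i, c.j, round(c.sigma, 9)) for c in small_cmap.contacts
        )

    def test_linker_beads_have_bonded_terms_only(self, small_structure, small_cmap):
        s2, m2, imap = circular_permute(small_structure, small_cmap, 8, 4)
        linker = set(range(13, 17))  # new positions of the 4 linker beads
        occupied = {r for c in m2.contacts for r in (c.i, c.j)}
        assert not (linker & occupied)
        topo = build_wt_model(s2, m2)
        # consecutive bonds exist across both junctions
        bond_pairs = {tuple(b) for b in topo.bond_idx}
        assert all((k, k + 1) in bond_pairs for k in range(len(s2) - 1))

    def test_cut_at_end_with_linker_rejected(self, small_structure, small_cmap):
        with pytest.raises(ValueError):
            circular_permute(small_structure, small_cmap, 20, 4)


class TestBuildDualModel:
    def test_identical_conformations_add_nothing(self, small_structure,
                                                 small_cmap, small_topology):
        dual = build_dual_model(small_topology, small_structure)
        assert len(dual.contacts) == len(small_cmap)

    def test_toy_two_conformation_pair(self):
        """A pair within the cutoff only in the second conformation becomes
        the single closed-specific contact."""
        xyz_open = np.column_stack([3.8 * np.arange(8), np.zeros(8), np.zeros(8)])
        xyz_closed = xyz_open.copy()
        # fold the tail back so residues 1 and 8 approach to ~5 A
        xyz_closed[4:] = xyz_open[4:][::-1] * np.array([1, 1, 1.0])
        xyz_closed[4:, 0] = xyz_open[:4][::-1, 0]
        xyz_closed[4:, 1] = 5.0
        s_open = CAlphaStructure(np.arange(1, 9), xyz_open)
        s_closed = CAlphaStructure(np.arange(1, 9), xyz_closed)
        open_map = compute_contact_map(s_open)
        closed_map = compute_contact_map(s_closed)
        expected_added = {
            (c.i, c.j) for c in closed_map.contacts
        } - {(c.i, c.j) for c in open_map.contacts}
        topo = build_wt_model(s_open, open_map)
        dual = build_dual_model(topo, s_closed, epsilon_closed=0.8)
        added = [c for c in dual.contacts.contacts if c.label == "closed-specific"]
        assert {(c.i, c.j) for c in added} == expected_added
        assert all(c.epsilon == 0.8 for c in added)

    def test_energy_decomposition_exact(self, small_structure, small_topology):
        """E_dual(x) = E_open(x) + E_closed_contacts(x) for arbitrary x."""
        rng = np.random.default_rng(0)
        closed = CAlphaStructure(
            small_structure.residue_ids,
            small_structure.coords + 2.0 * rng.standard_normal((20, 3)),
        )
        dual = build_dual_model(small_topology, closed, epsilon_closed=0.5)
        added = [c for c in dual.contacts.contacts if c.label == "closed-specific"]
        assert added, "perturbed conformation should contribute new contacts"
        for _ in range(3):
            x = small_structure.coords + 0.7 * rng.standard_normal((20, 3))
            e_dual, _ = potential_energy(dual, x)
            e_open, _ = potential_energy(small_topology, x)
            r = np.linalg.norm(
                x[[c.i - 1 for c in added]] - x[[c.j - 1 for c in added]], axis=1
            )
            sig = np.array([c.sigma for c in added])
            eps = np.array([c.epsilon for c in added])
            e_closed = float(np.sum(eps * (5 * (sig / r) ** 12 - 6 * (sig / r) ** 10)))
            assert e_dual == pytest.approx(e_open + e_closed, abs=1e-9)

    def test_length_mismatch_rejected(self, small_topology):
        bad = CAlphaStructure(np.arange(1, 11), np.random.default_rng(1).standard_normal((10, 3)) * 20)
        with pytest.raises(ValueError, match="residues"):
            build_dual_model(small_topology, bad)


class TestTuneClosedStrength:
    @staticmethod
    def _lobe_arm_dual():
        """Open state: compact 12-bead lobe with a straight 4-bead arm.
        Closed state: the arm rigidly rotated onto the lobe surface
        (rotation found by a deterministic search), so closed-specific
        contacts dock the arm.  Soft bending terms keep the hinge mobile."""
        import dataclasses

        n_lobe, n_arm = 12, 4
        lobe = random_compact_chain(n_lobe, seed=33)
        c = lobe.mean(axis=0)
        d = lobe[-1] - c
        d /= np.linalg.norm(d)
        arm = np.array([lobe[-1] + d * 3.8 * (k + 1) for k in range(n_arm)])
        pivot = lobe[-1]
        best = None
        sep3 = np.array([[12 + k - j >= 3 for j in range(n_lobe)]
                         for k in range(n_arm)])
        sep2 = np.array([[12 + k - j >= 2 for j in range(n_lobe)]
                         for k in range(n_arm)])
        for ax_seed in range(40):
            rng = np.random.default_rng(ax_seed)
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            for th in np.linspace(0.5, 2.6, 22):
                R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
                arm_c = (arm - pivot) @ R.T + pivot
                dmat = np.linalg.norm(arm_c[:, None] - lobe[None, :], axis=2)
                if dmat[sep2].min() < 4.0:
                    continue
                n_contacts = int(((dmat < 7.8) & sep3).sum())
                if best is None or n_contacts > best[0]:
                    best = (n_contacts, arm_c.copy())
        xyz_open = np.vstack([lobe, arm])
        xyz_closed = np.vstack([lobe, best[1]])
        open_s = CAlphaStructure(np.arange(1, 17), xyz_open)
        closed_s = CAlphaStructure(np.arange(1, 17), xyz_closed)
        topo = dataclasses.replace(
            build_wt_model(open_s, compute_contact_map(open_s)),
            k_angle=2.0, k_dih=0.2,
        )
        return build_dual_model(topo, closed_s, epsilon_closed=1.0)

    def test_returns_smallest_workable_scale(self):
        from cago.dynamics import run_langevin
        from cago.sbm import _closed_scaled, tune_closed_strength
        from cago.thermo import compute_q

        dual = self._lobe_arm_dual()
        grid = (0.1, 0.2, 0.4, 0.7, 1.0, 1.5, 2.0, 3.0)
        scale = tune_closed_strength(dual, T=0.6, seed=5, n_steps=100_000,
                                     grid=grid)
        assert scale in grid

        def occupancies(s):
            closed_idx = dual.contacts.indices_with_label("closed-specific")
            open_eps = [c.epsilon for c in dual.contacts.contacts
                        if c.label != "closed-specific"]
            topo_s = _closed_scaled(dual, s * float(np.mean(open_eps)))
            traj = run_langevin(topo_s, T=0.6, n_steps=100_000, dt=0.003,
                                friction=1.0, seed=5, save_every=100)
            closed = [topo_s.contacts.contacts[k] for k in closed_idx]
            q = compute_q(traj.frames, closed).values
            return float(np.mean(q < 0.3)), float(np.mean(q > 0.7))

        o_open, o_closed = occupancies(scale)
        assert o_open >= 0.10 and o_closed >= 0.10
        below = grid[grid.index(scale) - 1]
        b_open, b_closed = occupancies(below)
        assert b_open < 0.10 or b_closed < 0.10

    def test_hopeless_grid_reports_occupancies(self):
        from cago.sbm import tune_closed_strength

        dual = self._lobe_arm_dual()
        with pytest.raises(RuntimeError, match="occupanc"):
            tune_closed_strength(dual, T=0.6, seed=5, n_steps=20_000,
                                 grid=(0.01,))
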