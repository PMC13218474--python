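"""Contact maps, interface composition, enrichment and the regression."""

import numpy as np
import pytest

from rhpdimer.contacts import (
    adsorption_composition_regression,
    composition_enrichment,
    interacting_residues,
    interface_composition,
    residue_contact_map,
    typepair_contact_timeseries,
)
from rhpdimer.model import MONOMER_CODES, AnalysisConfig

from conftest import build_topology, build_trajectory


class TestResidueContactMap:
    def test_heavy_only_rule_excludes_hydrogen_contacts(self):
        # hydrogens 1 Å apart, nearest heavy atoms 15 Å apart
        atoms = [
            ("A", 1, "M", "C1", "C", True),
            ("A", 1, "M", "H1", "H", False),
            ("B", 1, "O", "C1", "C", True),
            ("B", 1, "O", "H1", "H", False),
        ]
        topo = build_topology(atoms, box=(60.0, 60.0, 60.0))
        coords = [[10.0, 10, 10], [17.0, 10, 10], [25.0, 10, 10], [18.0, 10, 10]]
        traj = build_trajectory(topo, [coords])
        assert residue_contact_map(topo, traj.frame(0), 10.0) == set()
        # any-atom determination still sees the pair
        assert residue_contact_map(topo, traj.frame(0), 10.0, heavy_only=False) == {(1, 1)}

    def test_beyond_cutoff_absent(self):
        atoms = [("A", 1, "M", "C1", "C", True), ("B", 1, "O", "C1", "C", True)]
        topo = build_topology(atoms, box=(60.0, 60.0, 60.0))
        traj = build_trajectory(topo, [[[10.0, 10, 10], [20.5, 10, 10]]])
        assert residue_contact_map(topo, traj.frame(0), 10.0) == set()

    def test_symmetric_under_chain_swap(self, assoc_scenario):
        _, traj, _ = assoc_scenario
        frame = traj.frame(int(np.flatnonzero(assoc_scenario[2].adsorbed_mask)[0]))
        cmap = residue_contact_map(traj.topology, frame, 10.0)
        assert cmap  # adsorbed frame has contacts
        # rebuild from chain 2's perspective by brute force
        topo = traj.topology
        a1 = topo.chain_atoms("A")
        a2 = topo.chain_atoms("B")
        heavy = topo.is_heavy
        a1, a2 = a1[heavy[a1]], a2[heavy[a2]]
        c1 = frame.coordinates[a1].astype(np.float64)
        c2 = frame.coordinates[a2].astype(np.float64)
        d = c2[:, None, :] - c1[None, :, :]
        d -= topo.box * np.round(d / topo.box)
        close = np.sqrt((d**2).sum(axis=2)) <= 10.0
        swapped = {
            (int(topo.residue_index[a1[j]]), int(topo.residue_index[a2[i]]))
            for i, j in zip(*np.nonzero(close))
        }
        assert cmap == swapped


class TestInteractingResidues:
    def test_separated_chains_have_zero_percent(self, null_scenario, default_config):
        _, traj, _ = null_scenario
        rep = interacting_residues(traj, 10.0, default_config)
        for chain in rep.chains:
            assert rep.pct_any_atom(chain) == 0.0
            assert rep.pct_backbone(chain) == 0.0

    def test_recovers_planted_interface(self, assoc_scenario, default_config):
        _, traj, truth = assoc_scenario
        rep = interacting_residues(traj, 10.0, default_config)
        assert rep.interacting["A"] == truth.interface_residues["A"]
        assert rep.interacting["B"] == truth.interface_residues["B"]

    def test_backbone_percent_never_exceeds_any_atom(self, assoc_scenario, default_config):
        _, traj, _ = assoc_scenario
        rep = interacting_residues(traj, 10.0, default_config)
        for chain in rep.chains:
            assert rep.pct_backbone(chain) <= rep.pct_any_atom(chain)

    def test_percent_uses_residue_count_denominator(self):
        atoms = []
        for r in range(1, 11):
            atoms.append(("A", r, "M", "C1", "C", True))
        atoms.append(("B", 1, "O", "C1", "C", True))
        topo = build_topology(atoms, box=(80.0, 80.0, 80.0))
        # only residues 1-3 of chain A near chain B
        coords = [[float(10 + 30 * (r > 3)), 10, 10] for r in range(1, 11)]
        coords.append([15.0, 10, 10])
        traj = build_trajectory(topo, [coords])
        rep = interacting_residues(traj, 10.0)
        assert rep.interacting["A"] == {1, 2, 3}
        assert rep.pct_any_atom("A") == pytest.approx(30.0)


class TestTypepairContacts:
    def test_single_pair_arithmetic(self):
        atoms = [("A", 1, "M", "C1", "C", True), ("B", 1, "E", "C1", "C", True)]
        topo = build_topology(atoms, box=(60.0, 60.0, 60.0))
        traj = build_trajectory(topo, [[[10.0, 10, 10], [15.0, 10, 10]]])
        cts = typepair_contact_timeseries(traj, AnalysisConfig())
        i_m, i_e = MONOMER_CODES.index("M"), MONOMER_CODES.index("E")
        assert cts.raw[0, i_m, i_e] == 1
        assert cts.normalized[0, i_m, i_e] == pytest.approx(1.0)  # a=b=1
        # absent types undefined
        i_o = MONOMER_CODES.index("O")
        assert np.isnan(cts.normalized[0, i_o, i_e])

    def test_no_contacts_gives_zero_series(self, null_scenario, default_config):
        _, traj, _ = null_scenario
        cts = typepair_contact_timeseries(traj, default_config)
        assert cts.raw.sum() == 0

    def test_raw_total_equals_pair_total(self, assoc_scenario, default_config):
        _, traj, truth = assoc_scenario
        cfg = AnalysisConfig(stride=10)
        cts = typepair_contact_timeseries(traj, cfg)
        # independent recount on one adsorbed frame
        f = int(np.flatnonzero(truth.adsorbed_mask)[0])
        row = np.flatnonzero(np.isclose(cts.times_ns, traj.times_ns[f]))
        if len(row):
            topo = traj.topology
            a1, a2 = topo.chain_atoms("A"), topo.chain_atoms("B")
            heavy = topo.is_heavy
            c1 = traj.coordinates[f][a1[heavy[a1]]].astype(np.float64)
            c2 = traj.coordinates[f][a2[heavy[a2]]].astype(np.float64)
            d = c1[:, None, :] - c2[None, :, :]
            d -= topo.box * np.round(d / topo.box)
            n_pairs = int((np.sqrt((d**2).sum(2)) <= 10.0).sum())
            assert cts.raw[row[0]].sum() == n_pairs

    def test_duplicating_type_doubles_raw_not_normalized(self):
        rng = np.random.default_rng(8)
        atoms = [
            ("A", 1, "M", "C1", "C", True),
            ("A", 2, "E", "C1", "C", True),
            ("B", 1, "M", "C1", "C", True),
            ("B", 2, "O", "C1", "C", True),
        ]
        base_coords = np.vstack([rng.uniform(20, 30, (4, 3))])
        topo = build_topology(atoms, box=(60.0, 60.0, 60.0))
        traj = build_trajectory(topo, [base_coords])
        cts = typepair_contact_timeseries(traj, AnalysisConfig())

        # duplicate chain 2's M atom at identical coordinates
        atoms_dup = atoms + [("B", 1, "M", "C1X", "C", False)]
        coords_dup = np.vstack([base_coords, base_coords[2]])
        topo_dup = build_topology(atoms_dup, box=(60.0, 60.0, 60.0))
        traj_dup = build_trajectory(topo_dup, [coords_dup])
        cts_dup = typepair_contact_timeseries(traj_dup, AnalysisConfig())

        i_m = MONOMER_CODES.index("M")
        for i_x in range(len(MONOMER_CODES)):
            assert cts_dup.raw[0, i_x, i_m] == 2 * cts.raw[0, i_x, i_m]
            if cts.raw[0, i_x, i_m]:
                np.testing.assert_allclose(
                    cts_dup.normalized[0, i_x, i_m],
                    cts.normalized[0, i_x, i_m],
                    rtol=1e-12,
                )


class TestInterfaceComposition:
    def test_time_weighting_worked_example(self):
        # chain A: an M residue and an O residue; chain B: one partner atom.
        # The M atom is interfacial for 2 frames, the O atom for 5000.
        atoms = [
            ("A", 1, "M", "C1", "C", True),
            ("A", 2, "O", "C1", "C", True),
            ("B", 1, "E", "C1", "C", True),
        ]
        topo = build_topology(atoms, box=(80.0, 80.0, 80.0))
        far, near_b = [70.0, 40, 40], [35.0, 40, 40]
        frames = []
        for f in range(5000):
            m_pos = [30.0, 40, 40] if f < 2 else far
            frames.append([m_pos, [32.0, 40, 40], near_b])
        traj = build_trajectory(topo, frames, times=np.arange(5000) * 0.01)
        iface = interface_composition(traj, 10.0)
        fr_a = iface.fractions_for("A")
        assert fr_a["M"] == pytest.approx(2 / 5002)
        assert fr_a["O"] == pytest.approx(5000 / 5002)
        # pooled fractions include chain B's partner atom appearances
        assert iface.appearances["E"] == 5000
        assert sum(iface.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_type_interface(self):
        atoms = [
            ("A", 1, "E", "C1", "C", True),
            ("B", 1, "E", "C1", "C", True),
        ]
        topo = build_topology(atoms, box=(60.0, 60.0, 60.0))
        traj = build_trajectory(topo, [[[10.0, 10, 10], [15.0, 10, 10]]])
        iface = interface_composition(traj, 10.0)
        assert iface.fractions == {"M": 0.0, "O": 0.0, "E": 1.0, "S": 0.0}

    def test_undefined_when_no_appearances(self, null_scenario, default_config):
        _, traj, _ = null_scenario
        iface = interface_composition(traj, 10.0, default_config)
        assert iface.fractions is None
        with pytest.raises(ValueError, match="undefined"):
            composition_enrichment(iface, traj.topology)

    def test_matches_planted_appearance_ratios(self, assoc_scenario, default_config):
        _, traj, truth = assoc_scenario
        iface = interface_composition(traj, 10.0, default_config)
        assert iface.appearances == truth.composition_appearances
        assert iface.atom_appearances == truth.atom_appearances

    def test_invariant_to_frame_reordering(self, small_scenario):
        _, traj, _ = small_scenario
        iface = interface_composition(traj, 10.0)
        reordered = build_trajectory(
            traj.topology, traj.coordinates[::-1], traj.times_ns
        )
        iface_r = interface_composition(reordered, 10.0)
        assert iface.appearances == iface_r.appearances


class TestEnrichment:
    def _iface(self, appearances):
        from rhpdimer.contacts import InterfaceComposition

        return InterfaceComposition(
            appearances=appearances,
            atom_appearances={},
            appearances_by_chain={"A": appearances, "B": {c: 0 for c in MONOMER_CODES}},
        )

    def _uniform_topology(self, counts):
        atoms = []
        for chain in ("A", "B"):
            r = 1
            for code, n in counts.items():
                for _ in range(n):
                    atoms.append((chain, r, code, "C1", "C", True))
                    r += 1
        return build_topology(atoms, box=(60.0, 60.0, 60.0))

    def test_neutral_interface_has_unit_enrichment(self):
        counts = {"M": 5, "O": 3, "E": 2, "S": 1}
        topo = self._uniform_topology(counts)
        iface = self._iface({c: 10 * n for c, n in counts.items()})
        rep = composition_enrichment(iface, topo)
        for c in MONOMER_CODES:
            assert rep.enrichment_ratio[c] == pytest.approx(1.0)

    def test_single_type_scaling(self):
        counts = {"M": 2, "O": 2, "E": 2, "S": 2}
        topo = self._uniform_topology(counts)
        iface = self._iface({"M": 100, "O": 0, "E": 0, "S": 0})
        rep = composition_enrichment(iface, topo)
        assert rep.scaled_contacts_per_atom["M"] == pytest.approx(1.0)
        for c in "OES":
            assert rep.scaled_contacts_per_atom[c] == 0.0

    def test_matches_hand_recomputation(self):
        rng = np.random.default_rng(77)
        counts = {"M": 6, "O": 4, "E": 3, "S": 2}
        topo = self._uniform_topology(counts)
        appearances = {c: int(rng.integers(1, 500)) for c in MONOMER_CODES}
        iface = self._iface(appearances)
        rep = composition_enrichment(iface, topo)
        total_app = sum(appearances.values())
        total_atoms = 2 * sum(counts.values())
        for c in MONOMER_CODES:
            cpa = appearances[c] / (2 * counts[c])
            assert rep.contacts_per_atom[c] == pytest.approx(cpa, rel=1e-12)
            want_enrich = (appearances[c] / total_app) / (2 * counts[c] / total_atoms)
            assert rep.enrichment_ratio[c] == pytest.approx(want_enrich, rel=1e-12)


class TestRegression:
    def test_collinear_points(self):
        fits = adsorption_composition_regression(
            {"M": [(0, 0), (1, 1), (2, 2)], "O": [(0, 1), (1, 0)]}
        )
        assert fits["M"].slope == pytest.approx(1.0)
        assert fits["M"].intercept == pytest.approx(0.0)
        assert fits["M"].r == pytest.approx(1.0)
        assert fits["O"].slope == pytest.approx(-1.0)
        assert fits["O"].intercept == pytest.approx(1.0)
        assert fits["O"].r == pytest.approx(-1.0)

    def test_identical_x_undefined(self):
        fits = adsorption_composition_regression({"E": [(1.0, 0.2), (1.0, 0.8)]})
        assert fits["E"] is None

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0, 50, 50)
        y = 0.7 * x + rng.normal(0, 5, 50)
        fits = adsorption_composition_regression({"S": list(zip(x, y))})
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = np.corrcoef(x, y)[0, 1]
        assert fits["S"].slope == pytest.approx(beta[0], abs=1e-10)
        assert fits["S"].intercept == pytest.approx(beta[1], abs=1e-10)
        assert fits["S"].r == pytest.approx(r, abs=1e-10)
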