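"""Side-chain truncation, contact potential, and Delta-affinity scans."""

import numpy as np
import pytest

from condock.alascan import (
    ALA_KEEP,
    EnergyParams,
    MutantSpec,
    alanine_scan,
    ensemble_scan,
    interaction_energy,
    mutate_to_ala,
)
from condock.errors import TopologyError, ValidationError
from condock.structmodel import Pose, ProteinStructure

from tests.conftest import make_residue


LYS_ATOMS = [("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)), ("C", "C", (2.2, 1.3, 0)),
             ("O", "O", (3.4, 1.4, 0)), ("CB", "C", (2.1, -1.2, 0.8)),
             ("CG", "C", (3.0, -2.0, 1.2)), ("CD", "C", (3.9, -2.8, 1.7)),
             ("CE", "C", (4.8, -3.6, 2.2)), ("NZ", "N", (5.7, -4.4, 2.7))]


def _lys_structure(chain="A", seq=1):
    return ProteinStructure("lys", [make_residue(chain, seq, "LYS", LYS_ATOMS)])


def brute_force_energy(pose, params):
    """Independent double loop over all inter-chain heavy-atom pairs."""
    total = 0.0
    for _, ra in pose.receptor.iter_heavy():
        ri = params.radius_of(ra.element)
        for _, la in pose.ligand.iter_heavy():
            rj = params.radius_of(la.element)
            r = float(np.linalg.norm(ra.coord - la.coord))
            if r <= params.pair_cutoff:
                sigma = (ri + rj) * 2 ** (-1 / 6)
                total += 4 * params.epsilon0 * ((sigma / r) ** 12 - (sigma / r) ** 6)
    return total


class TestMutateToAla:
    def test_lysine_truncated_past_cb(self):
        s = _lys_structure()
        mutant = mutate_to_ala(s, MutantSpec((("A", 1, ""),)))
        res = mutant.residues[0]
        assert res.res_name == "ALA"
        assert {a.name for a in res.atoms} == {"N", "CA", "C", "O", "CB"}
        # retained coordinates untouched
        for a in res.atoms:
            orig = next(x for x in s.residues[0].atoms if x.name == a.name)
            np.testing.assert_array_equal(a.coord, orig.coord)

    def test_ala_target_is_identity(self):
        atoms = [a for a in LYS_ATOMS if a[0] in ALA_KEEP]
        s = ProteinStructure("ala", [make_residue("A", 1, "ALA", atoms)])
        mutant = mutate_to_ala(s, MutantSpec((("A", 1, ""),)))
        assert mutant.heavy_identity() == s.heavy_identity()

    def test_gly_is_logged_noop(self, caplog):
        atoms = [a for a in LYS_ATOMS if a[0] in {"N", "CA", "C", "O"}]
        s = ProteinStructure("gly", [make_residue("A", 1, "GLY", atoms)])
        with caplog.at_level("INFO"):
            mutant = mutate_to_ala(s, MutantSpec((("A", 1, ""),)))
        assert mutant.residues[0].res_name == "GLY"
        assert mutant.heavy_identity() == s.heavy_identity()

    def test_double_mutant_commutes(self):
        s = ProteinStructure("two", [
            make_residue("A", 1, "LYS", LYS_ATOMS),
            make_residue("A", 2, "LYS", [(n, e, (x + 10, y, z))
                                         for n, e, (x, y, z) in LYS_ATOMS]),
        ])
        ab = mutate_to_ala(mutate_to_ala(s, MutantSpec((("A", 1, ""),))),
                           MutantSpec((("A", 2, ""),)))
        ba = mutate_to_ala(mutate_to_ala(s, MutantSpec((("A", 2, ""),))),
                           MutantSpec((("A", 1, ""),)))
        both = mutate_to_ala(s, MutantSpec((("A", 1, ""), ("A", 2, ""))))
        assert ab.heavy_identity() == ba.heavy_identity() == both.heavy_identity()

    def test_missing_target_named(self):
        with pytest.raises(ValidationError, match="9"):
            mutate_to_ala(_lys_structure(), MutantSpec((("A", 9, ""),)))

    def test_mutant_spec_parsing(self):
        spec = MutantSpec.parse("A:595:ALA, A:610:ALA")
        assert spec.substitutions == (("A", 595, ""), ("A", 610, ""))
        with pytest.raises(ValidationError):
            MutantSpec.parse("A:595:TRP")


class TestInteractionEnergy:
    def test_pair_minimum_is_minus_epsilon(self):
        """Two carbons at exactly r_i + r_j = 3.40 A sit at the analytic
        minimum of the 12-6 form: energy -epsilon0."""
        rec = ProteinStructure("r", [make_residue("A", 1, "GLY", [("CA", "C", (0, 0, 0))])])
        lig = ProteinStructure("l", [make_residue("B", 1, "GLY", [("CA", "C", (3.40, 0, 0))])])
        e = interaction_energy(Pose("p:1", rec, lig, "p", 1), EnergyParams())
        assert e == pytest.approx(-0.2, abs=1e-12)

    def test_zero_beyond_cutoff(self):
        rec = ProteinStructure("r", [make_residue("A", 1, "GLY", [("CA", "C", (0, 0, 0))])])
        lig = ProteinStructure("l", [make_residue("B", 1, "GLY", [("CA", "C", (10.5, 0, 0))])])
        assert interaction_energy(Pose("p:1", rec, lig, "p", 1)) == 0.0

    def test_agrees_with_brute_force(self, sidechain_pose):
        params = EnergyParams()
        got = interaction_energy(sidechain_pose, params)
        expected = brute_force_energy(sidechain_pose, params)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_invariant_under_rigid_motion(self, sidechain_pose):
        from scipy.spatial.transform import Rotation
        from condock.geometry import RigidTransform

        rng = np.random.default_rng(3)
        t = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(0, 7, 3))
        moved = Pose(
            "m:1",
            sidechain_pose.receptor.with_coords(t.apply(sidechain_pose.receptor.heavy_coords())),
            sidechain_pose.ligand.with_coords(t.apply(sidechain_pose.ligand.heavy_coords())),
            "m", 1)
        assert interaction_energy(moved) == pytest.approx(
            interaction_energy(sidechain_pose), rel=1e-9)


class TestAlanineScan:
    def test_removing_attractive_contacts_weakens_binding(self):
        """A lysine whose side chain provides the only favourable
        inter-chain contacts scans positive (weaker binding)."""
        rec = _lys_structure()
        # partner atom at ideal contact distance from NZ only
        lig = ProteinStructure("l", [make_residue("B", 1, "GLY",
                                                  [("CA", "C", (5.7, -4.4, 6.1))])])
        pose = Pose("p:1", rec, lig, "p", 1)
        result = alanine_scan(pose, side="receptor")
        row = next(r for r in result.rows if r.residue[:2] == ("A", 1))
        assert row.delta_affinity > 0
        # direct recomputation
        mutant = Pose("p:1", mutate_to_ala(rec, MutantSpec((("A", 1, ""),))), lig, "p", 1)
        expected = interaction_energy(mutant) - interaction_energy(pose)
        assert row.delta_affinity == pytest.approx(expected, rel=1e-12)

    def test_gly_and_ala_rows_exactly_zero(self, sidechain_pose):
        result = alanine_scan(sidechain_pose)
        for row in result.rows:
            if row.res_name in ("GLY", "ALA"):
                assert row.delta_affinity == 0.0

    def test_matches_independent_mutate_then_score_loop(self, sidechain_pose):
        params = EnergyParams()
        result = alanine_scan(sidechain_pose, side="both", cutoff=5.0, params=params)
        from condock.interface import interface_map

        imap = interface_map(sidechain_pose, 5.0)
        e_wt = brute_force_energy(sidechain_pose, params)
        for row in result.rows:
            chain, seq, icode, name = row.residue
            if name in ("GLY", "ALA"):
                continue
            spec = MutantSpec(((chain, seq, icode),))
            if row.residue in imap.interface_residues_receptor and chain == "A":
                mut = Pose("m:1", mutate_to_ala(sidechain_pose.receptor, spec),
                           sidechain_pose.ligand, "m", 1)
            else:
                mut = Pose("m:1", sidechain_pose.receptor,
                           mutate_to_ala(sidechain_pose.ligand, spec), "m", 1)
            expected = brute_force_energy(mut, params) - e_wt
            assert row.delta_affinity == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_scan_set_is_interface_only(self, sidechain_pose):
        """Residues outside the 5 A interface are not scanned even when
        their atoms fall inside the energy cutoff."""
        from condock.interface import interface_map

        imap = interface_map(sidechain_pose, 5.0)
        allowed = imap.interface_residues_receptor | imap.interface_residues_ligand
        result = alanine_scan(sidechain_pose)
        assert {r.residue for r in result.rows} <= allowed
        assert len(result.rows) == len(allowed)

    def test_rows_sorted_by_descending_delta(self, sidechain_pose):
        deltas = [r.delta_affinity for r in alanine_scan(sidechain_pose).rows]
        assert deltas == sorted(deltas, reverse=True)

    def test_empty_interface_warns_and_returns_empty(self, sidechain_pose, caplog):
        with caplog.at_level("WARNING"):
            result = alanine_scan(sidechain_pose, cutoff=0.1)
        assert result.rows == []

    def test_double_mutant_additivity(self):
        """For the pairwise inter-chain energy, a double mutation's
        Delta-affinity is exactly the sum of the single mutations'."""
        rec = ProteinStructure("r", [
            make_residue("A", 1, "LYS", LYS_ATOMS),
            make_residue("A", 2, "LYS", [(n, e, (x, y + 8, z))
                                         for n, e, (x, y, z) in LYS_ATOMS]),
        ])
        lig = ProteinStructure("l", [make_residue("B", 1, "GLY", [
            ("CA", "C", (5.7, -4.4, 6.1)), ("C", "C", (5.7, 4.0, 6.1))])])
        pose = Pose("p:1", rec, lig, "p", 1)
        e_wt = interaction_energy(pose)

        def delta(subs):
            mut = Pose("p:1", mutate_to_ala(rec, MutantSpec(subs)), lig, "p", 1)
            return interaction_energy(mut) - e_wt

        d1 = delta((("A", 1, ""),))
        d2 = delta((("A", 2, ""),))
        d12 = delta((("A", 1, ""), ("A", 2, "")))
        assert d12 == pytest.approx(d1 + d2, rel=1e-12, abs=1e-15)


class TestEnsembleScan:
    def _jittered_frames(self, pose, n, sigma, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for i in range(n):
            jr = pose.receptor.with_coords(
                pose.receptor.heavy_coords() + rng.normal(0, sigma, (pose.receptor.n_heavy_atoms, 3)))
            jl = pose.ligand.with_coords(
                pose.ligand.heavy_coords() + rng.normal(0, sigma, (pose.ligand.n_heavy_atoms, 3)))
            frames.append(Pose(f"f:{i}", jr, jl, "f", i + 1))
        return frames

    def test_single_frame_equals_plain_scan(self, sidechain_pose):
        single = ensemble_scan([sidechain_pose])
        plain = alanine_scan(sidechain_pose)
        got = {r.residue: r.delta_affinity for r in single.rows}
        expected = {r.residue: r.delta_affinity for r in plain.rows}
        assert got == pytest.approx(expected)

    def test_two_frames_average(self, sidechain_pose):
        frames = self._jittered_frames(sidechain_pose, 2, 0.05)
        combined = ensemble_scan(frames)
        per_frame = [
            {r.residue: r.delta_affinity for r in alanine_scan(f).rows}
            for f in frames
        ]
        for row in combined.rows:
            vals = [pf.get(row.residue, None) for pf in per_frame]
            if all(v is not None for v in vals):
                assert row.delta_affinity == pytest.approx(np.mean(vals), rel=1e-9)

    def test_jittered_mean_near_zero_jitter_value(self, sidechain_pose):
        """With small frame jitter the snapshot average stays within 3
        standard errors of the rigid value."""
        frames = self._jittered_frames(sidechain_pose, 30, 0.02, seed=4)
        combined = ensemble_scan(frames)
        base = {r.residue: r.delta_affinity for r in alanine_scan(sidechain_pose).rows}
        for row in combined.rows:
            if row.residue not in base or row.res_name in ("GLY", "ALA"):
                continue
            per_frame = []
            for f in frames:
                rows = {r.residue: r.delta_affinity for r in alanine_scan(f).rows}
                if row.residue in rows:
                    per_frame.append(rows[row.residue])
            se = np.std(per_frame, ddof=1) / np.sqrt(len(per_frame))
            assert abs(row.delta_affinity - base[row.residue]) <= 3 * se + 1e-6

    def test_topology_drift_rejected(self, sidechain_pose, toy_complex):
        rec, lig = toy_complex
        other = Pose("o:1", rec, lig, "o", 1)
        with pytest.raises(TopologyError):
            ensemble_scan([sidechain_pose, other])
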