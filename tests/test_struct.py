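"""Superposition, ensemble RMSD, restraint parsing and classification."""

import numpy as np
import pytest

from ssbnmr import simulate as sim
from ssbnmr.struct import (RestraintRecord, ResidueSelection, classify_restraints,
                           ensemble_pairwise_rmsd, read_ensemble,
                           read_restraints_xplor, residue_displacement,
                           superpose, write_ensemble)

from _oracles import quaternion_rotation


def random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


class TestSuperpose:
    def test_identical_models_identity_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 3))
        res = superpose(x, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_invariance_and_transform_recovery(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 3)) * 10
        R = random_rotation(rng)
        t = rng.uniform(-5, 5, 3)
        moved = x @ R.T + t
        res = superpose(moved, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.rotation @ R, np.eye(3), atol=1e-9)
        assert np.allclose(res.apply(moved), x, atol=1e-9)

    def test_rotation_is_always_proper(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = rng.normal(size=(5, 3))
            b = rng.normal(size=(5, 3))
            res = superpose(a, b)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle(self):
        """Kabsch and Horn quaternion solutions agree on random instances."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(4, 15)
            a = rng.normal(size=(n, 3)) * rng.uniform(0.5, 20)
            b = a @ random_rotation(rng).T + rng.normal(size=(n, 3)) * 0.3
            res = superpose(a, b)
            oracle = quaternion_rotation(a, b)
            assert np.allclose(res.rotation, oracle, atol=1e-6)

    def test_degenerate_inputs_rejected(self):
        line = np.c_[np.arange(5.0), np.zeros(5), np.zeros(5)]
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line + 1.0)
        with pytest.raises(ValueError, match="at least 3"):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestEnsembleRmsd:
    def test_identical_models_zero(self):
        ref = sim.build_reference_model(20)
        ens = sim.make_ensemble(ref, 5, dispersion_A=0.0)
        mean, sd, rmsds = ensemble_pairwise_rmsd(ens, ResidueSelection.parse("all:backbone"))
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert len(rmsds) == 10  # C(5, 2)

    def test_rigid_copies_have_zero_pairwise_rmsd(self):
        ref = sim.build_reference_model(15)
        cfg = sim.SimulationConfig(seed=5)
        ens = sim.make_ensemble(ref, 2, dispersion_A=0.0, cfg=cfg)
        moved = sim.rigid_copy(ens, cfg)
        stacked = ens
        stacked.coords[1] = moved.coords[1]
        mean, _, _ = ensemble_pairwise_rmsd(stacked, ResidueSelection.parse("all:all"))
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_dispersion_calibration(self):
        """Mean pairwise RMSD tracks the requested dispersion within 10%."""
        ref = sim.build_reference_model(60)
        sel = ResidueSelection.parse("all:backbone")
        means = []
        for seed in range(1, 41):
            ens = sim.make_ensemble(ref, 8, dispersion_A=1.0,
                                    cfg=sim.SimulationConfig(seed=seed))
            mean, _, _ = ensemble_pairwise_rmsd(ens, sel)
            means.append(mean)
        assert np.mean(means) == pytest.approx(1.0, rel=0.10)

    def test_selection_restricts_atoms(self):
        ref = sim.build_reference_model(30)
        sel = ResidueSelection.parse("3-10:calpha")
        mask = sel.atom_mask(ref)
        assert mask.sum() == 8
        assert set(ref.atom_names[mask]) == {"CA"}

    def test_empty_selection_is_an_error(self):
        ref = sim.build_reference_model(10)
        ens = sim.make_ensemble(ref, 3, dispersion_A=0.5)
        with pytest.raises(ValueError, match="no atoms"):
            ensemble_pairwise_rmsd(ens, ResidueSelection.parse("900-950:backbone"))


class TestDisplacement:
    def test_identical_ensembles_zero_everywhere(self):
        ref = sim.build_reference_model(20)
        ens = sim.make_ensemble(ref, 3, dispersion_A=0.0)
        res = residue_displacement(ens, ens, ResidueSelection.parse("1-20:backbone"),
                                   probe_residue=10)
        assert res.mean == pytest.approx(0.0, abs=1e-9)
        assert res.designated == pytest.approx(0.0, abs=1e-9)

    def test_constructed_probe_displacement_recovered(self):
        """A 3 A probe shift outside the superposition frame is recovered."""
        ref = sim.build_reference_model(30)
        a = sim.make_ensemble(ref, 2, dispersion_A=0.0)
        b = sim.make_ensemble(ref, 2, dispersion_A=0.0)
        probe_mask = (b.residue_ids == 25) & (b.atom_names == "CA")
        b.coords[:, probe_mask, :] += np.array([3.0, 0.0, 0.0])
        # superpose on residues 1-20 only; residue 25 is free to differ
        res = residue_displacement(a, b, ResidueSelection.parse("1-20:backbone"),
                                   probe_residue=25)
        assert res.designated == pytest.approx(3.0, abs=1e-9)
        assert res.mean == pytest.approx(3.0, abs=1e-9)

    def test_missing_probe_is_an_error(self):
        ref = sim.build_reference_model(10)
        ens = sim.make_ensemble(ref, 2, dispersion_A=0.0)
        with pytest.raises(ValueError, match="probe"):
            residue_displacement(ens, ens, ResidueSelection.parse("1-10:backbone"),
                                 probe_residue=99)


class TestClassifyRestraints:
    @staticmethod
    def rec(i, j, source="noe"):
        return RestraintRecord(residue_i=i, residue_j=j, atom_i="HA", atom_j="HN",
                               d=4.0, d_minus=2.2, d_plus=1.0, source=source)

    def test_separation_bin_edges(self):
        """|i-j| of 0/1/4/5/6 fall in intra/sequential/medium/medium/long."""
        records = [self.rec(10, 10 + s) for s in (0, 1, 4, 5, 6)]
        stats = classify_restraints(records)
        assert (stats.intra, stats.sequential, stats.medium, stats.long) == (1, 1, 2, 1)

    def test_single_intra_record_zero_medium_share(self):
        stats = classify_restraints([self.rec(5, 5)])
        assert stats.medium_share == 0.0
        assert stats.noe_total == 1

    def test_categories_partition_noe_total(self):
        rng = np.random.default_rng(7)
        records = [self.rec(int(i), int(j))
                   for i, j in rng.integers(1, 100, size=(200, 2))]
        records += [self.rec(3, 40, source="hbond")]
        stats = classify_restraints(records)
        assert stats.intra + stats.sequential + stats.medium + stats.long == 200
        assert stats.hbond == 1
        assert stats.total == 201

    def test_printed_table_counts_give_medium_share(self):
        """Counts 259/225/85/291 give a 9.9% medium-range share."""
        records = ([self.rec(10, 10)] * 259 + [self.rec(10, 11)] * 225
                   + [self.rec(10, 13)] * 85 + [self.rec(10, 60)] * 291
                   + [self.rec(10, 50, source="hbond")] * 33)
        stats = classify_restraints(records)
        assert stats.noe_total == 860
        assert stats.medium_share == pytest.approx(9.8837, abs=1e-3)
        assert round(stats.medium_share, 1) == 9.9
        assert stats.total == 893


XPLOR_FIXTURE = """\
! synthetic restraint fixture
this line is garbage
assign (resid 3 and name HA)(resid 10 and name HN) 4.0 2.2 1.0
assign (resid 5 and name HN)(resid 5 and name HB) 3.2 1.4 0.6
assign ((resid 7 and name HB1) or (resid 7 and name HB2))
       (resid 8 and name HN) 5.0 3.2 1.2
assign (resid 12 and name HA)(resid 15 and name HN) 4.5 2.7 1.1
assign (resid 2 and name)(resid 4 and name HN) 4.0 2.2 1.0
! hydrogen bond restraints
assign (resid 20 and name N)(resid 24 and name O) 2.9 0.5 0.5
assign (resid 21 and name HN)(resid 25 and name O) 1.9 0.3 0.3
"""


class TestXplorParser:
    def test_fixture_parsing(self, tmp_path):
        path = tmp_path / "restraints.mr"
        path.write_text(XPLOR_FIXTURE)
        records = read_restraints_xplor(path)
        assert len(records) == 6
        first = records[0]
        assert (first.residue_i, first.residue_j) == (3, 10)
        assert first.separation == 7  # long range
        ambiguous = [r for r in records if r.ambiguous]
        assert len(ambiguous) == 1 and ambiguous[0].residue_i == 7
        hbonds = [r for r in records if r.source == "hbond"]
        assert {(r.residue_i, r.residue_j) for r in hbonds} == {(20, 24), (21, 25)}
        # two bad statements collected with line numbers, parsing continued
        assert len(records.parse_errors) == 2
        stats = classify_restraints(records)
        assert stats.hbond == 2
        assert stats.noe_total == 4

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.mr"
        path.write_text("")
        records = read_restraints_xplor(path)
        assert list(records) == []

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="d_minus"):
            RestraintRecord(residue_i=1, residue_j=2, atom_i="HA", atom_j="HN",
                            d=2.0, d_minus=3.0, d_plus=1.0)


class TestPdbIO:
    def test_multi_model_roundtrip(self, tmp_path):
        ref = sim.build_reference_model(12)
        ens = sim.make_ensemble(ref, 4, dispersion_A=0.8,
                                cfg=sim.SimulationConfig(seed=3))
        path = tmp_path / "ens.pdb"
        write_ensemble(ens, path)
        back = read_ensemble(path)
        assert back.n_models == 4
        assert back.n_atoms == ens.n_atoms
        assert np.allclose(back.coords, ens.coords, atol=1e-3)  # 3-decimal columns
        assert list(back.atom_names) == list(ens.atom_names)

    def test_single_model_file(self, tmp_path):
        ref = sim.build_reference_model(8)
        path = tmp_path / "one.pdb"
        write_ensemble(ref, path)
        back = read_ensemble(path)
        assert back.n_models == 1

    def test_mismatched_models_hard_error(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("""\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       3.800   3.800   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ENDMDL
END
""")
        with pytest.raises(ValueError, match="model 2"):
            read_ensemble(path)
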