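"""Chain construction: A-form template, bead topology, restraints, PDB I/O."""

import io

import numpy as np
import pytest

from rnatopo import builder, geometry, sampler, synthetic
from rnatopo.builder import B, P, S, X
from rnatopo.forcefield import ForceFieldParams
from rnatopo.secstruct import parse_structure


class TestAformTemplate:
    def test_one_bp_is_six_beads(self):
        s1, s2 = builder.build_aform_helix([("G", "C")])
        assert s1.shape == (1, 3, 3) and s2.shape == (1, 3, 3)

    def test_axis_length_matches_rise(self):
        # reference value computed from the ideal template itself
        s1, _ = geometry.aform_duplex(11)
        axis = s1[-1, 1] - s1[0, 1]
        # S beads spiral; project onto the helix axis (z of the template)
        assert s1[-1, 1][2] - s1[0, 1][2] == pytest.approx(10 * geometry.RISE)

    def test_cross_pair_distances(self):
        s1, s2 = geometry.aform_duplex(6)
        # strand2 index n-1-k pairs strand1 index k
        ss_dist = np.linalg.norm(s1[0, 1] - s2[-1, 1])
        assert 9.5 < ss_dist < 11.5     # C1'-C1' across a canonical pair
        bb_dist = np.linalg.norm(s1[0, 2] - s2[-1, 2])
        assert 7.0 < bb_dist < 9.5      # glycosidic N-N across a pair

    def test_determinism(self):
        a1, a2 = geometry.aform_duplex(7)
        b1, b2 = geometry.aform_duplex(7)
        assert geometry.kabsch_rmsd(a1.reshape(-1, 3), b1.reshape(-1, 3)) == 0.0


class TestBuildChain:
    def test_hairpin_counts(self, hairpin_chain):
        assert hairpin_chain.n_beads == 27
        assert len(hairpin_chain.group_names) == 1
        gid = hairpin_chain.group_id
        assert (gid >= 0).sum() == 18  # 6 paired residues x 3 beads

    def test_bead_count_formula(self, fixture_library):
        fx = fixture_library["azoarcus"]
        chain = fx.build(relax=False)
        n_nc = sum(1 for p in fx.structure.pairs
                   if p.pair_class == "noncanonical_internal")
        assert n_nc == 5
        assert chain.n_beads == 3 * 195 + n_nc

    def test_noncanonical_pair_machinery(self):
        text = "i\tj\tclass\n1\t12\tcanonical\n2\t11\tcanonical\n" \
               "4\t9\tnoncanonical_internal\n"
        chain = builder.build_chain(
            parse_structure(text, sequence="GGAAGAAACUCC"), relax=False)
        # one extra steric bead, on the purine member (A4 vs C9)
        assert len(chain.extra_bead_of) == 1
        bx = chain.extra_bead_of[(4, 9)]
        assert chain.bead_res[bx] == 4
        # fixed internal NOEs: B-B (5.5, 7.5) and S-S (11, 14)
        windows = {(row[2], row[3]) for row in chain.internal_noe}
        assert windows == {(5.5, 7.5), (11.0, 14.0)}
        # weak base-base attraction exclusively between the paired B beads
        assert chain.attraction_pairs.tolist() == [
            [chain.bead_index(4, B), chain.bead_index(9, B)]]
        # quarter-strength backbone dihedrals on both residues
        assert np.allclose(chain.dihedral_k,
                           0.25 * chain.params.k_dihedral_paired)

    def test_built_helix_is_strain_free(self, hairpin_chain):
        # bonds internal to the rigid group sit exactly at rest length
        chain = builder.build_chain(parse_structure("(((...)))"), relax=False)
        coords = chain.coords
        for (i, j), r0 in zip(chain.bonds, chain.bond_r0):
            if chain.group_id[i] >= 0 and chain.group_id[i] == chain.group_id[j]:
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(r0, abs=1e-9)

    def test_relaxed_build_has_no_overlap_or_broken_bonds(self, hairpin_chain):
        coords = hairpin_chain.coords
        d = np.linalg.norm(coords[hairpin_chain.bonds[:, 0]]
                           - coords[hairpin_chain.bonds[:, 1]], axis=1)
        assert np.max(np.abs(d - hairpin_chain.bond_r0)) < 1.0

    def test_init_coordinates_used_verbatim(self, fixture_library):
        fx = fixture_library["hairpin"]
        chain = fx.build(seed=0, relax=False)
        init = chain.coords + 3.0
        chain2 = builder.build_chain(fx.structure, init=init)
        assert np.array_equal(chain2.coords, init)

    def test_init_wrong_size_rejected(self, fixture_library):
        fx = fixture_library["hairpin"]
        with pytest.raises(builder.BuildError, match="beads"):
            builder.build_chain(fx.structure, init=np.zeros((5, 3)))


class TestRestraints:
    def test_th_roster(self, azoarcus_chain):
        rs = builder.make_restraints("TH", azoarcus_chain)
        assert len(rs.noe) == 8
        assert len(rs.dihedral) == 2
        assert all(k == 50.0 for _, _, k in rs.dihedral)
        assert all(row[4:] == (2.0, 2.0, 2.0) for row in rs.noe)

    def test_l9j5_roster(self, azoarcus_chain):
        rs = builder.make_restraints("L9J5", azoarcus_chain)
        assert len(rs.noe) == 4
        assert len(rs.dihedral) == 0

    def test_rg32(self, azoarcus_chain):
        rs = builder.make_restraints("RG32", azoarcus_chain)
        assert rs.noe == [] and rs.dihedral == []
        assert rs.rg[0] == 32.0

    def test_reference_windows_are_plus_minus_one(self, azoarcus_chain):
        ref = azoarcus_chain.coords
        rs = builder.make_restraints("L9J5", azoarcus_chain, reference=ref)
        for i, j, rmin, rmax, *_ in rs.noe:
            d = np.linalg.norm(ref[i] - ref[j])
            assert rmin == pytest.approx(d - 1.0)
            assert rmax == pytest.approx(d + 1.0)

    def test_reference_defined_restraints_have_zero_energy(self, azoarcus_chain):
        ref = azoarcus_chain.coords
        rs = builder.make_restraints("TH", azoarcus_chain, reference=ref)
        system = sampler.build_system(azoarcus_chain, rs)
        _, terms = system.energy(ref)
        # NOE windows bracket the reference distances, dihedrals target
        # the reference angles: restraint energy is exactly zero
        base = sampler.build_system(azoarcus_chain)
        _, terms0 = base.energy(ref)
        assert terms["noe"] == pytest.approx(terms0["noe"], abs=1e-9)
        assert terms["dihedral"] == pytest.approx(terms0["dihedral"], abs=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            builder.RestraintSet(noe=[(0, 1, 5.0, 4.0, 2, 2, 2)])
        with pytest.raises(ValueError):
            builder.RestraintSet(noe=[(0, 1, 4.0, 5.0, -2, 2, 2)])


class TestPdbMapping:
    SYNTH_PDB = """\
ATOM      1  P     G A  12      10.000  20.000  30.000  1.00  0.00           P
ATOM      2  C1'   G A  12      13.000  21.000  30.500  1.00  0.00           C
ATOM      3  N9    G A  12      14.500  22.000  31.000  1.00  0.00           N
ATOM      4  O5'   C A  13      18.000  20.000  30.000  1.00  0.00           O
ATOM      5  C1'   C A  13      20.000  21.000  30.000  1.00  0.00           C
ATOM      6  N1    C A  13      21.500  22.000  30.200  1.00  0.00           N
END
"""

    def _ss(self):
        return parse_structure("..", sequence="GC",
                               numbering_map={1: "G12", 2: "C13"})

    def test_atom_selection(self):
        coords, report = builder.map_pdb_to_beads(io.StringIO(self.SYNTH_PDB),
                                                  self._ss())
        assert np.allclose(coords[0], [10, 20, 30])       # P <- P atom
        assert np.allclose(coords[1], [13, 21, 30.5])     # S <- C1'
        assert np.allclose(coords[2], [14.5, 22, 31])     # B <- N9 (purine)
        assert np.allclose(coords[5], [21.5, 22, 30.2])   # B <- N1 (pyrimidine)

    def test_missing_p_imputed_from_o5(self):
        coords, report = builder.map_pdb_to_beads(io.StringIO(self.SYNTH_PDB),
                                                  self._ss())
        assert np.allclose(coords[3], [18, 20, 30])
        assert any("imputed from O5'" in line for line in report)

    def test_missing_chain_errors(self):
        with pytest.raises(builder.BuildError, match="chain"):
            builder.map_pdb_to_beads(io.StringIO(self.SYNTH_PDB), self._ss(),
                                     chain_id="Z")

    def test_coarse_pdb_round_trip(self, hairpin_chain):
        buf = io.StringIO()
        builder.write_coarse_pdb(hairpin_chain, buf)
        buf.seek(0)
        coords = builder.read_coarse_pdb(buf)
        # PDB format carries 3 decimals
        assert np.allclose(coords, hairpin_chain.coords, atol=2e-3)
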