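"""Contact free energies, cooperativity, fold-energy transfer, proxies."""

import math

import numpy as np
import pytest

from rnatopo import energetics, synthetic
from rnatopo.energetics import (
    ContactDefinition,
    FoldEnergyParams,
    contact_probability_from_mask,
    ddg_coop,
    detect_p4p6_stacking,
    dg_fold,
    dg_topo,
    dg_topo_bound,
    fjc_pivot_penalty,
)
from rnatopo.forcefield import R_KCAL


class TestDgTopo:
    def test_half_probability_is_zero(self):
        assert dg_topo(0.5) == 0.0

    def test_printed_example(self):
        assert dg_topo(0.003, 300.0) == pytest.approx(3.46, abs=0.01)

    @pytest.mark.parametrize("p", [0.1, 0.25, 0.4])
    def test_antisymmetry(self, p):
        assert dg_topo(p) == pytest.approx(-dg_topo(1 - p), abs=1e-12)

    def test_oracle_equivalence(self):
        # independent brute-force counter on a synthetic trajectory slice
        ens = synthetic.gen_contact_ensemble(0.2, 5000, seed=3)
        d = np.linalg.norm(ens.frames[:, 0] - ens.frames[:, 1], axis=1)
        hits = int((d < ens.cutoff).sum())
        p = hits / len(d)
        direct = -R_KCAL * 300.0 * math.log(p / (1 - p))
        assert dg_topo(p) == pytest.approx(direct, abs=1e-12)
        assert hits == int(ens.mask.sum())  # generator embeds exact truth

    def test_degenerate_p_raises_and_bounds(self):
        with pytest.raises(ValueError):
            dg_topo(0.0)
        with pytest.raises(ValueError):
            dg_topo(1.0)
        lo = dg_topo_bound(1000, formed=False)
        hi = dg_topo_bound(1000, formed=True)
        assert lo == pytest.approx(-hi)
        assert lo == pytest.approx(dg_topo(1 / 1001))


class TestDdgAndFold:
    def test_equal_inputs_zero(self):
        assert ddg_coop(2.2, 2.2) == 0.0

    def test_arithmetic(self):
        assert ddg_coop(2.4, 4.3) == pytest.approx(-1.9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ddg_coop(float("inf"), 1.0)

    def test_fold_transfer_printed_value(self):
        # reference constants (-0.3, 2.9) and the L2/J8 penalty 3.5
        assert dg_fold(3.5, FoldEnergyParams(-0.3, 2.9)) == pytest.approx(0.3)

    def test_fold_identity_at_reference(self):
        p = FoldEnergyParams(-0.3, 2.9)
        assert dg_fold(p.dg_ref_topo, p) == pytest.approx(p.dg_ref_fold)

    def test_fold_linearity(self):
        p = FoldEnergyParams()
        for x, d in ((1.0, 0.25), (4.2, -1.3)):
            assert dg_fold(x + d, p) - dg_fold(x, p) == pytest.approx(d)


class TestFjcPenalty:
    def test_equal_counts(self):
        assert fjc_pivot_penalty(3, 3) == 0.0

    def test_two_vs_four(self):
        # closed-form Gaussian-chain ratio: -RT (3/2) ln 2 at 300 K
        expect = -R_KCAL * 300.0 * 1.5 * math.log(2.0)
        got = fjc_pivot_penalty(2, 4)
        assert got == pytest.approx(expect)
        assert got == pytest.approx(-0.62, abs=0.01)

    def test_monotone(self):
        vals = [fjc_pivot_penalty(2, nb) for nb in (2, 3, 4, 6)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            fjc_pivot_penalty(0, 2)


class TestContactProbability:
    def test_generator_recovery(self):
        ens = synthetic.gen_contact_ensemble(0.25, 100_000, seed=9)
        res = contact_probability_from_mask(ens.mask, seed=1)
        truth = dg_topo(0.25)
        se = np.sqrt(0.25 * 0.75 / len(ens.mask))
        assert res.p == pytest.approx(0.25, abs=3 * se)
        assert res.ci[0] <= res.dg <= res.ci[1]
        assert abs(res.dg - truth) < 0.02

    def test_parameter_recovery_coverage(self):
        # >= 90% CI coverage over 50 seeded replicates for each target p
        for p_target in (0.5, 0.1, 0.01):
            truth = dg_topo(p_target)
            cover = 0
            for seed in range(50):
                ens = synthetic.gen_contact_ensemble(p_target, 4000, seed=seed)
                res = contact_probability_from_mask(ens.mask, seed=seed,
                                                    n_boot=400)
                if res.is_bound:
                    continue
                if res.ci[0] <= truth <= res.ci[1]:
                    cover += 1
            assert cover >= 45

    def test_infinite_cutoff_always_formed(self, hairpin_chain):
        cdef = ContactDefinition((1, 2), (8, 9), cutoff=1e9)
        mask = energetics.contact_mask(hairpin_chain,
                                       hairpin_chain.coords[None], cdef)
        assert mask.all()

    def test_min_pairs_exceeding_combinations_never_forms(self, hairpin_chain):
        cdef = ContactDefinition((1,), (9,), cutoff=1e9, min_pairs=2)
        mask = energetics.contact_mask(hairpin_chain,
                                       hairpin_chain.coords[None], cdef)
        assert not mask.any()

    def test_symmetry_in_sets(self, hairpin_chain):
        frames = hairpin_chain.coords[None]
        a = energetics.contact_mask(hairpin_chain, frames,
                                    ContactDefinition((1, 2), (8, 9)))
        b = energetics.contact_mask(hairpin_chain, frames,
                                    ContactDefinition((8, 9), (1, 2)))
        assert np.array_equal(a, b)

    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError, match="zero frames"):
            contact_probability_from_mask(np.zeros(10, bool),
                                          condition=np.zeros(10, bool))

    def test_conditioning_mask(self):
        mask = np.array([1, 1, 0, 0, 1, 0, 1, 0], bool)
        cond = np.array([1, 0, 1, 0, 1, 0, 1, 0], bool)
        res = contact_probability_from_mask(mask, condition=cond)
        assert res.p == pytest.approx(3 / 4)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            ContactDefinition((1, 2), (2, 3))

    def test_bound_result_flagged(self):
        res = contact_probability_from_mask(np.zeros(500, bool))
        assert res.is_bound
        assert res.dg is None
        assert res.value_or_bound() == pytest.approx(dg_topo(1 / 501))


class TestStackingProxy:
    def test_threshold_grid_matches_brute_force(self, azoarcus_chain):
        # synthetic bend/gap grid: rigidly re-pose P6 relative to P4 and
        # compare the detector against an exhaustive classifier
        from rnatopo import euler as eu

        chain = azoarcus_chain
        coords = chain.coords
        hits_detector = []
        hits_oracle = []
        for beta_min in (120.0, 150.0):
            for gap_max in (5.0, 7.0, 12.0, 40.0):
                got = detect_p4p6_stacking(coords, chain,
                                           beta_min=beta_min, gap_max=gap_max)
                fa = eu.helix_frame(chain, coords, "P4")
                fb = eu.helix_frame(chain, coords, "P6")
                beta = eu.euler_angles(fa, fb)[1]
                gap = energetics._facing_gap(coords, chain, "P4", "P6")
                hits_detector.append(got)
                hits_oracle.append(bool(beta > beta_min and gap < gap_max))
        assert hits_detector == hits_oracle

    def test_far_apart_is_false(self, azoarcus_chain):
        # blow the molecule apart: shift everything after P4 by 100 Å
        coords = azoarcus_chain.coords.copy()
        sel = azoarcus_chain.bead_res > 70
        coords[sel] += 100.0
        assert not detect_p4p6_stacking(coords, azoarcus_chain)


class TestMatrices:
    def test_tl_tlr_matrix_shape(self, fixture_library):
        import rnatopo.sampler as smp

        chain = fixture_library["two_way_junction"].build(seed=0)
        cfg = smp.SamplerConfig(temperatures=(300.0,), total_steps=20_000,
                                steps_per_exchange=500, store_frame_stride=1,
                                seed=8)
        traj = smp.remd_run(chain, None, cfg)
        df = energetics.tl_tlr_matrix(chain, traj, ["loop"], ["bulge"],
                                      native_pairs=[], min_pairs=1)
        assert len(df) == 1
        row = df.iloc[0]
        assert np.isfinite(row.dG_topo)
        assert 0 <= row.p <= 1

    def test_pairwise_map_excludes_self(self, fixture_library):
        import rnatopo.sampler as smp

        chain = fixture_library["hairpin"].build(seed=0)
        cfg = smp.SamplerConfig(temperatures=(300.0,), total_steps=5_000,
                                steps_per_exchange=500, store_frame_stride=1,
                                seed=9)
        traj = smp.remd_run(chain, None, cfg)
        df = energetics.pairwise_dg_map(chain, traj, ["loop"])
        assert set(df.residue) == set(range(1, 10)) - {4, 5, 6}
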