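"""Interhelical Euler angles, binning, and sampled-fraction statistics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rnatopo import euler, geometry
from rnatopo.euler import (
    EulerSeries,
    bin_indices,
    decompose_zyz,
    euler_angles,
    fraction_joint,
    fraction_norm,
    fraction_sampled,
    helix_frame,
    n_bins,
    recompose_zyz,
    reference_subsample_size,
)


class TestFrames:
    def test_ideal_helix_axis(self, fixture_library):
        from rnatopo import builder
        # unrelaxed build: the helix is an exact template copy laid along
        # the +x construction direction
        chain = builder.build_chain(fixture_library["hairpin"].structure,
                                    relax=False)
        f = helix_frame(chain, chain.coords, chain.group_names[0])
        assert abs(f.axes[:, 2] @ np.array([1.0, 0, 0])) > 0.999

    def test_equivariance_under_rigid_rotation(self, hairpin_chain):
        r = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        name = hairpin_chain.group_names[0]
        f0 = helix_frame(hairpin_chain, hairpin_chain.coords, name)
        f1 = helix_frame(hairpin_chain, hairpin_chain.coords @ r.T, name)
        assert np.allclose(f1.axes, r @ f0.axes, atol=1e-9)

    def test_subhelix_axis_agrees(self):
        # axis from an 11-bp ideal duplex vs its first 6 bp: < 1 degree
        s1, s2 = geometry.aform_duplex(11)

        def axis(k):
            t1, t2 = geometry.aform_duplex(k)
            tmpl = np.vstack([t1[:, 1], t2[::-1, 1]])
            cur = np.vstack([s1[:k, 1], s2[::-1][:k, 1]])
            rot, _ = geometry.kabsch_transform(tmpl, cur)
            return rot @ np.array([0.0, 0.0, 1.0])

        a, b = axis(11), axis(6)
        ang = np.degrees(np.arccos(min(abs(a @ b), 1.0)))
        assert ang < 1.0

    def test_one_bp_helix_rejected(self, fixture_library):
        from rnatopo import builder
        from rnatopo.secstruct import parse_structure
        chain = builder.build_chain(parse_structure("(...)"), relax=False)
        with pytest.raises(ValueError, match="axis"):
            helix_frame(chain, chain.coords, "H1")


class TestDecomposition:
    def test_identity(self):
        assert euler_angles(np.eye(3), np.eye(3)) == (0.0, 0.0, 0.0)

    def test_pure_bend(self):
        r = recompose_zyz(0.0, 90.0, 0.0)
        a, b, g = decompose_zyz(r)
        assert (a, b, g) == pytest.approx((0.0, 90.0, 0.0), abs=1e-9)

    def test_round_trip_1000_random_rotations(self):
        rng = np.random.default_rng(7)
        mats = Rotation.random(1000, random_state=rng).as_matrix()
        for m in mats:
            a, b, g = decompose_zyz(m)
            assert -180.0 <= a < 180.0 and 0.0 <= b <= 180.0 and -180.0 <= g < 180.0
            assert np.linalg.norm(recompose_zyz(a, b, g) - m) < 1e-9

    @pytest.mark.parametrize("beta", [0.0, 180.0])
    def test_gimbal_assigns_twist_to_alpha(self, beta):
        r = recompose_zyz(40.0, beta, 25.0)
        a, b, g = decompose_zyz(r)
        assert g == 0.0
        assert np.linalg.norm(recompose_zyz(a, b, g) - r) < 1e-9

    def test_inverse_rotations_are_transposes(self):
        rng = np.random.default_rng(3)
        for m in Rotation.random(50, random_state=rng).as_matrix():
            ab = recompose_zyz(*decompose_zyz(m))
            ba = recompose_zyz(*decompose_zyz(m.T))
            assert np.allclose(ab.T, ba, atol=1e-9)


class TestFractions:
    def test_single_conformation(self):
        f = fraction_sampled(EulerSeries([[12.0, 40.0, -100.0]]), 10.0)
        assert f == pytest.approx(1.0 / 23328)

    def test_full_grid(self):
        w = 60.0
        alphas = np.arange(-180, 180, w) + w / 2
        betas = np.arange(0, 180, w) + w / 2
        grid = np.array([(a, b, g) for a in alphas for b in betas for g in alphas])
        assert fraction_sampled(EulerSeries(grid), w) == 1.0

    def test_brute_force_histogram_oracle(self):
        rng = np.random.default_rng(11)
        mats = Rotation.random(3000, random_state=rng).as_matrix()
        angles = np.array([decompose_zyz(m) for m in mats])
        f = fraction_sampled(EulerSeries(angles), 30.0)
        # independent oracle: direct 3D histogram occupancy count
        w = 30.0
        ia = np.floor((angles[:, 0] + 180) / w).astype(int)
        ib = np.minimum(np.floor(angles[:, 1] / w).astype(int), 5)
        ig = np.floor((angles[:, 2] + 180) / w).astype(int)
        occ = len({(x, y, z) for x, y, z in zip(ia, ib, ig)})
        assert f == pytest.approx(occ / (12 * 6 * 12))
        # sin(beta) weighting leaves polar bins rare: strictly below 1
        assert f < 1.0

    def test_bad_bin_width(self):
        with pytest.raises(ValueError, match="bin width"):
            fraction_sampled(EulerSeries([[0, 0, 0]]), 25.0)

    def test_prefix_monotonicity(self):
        rng = np.random.default_rng(5)
        mats = Rotation.random(2000, random_state=rng).as_matrix()
        angles = np.array([decompose_zyz(m) for m in mats])
        fracs = [fraction_sampled(EulerSeries(angles[:m]), 30.0)
                 for m in (100, 500, 1000, 2000)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_joint_denominators(self):
        assert n_bins(30.0) ** 2 == 746_496
        assert n_bins(60.0) ** 3 == 1_259_712

    def test_joint_of_identical_series_equals_single(self):
        rng = np.random.default_rng(9)
        mats = Rotation.random(500, random_state=rng).as_matrix()
        s = EulerSeries(np.array([decompose_zyz(m) for m in mats]))
        occ_single = fraction_sampled(s, 60.0) * n_bins(60.0)
        occ_joint = fraction_joint([s, s], 60.0) * n_bins(60.0) ** 2
        assert occ_single == occ_joint

    def test_joint_k1_equals_fraction_sampled(self):
        rng = np.random.default_rng(13)
        mats = Rotation.random(300, random_state=rng).as_matrix()
        s = EulerSeries(np.array([decompose_zyz(m) for m in mats]))
        assert fraction_joint([s], 30.0) == fraction_sampled(s, 30.0)

    def test_misaligned_series_rejected(self):
        a = EulerSeries(np.zeros((10, 3)))
        b = EulerSeries(np.zeros((9, 3)))
        with pytest.raises(ValueError, match="misaligned"):
            fraction_joint([a, b], 30.0)


class TestFractionNorm:
    def test_matched_density_subsample_size(self):
        # three-way (2x) junction matched to the four-way (3x) reference
        assert reference_subsample_size(k=2) == 4621
        assert reference_subsample_size(k=3) == 499_000

    def test_f_norm_identity(self):
        rng = np.random.default_rng(21)
        mats = Rotation.random(4000, random_state=rng).as_matrix()
        s = EulerSeries(np.array([decompose_zyz(m) for m in mats]))
        out = fraction_norm([s, s], f_trna=1.0, n_conf=4000, seed=0)
        assert out["f_norm"] == out["f_star_samp"]

    def test_f_trna_required(self):
        s = EulerSeries(np.zeros((10, 3)))
        with pytest.raises(ValueError, match="F_trna"):
            fraction_norm([s], f_trna=None, n_conf=5)

    def test_subsample_exceeding_pool(self):
        s = EulerSeries(np.zeros((10, 3)))
        with pytest.raises(ValueError, match="exceeds"):
            fraction_norm([s], f_trna=0.5, n_conf=11)

    def test_edge_sample_goes_to_higher_bin(self):
        idx_lo = bin_indices(np.array([[-180.0, 0.0, -180.0]]), 45.0)[0]
        idx_edge = bin_indices(np.array([[-135.0, 45.0, -135.0]]), 45.0)[0]
        assert idx_lo == 0
        a = bin_indices(np.array([[-135.0 - 1e-9, 0.0, -180.0]]), 45.0)[0]
        b = bin_indices(np.array([[-135.0, 0.0, -180.0]]), 45.0)[0]
        assert b == a + 4 * 8  # exactly one alpha-bin stride higher
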