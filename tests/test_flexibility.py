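import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import pearsonr

from ctxflex import (
    SyntheticSpec,
    chain_profile,
    compute_wcn,
    make_chain,
    seq_profile,
    str_profile,
    znormalize,
)


def wcn_oracle(coords):
    """Naive double-loop weighted contact number."""
    n = len(coords)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i] += 1.0 / np.sum((coords[i] - coords[j]) ** 2)
    return out


def seq_oracle(inv_wcn, n):
    """Naive windowed average ignoring out-of-range indices."""
    length = len(inv_wcn)
    out = np.zeros(length)
    for i in range(length):
        idx = [j for j in range(i - n, i + n + 1) if 0 <= j < length]
        out[i] = np.mean([inv_wcn[j] for j in idx])
    return out


def str_oracle(coords, inv_wcn, cutoff):
    """Naive neighbor-set average with strict cutoff and self-inclusion."""
    n = len(coords)
    out = np.zeros(n)
    for i in range(n):
        members = [
            j for j in range(n)
            if np.linalg.norm(coords[i] - coords[j]) < cutoff
        ]
        out[i] = np.mean([inv_wcn[j] for j in members])
    return out


class TestWCN:
    def test_single_pair(self):
        np.testing.assert_allclose(
            compute_wcn(np.array([[0.0, 0, 0], [2.0, 0, 0]])), [0.25, 0.25]
        )

    def test_three_collinear_hand_sum(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]])
        expected = [1 / 9 + 1 / 36, 1 / 9 + 1 / 9, 1 / 36 + 1 / 9]
        np.testing.assert_allclose(compute_wcn(coords), expected, atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.uniform(0, 30, size=(50, 3))
        np.testing.assert_allclose(compute_wcn(coords), wcn_oracle(coords), atol=1e-12)

    def test_permutation_equivariance(self, rng):
        coords = rng.uniform(0, 30, size=(30, 3))
        perm = rng.permutation(30)
        np.testing.assert_allclose(
            compute_wcn(coords[perm]), compute_wcn(coords)[perm], atol=1e-12
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_wcn(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            compute_wcn(np.array([[0.0, 0, 0], [0.0, 0, 0]]))


class TestSeqProfile:
    def test_edge_windows_average_included_terms(self):
        np.testing.assert_allclose(
            seq_profile(np.array([2.0, 4.0, 6.0]), n=1), [3.0, 4.0, 5.0]
        )

    def test_fixed_denominator_mode_deflates_termini(self):
        np.testing.assert_allclose(
            seq_profile(np.array([2.0, 4.0, 6.0]), n=1, edge="fixed_denominator"),
            [2.0, 4.0, 10.0 / 3.0],
        )

    def test_constant_input_invariant(self, rng):
        const = np.full(17, 3.5)
        for n in (1, 3, 16, 40):
            np.testing.assert_allclose(seq_profile(const, n), const)

    def test_full_window_limit_equals_global_mean(self, rng):
        x = rng.uniform(0.5, 3.0, size=12)
        np.testing.assert_allclose(
            seq_profile(x, n=11), np.full(12, x.mean()), atol=1e-12
        )

    @pytest.mark.parametrize("n", [1, 2, 5, 11])
    def test_matches_oracle(self, rng, n):
        x = rng.uniform(0.1, 5.0, size=37)
        np.testing.assert_allclose(seq_profile(x, n), seq_oracle(x, n), atol=1e-12)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            seq_profile(np.ones(5), n=0)


class TestStrProfile:
    def test_hand_neighbor_sets(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [10.0, 0, 0]])
        inv = np.array([1.0, 3.0, 5.0])
        np.testing.assert_allclose(
            str_profile(coords, inv, cutoff=3.0), [2.0, 2.0, 5.0]
        )

    def test_cutoff_below_min_distance_gives_self_only(self, rng):
        coords = rng.uniform(0, 50, size=(20, 3))
        inv = rng.uniform(0.5, 2.0, size=20)
        np.testing.assert_allclose(str_profile(coords, inv, cutoff=1e-6), inv)

    def test_cutoff_beyond_diameter_gives_global_mean(self, rng):
        coords = rng.uniform(0, 10, size=(15, 3))
        inv = rng.uniform(0.5, 2.0, size=15)
        np.testing.assert_allclose(
            str_profile(coords, inv, cutoff=1e6), np.full(15, inv.mean()), atol=1e-12
        )

    @pytest.mark.parametrize("cutoff", [4.0, 8.0, 15.0])
    def test_matches_oracle(self, rng, cutoff):
        coords = rng.uniform(0, 25, size=(40, 3))
        inv = rng.uniform(0.2, 4.0, size=40)
        np.testing.assert_allclose(
            str_profile(coords, inv, cutoff), str_oracle(coords, inv, cutoff), atol=1e-12
        )

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            str_profile(np.zeros((2, 3)), np.ones(2), cutoff=0.0)


class TestZNormalize:
    def test_closed_form(self):
        np.testing.assert_allclose(
            znormalize(np.array([1.0, 2.0, 3.0])),
            [-np.sqrt(1.5), 0.0, np.sqrt(1.5)],
            atol=1e-12,
        )

    def test_affine_invariance(self, rng):
        x = rng.normal(size=60)
        np.testing.assert_allclose(znormalize(3.7 * x + 11.0), znormalize(x), atol=1e-9)

    def test_output_standardized(self, rng):
        z = znormalize(rng.uniform(size=200))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9

    def test_constant_input_is_error(self):
        with pytest.raises(ValueError):
            znormalize(np.full(10, 2.0))


class TestGeometricProperties:
    def test_rigid_motion_invariance(self, rng):
        coords = rng.uniform(0, 20, size=(40, 3))
        inv = 1.0 / compute_wcn(coords)
        rot = Rotation.random(rng=42).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -3.0, 12.0])
        np.testing.assert_allclose(compute_wcn(moved), compute_wcn(coords), atol=1e-9)
        np.testing.assert_allclose(
            str_profile(moved, inv, 8.0), str_profile(coords, inv, 8.0), atol=1e-9
        )

    def test_scale_covariance(self, rng):
        coords = rng.uniform(0, 20, size=(30, 3))
        s = 2.5
        wcn = compute_wcn(coords)
        np.testing.assert_allclose(compute_wcn(s * coords), wcn / s**2, rtol=1e-9)
        inv = 1.0 / wcn
        np.testing.assert_allclose(
            seq_profile(1.0 / compute_wcn(s * coords), 2),
            s**2 * seq_profile(inv, 2),
            rtol=1e-9,
        )
        np.testing.assert_allclose(
            str_profile(s * coords, 1.0 / compute_wcn(s * coords), s * 6.0),
            s**2 * str_profile(coords, inv, 6.0),
            rtol=1e-9,
        )
        # z-profiles are exactly scale-invariant
        np.testing.assert_allclose(
            znormalize(seq_profile(1.0 / compute_wcn(s * coords), 2)),
            znormalize(seq_profile(inv, 2)),
            atol=1e-9,
        )

    def test_outlier_residue_has_min_wcn_and_max_z(self, rng):
        # compact cluster plus one distant residue: the outlier is least packed
        cluster = rng.normal(scale=3.0, size=(30, 3))
        outlier = np.array([[60.0, 60.0, 60.0]])
        coords = np.vstack([cluster, outlier])
        wcn = compute_wcn(coords)
        assert wcn.argmin() == 30
        assert znormalize(1.0 / wcn).argmax() == 30


class TestChainProfile:
    def test_profiles_standardized_and_consistent(self):
        chain = make_chain(SyntheticSpec(n_residues=60, seed=3))
        prof = chain_profile(chain, n=1, cutoff=3.0)
        for z in (prof.z_seq, prof.z_str, prof.z_b):
            assert abs(z.mean()) < 1e-9
            assert abs(z.std() - 1.0) < 1e-9
        assert np.all(prof.wcn > 0)
        np.testing.assert_allclose(prof.inv_wcn, 1.0 / prof.wcn)
        assert len(prof) == 60

    def test_wcn_bfactor_correlation_on_compact_chain(self):
        # packing density should track the (synthetic) B-factor channel
        chain = make_chain(SyntheticSpec(n_residues=150, seed=5))
        prof = chain_profile(chain)
        r, _ = pearsonr(prof.inv_wcn, chain.b_factors)
        assert r > 0.5

    def test_dataframe_layout(self):
        chain = make_chain(SyntheticSpec(n_residues=30, seed=2))
        df = chain_profile(chain).to_dataframe(chain)
        assert list(df.columns[:5]) == ["res_seq", "icode", "aa", "b_factor", "is_catalytic"]
        assert len(df) == 30
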