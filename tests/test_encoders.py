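import numpy as np
import pytest

from conftest import make_profile, random_profile
from dbp_idwt.encoders import (
    REDUCED_GROUPS,
    encode_fpssm,
    encode_pssm_dpc,
    encode_rpssm,
    filter_negative,
    reduce_profile,
)
from dbp_idwt.io_profiles import AA_ORDER


def naive_dpc(scores, denom):
    """Independent double-loop oracle for the dipeptide descriptor."""
    L = scores.shape[0]
    out = np.zeros((20, 20))
    for i in range(20):
        for j in range(20):
            for k in range(L - 1):
                out[i, j] += scores[k, i] * scores[k + 1, j]
    return (out / denom).ravel()


class TestFilterNegative:
    @pytest.mark.parametrize(
        "row,expected",
        [([-3.0] * 20, [0.0] * 20), ([2.0] * 20, [2.0] * 20)],
        ids=["all-negative", "all-positive"],
    )
    def test_clamps_negatives_only(self, row, expected):
        out = filter_negative(make_profile([row, row]))
        np.testing.assert_array_equal(out.scores, [expected, expected])

    def test_mixed_row(self):
        row = [-1.0, 0.0, 4.0] + [1.0] * 17
        out = filter_negative(make_profile([row, row]))
        assert list(out.scores[0][:3]) == [0.0, 0.0, 4.0]

    def test_idempotent(self, rng):
        profile = random_profile(rng, 12)
        once = filter_negative(profile)
        twice = filter_negative(once)
        np.testing.assert_array_equal(once.scores, twice.scores)


class TestFpssm:
    def test_hand_example_sequence_aa(self):
        profile = make_profile(np.ones((2, 20)), sequence="AA")
        fv = encode_fpssm(profile)
        comp = fv.values.reshape(20, 20)
        np.testing.assert_array_equal(comp[AA_ORDER.index("A")], np.ones(20))
        assert comp.sum() == pytest.approx(20.0)  # other rows all zero

    def test_all_negative_scores_give_zero_vector(self):
        fv = encode_fpssm(make_profile(-3 * np.ones((4, 20)), sequence="ACDE"))
        assert not fv.values.any()

    def test_length_400_and_unknown_residues_skipped(self, rng):
        profile = random_profile(rng, 9)
        fv = encode_fpssm(profile)
        assert fv.values.shape == (400,)
        # an X position contributes to no composition row
        with_x = make_profile(profile.scores, sequence="X" + profile.sequence[1:])
        base = make_profile(profile.scores[1:], sequence=profile.sequence[1:])
        scaled = encode_fpssm(with_x).values * profile.length / (profile.length - 1)
        np.testing.assert_allclose(scaled, encode_fpssm(base).values, atol=1e-12)

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError, match="L >= 2"):
            encode_fpssm(make_profile(np.ones((1, 20))))


class TestPssmDpc:
    def test_two_row_hand_example(self):
        profile = make_profile([[2.0] * 20, [3.0] * 20])
        fv = encode_pssm_dpc(profile)
        np.testing.assert_allclose(fv.values, np.full(400, 3.0))

    def test_matches_naive_oracle_on_random_profiles(self, rng):
        for _ in range(100):
            profile = random_profile(rng, 5)
            got = encode_pssm_dpc(profile).values
            np.testing.assert_allclose(
                got, naive_dpc(profile.scores, 5), atol=1e-9
            )

    def test_alternative_denominator(self, rng):
        profile = random_profile(rng, 6)
        by_l = encode_pssm_dpc(profile, denominator="L").values
        by_lm1 = encode_pssm_dpc(profile, denominator="L-1").values
        np.testing.assert_allclose(by_l * 6 / 5, by_lm1, atol=1e-9)

    def test_zero_row_kills_adjacent_products(self):
        scores = np.zeros((3, 20))
        scores[1] = 0.0
        scores[0] = scores[2] = 5.0
        np.testing.assert_array_equal(encode_pssm_dpc(make_profile(scores)).values, 0)


class TestReduceProfile:
    def test_group_means_hand_example(self):
        row = np.zeros(20)
        row[AA_ORDER.index("F")] = 3.0
        row[AA_ORDER.index("Y")] = 6.0
        row[AA_ORDER.index("W")] = 0.0
        reduced = reduce_profile(make_profile([row, row]))
        assert reduced.values[0, 0] == pytest.approx(3.0)  # G1 = (3+6+0)/3

    def test_constant_row_maps_to_constant_groups(self):
        reduced = reduce_profile(make_profile(np.full((2, 20), 7.0)))
        np.testing.assert_allclose(reduced.values, 7.0)

    def test_shape_and_group_order(self, rng):
        reduced = reduce_profile(random_profile(rng, 13))
        assert reduced.values.shape == (13, 10)
        assert reduced.group_order == tuple(g for g, _ in REDUCED_GROUPS)

    def test_commutes_with_row_permutation(self, rng):
        profile = random_profile(rng, 8)
        perm = rng.permutation(8)
        permuted = make_profile(
            profile.scores[perm], sequence="".join(profile.sequence[i] for i in perm)
        )
        np.testing.assert_array_equal(
            reduce_profile(permuted).values, reduce_profile(profile).values[perm]
        )

    def test_single_letter_groups_pass_through(self, rng):
        profile = random_profile(rng, 5)
        reduced = reduce_profile(profile)
        for col, aa in [(7, "C"), (8, "G"), (9, "P")]:
            np.testing.assert_array_equal(
                reduced.values[:, col], profile.scores[:, AA_ORDER.index(aa)]
            )


class TestRpssm:
    def test_constant_profile_gives_zero_vector(self):
        reduced = reduce_profile(make_profile(np.full((5, 20), 4.0)))
        assert not encode_rpssm(reduced).values.any()

    def test_two_row_hand_example(self):
        reduced = reduce_profile(make_profile([[0.0] * 20, [2.0] * 20]))
        fv = encode_rpssm(reduced).values
        np.testing.assert_allclose(fv[:100], 2.0)  # (1/2)(0-2)^2
        np.testing.assert_allclose(fv[100:], 1.0)  # variance of {0, 2}

    def test_length_110(self, rng):
        fv = encode_rpssm(reduce_profile(random_profile(rng, 17)))
        assert fv.values.shape == (110,)

    def test_row_reversal_invariance_at_length_two(self, rng):
        profile = random_profile(rng, 2)
        flipped = make_profile(profile.scores[::-1], sequence=profile.sequence[::-1])
        a = encode_rpssm(reduce_profile(profile)).values
        b = encode_rpssm(reduce_profile(flipped)).values
        # pseudo-dipeptide block transposes; dispersion block is equal —
        # compare as the symmetric objects they are
        np.testing.assert_allclose(
            a[:100].reshape(10, 10), b[:100].reshape(10, 10).T, atol=1e-12
        )
        np.testing.assert_allclose(a[100:], b[100:], atol=1e-12)

    def test_matches_naive_loops(self, rng):
        reduced = reduce_profile(random_profile(rng, 6))
        r, L = reduced.values, 6
        expected = np.empty(110)
        for s in range(10):
            for t in range(10):
                expected[s * 10 + t] = sum(
                    (r[i, s] - r[i + 1, t]) ** 2 for i in range(L - 1)
                ) / (2 * (L - 1))
        for s in range(10):
            expected[100 + s] = np.mean((r[:, s] - r[:, s].mean()) ** 2)
        np.testing.assert_allclose(encode_rpssm(reduced).values, expected, atol=1e-9)


def test_encoders_are_deterministic(rng):
    profile = random_profile(rng, 11)
    for encoder in (
        encode_fpssm,
        encode_pssm_dpc,
        lambda p: encode_rpssm(reduce_profile(p)),
    ):
        a, b = encoder(profile).values, encoder(profile).values
        assert np.array_equal(a, b)
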