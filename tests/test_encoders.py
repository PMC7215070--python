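"""Encoder correctness: worked-example golden values, dimension contracts,
and brute-force oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppistack import (
    PseAACParams,
    STANDARD_AA,
    ac_encode,
    ct_encode,
    ct_group,
    encoding_length,
    ld_ctd,
    ld_encode,
    ld_regions,
    pseaac_encode,
)
from ppistack.encoders import ct_index
from ppistack.properties import SEVEN_GROUPS, ac_property_table, pseaac_property_table

seqs = st.text(alphabet=STANDARD_AA, min_size=50, max_size=200)


from oracles import ac_oracle, pseaac_oracle


# ---------------------------------------------------------------------------
# conjoint triad


class TestConjointTriad:
    def test_group_mapping_follows_seven_group_table(self):
        assert ct_group("AGV") == "111"
        assert ct_group("DECK") == "7726"
        assert ct_group("") == ""

    def test_worked_example_triads(self):
        """A sequence grouping to '2762247' yields exactly the five sliding
        triads 276, 762, 622, 224, 247, each at frequency 1/5."""
        seq = "CDKCCME"  # groups: C=2, D=7, K=6, C=2, C=2, M=4, E=7
        assert ct_group(seq) == "2762247"
        vec = ct_encode(seq)
        nonzero = {
            (i // 49 + 1, (i // 7) % 7 + 1, i % 7 + 1)
            for i in np.flatnonzero(vec)
        }
        assert nonzero == {(2, 7, 6), (7, 6, 2), (6, 2, 2), (2, 2, 4), (2, 4, 7)}
        assert np.allclose(vec[vec > 0], 1 / 5)

    def test_homopolymer_single_bin(self):
        vec = ct_encode("A" * 10)
        assert vec[ct_index(1, 1, 1)] == 1.0
        assert vec.sum() == 1.0

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            ct_encode("AC")

    def test_strict_policy_reports_position(self):
        with pytest.raises(ValueError, match="position 3"):
            ct_group("ACXDE", policy="strict")

    @settings(max_examples=30, deadline=None)
    @given(seqs)
    def test_frequencies_sum_to_one(self, seq):
        vec = ct_encode(seq)
        assert vec.shape == (343,)
        assert np.all(vec >= 0)
        assert np.isclose(vec.sum(), 1.0)


# ---------------------------------------------------------------------------
# local descriptor


class TestLocalDescriptor:
    def test_region_lengths_l100(self):
        lens = [len(r) for r in ld_regions("A" * 100)]
        assert lens == [25, 25, 25, 25, 50, 50, 50, 75, 75, 75]

    def test_region_lengths_l8_exact_quarters(self):
        lens = [len(r) for r in ld_regions("A" * 8)]
        assert lens[:4] == [2, 2, 2, 2]

    def test_region_lengths_l26_floor_cuts(self):
        lens = [len(r) for r in ld_regions("A" * 26)]
        assert lens[:4] == [6, 7, 6, 7]

    def test_quarters_reconstruct_sequence(self, rng):
        seq = "".join(rng.choice(list(STANDARD_AA), size=61))
        regions = ld_regions(seq)
        assert "".join(regions[:4]) == seq

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="< 8"):
            ld_regions("A" * 7)

    def test_worked_example_composition_and_distribution(self):
        """The 26-residue worked region with group counts (9, 7, 10):
        composition 0.3461/0.2693/0.3846 and group-1 distribution
        0.0385/0.0769/0.1923/0.2692/0.3462 to the printed 3-4 decimals."""
        seq = "ACLACLCCLAALLCCCLALALAAALL"
        g = ct_group(seq)
        assert (g.count("1"), g.count("2"), g.count("3")) == (9, 7, 10)
        v = ld_ctd(seq)
        assert np.allclose(v[:3], [0.3461, 0.2693, 0.3846], atol=5e-4)
        d1 = v[7 + 21 : 7 + 21 + 5]
        assert np.allclose(d1, [0.0385, 0.0769, 0.1923, 0.2692, 0.3462], atol=5e-5)

    def test_worked_example_transitions(self):
        """A region realizing the worked example's stated group counts
        (9, 7, 10) and transition counts (2 for 1-2, 3 for 1-3, 6 for 2-3)
        reproduces the printed transition frequencies 0.08/0.12/0.24."""
        seq_groups = "111" "22" "33" "22" "33" "22" "33" "2" "111" "33" "111" "33"
        aa = {"1": "A", "2": "C", "3": "L"}
        seq = "".join(aa[c] for c in seq_groups)
        assert (len(seq), seq.count("A"), seq.count("C"), seq.count("L")) == (
            26, 9, 7, 10,
        )
        v = ld_ctd(seq)
        t = dict(zip(
            [(a, b) for a in range(1, 8) for b in range(a + 1, 8)],
            v[7:28],
        ))
        assert np.isclose(t[(1, 2)], 2 / 25)
        assert np.isclose(t[(1, 3)], 3 / 25)
        assert np.isclose(t[(2, 3)], 6 / 25)
        assert np.isclose(sum(t.values()), 11 / 25)

    def test_region_a_matches_direct_ctd(self, rng):
        seq = "".join(rng.choice(list(STANDARD_AA), size=83))
        full = ld_encode(seq)
        assert np.allclose(full[:63], ld_ctd(ld_regions(seq)[0]))

    def test_positional_distribution_variant(self):
        # homogeneous region: every quantile of group 1 sits at its own index
        v = ld_ctd("A" * 10, distribution="positional")
        assert np.allclose(v[7 + 21 : 7 + 21 + 5], [0.1, 0.3, 0.5, 0.8, 1.0])

    @settings(max_examples=20, deadline=None)
    @given(seqs)
    def test_length_and_composition_normalization(self, seq):
        vec = ld_encode(seq)
        assert vec.shape == (630,)
        for r in range(10):
            assert np.isclose(vec[r * 63 : r * 63 + 7].sum(), 1.0)


# ---------------------------------------------------------------------------
# autocovariance


class TestAutocovariance:
    def test_homopolymer_is_all_zero(self):
        assert np.allclose(ac_encode("A" * 100), 0.0)

    def test_min_length_error(self):
        with pytest.raises(ValueError, match="minimum length 31"):
            ac_encode("A" * 30)

    def test_matches_brute_force_oracle(self):
        seq = (STANDARD_AA * 4)[:62]
        assert np.allclose(ac_encode(seq, lg=5), ac_oracle(seq, 5), atol=1e-12)

    def test_translation_invariance_of_property_columns(self, rng):
        """Adding a constant to a property column leaves AC unchanged
        (the covariance is centered)."""
        seq = "".join(rng.choice(list(STANDARD_AA), size=80))
        shifted = ac_property_table(standardize=False)
        shifted.matrix = shifted.matrix + 5.0
        base = ac_property_table(standardize=False)
        assert np.allclose(
            ac_encode(seq, props=base, lg=10),
            ac_encode(seq, props=shifted, lg=10),
            atol=1e-9,
        )

    @settings(max_examples=20, deadline=None)
    @given(seqs)
    def test_output_length_is_constant(self, seq):
        assert ac_encode(seq, lg=30).shape == (210,)


# ---------------------------------------------------------------------------
# PseAAC


class TestPseAAC:
    def test_lambda_zero_reduces_to_frequencies(self):
        seq = "ACDEFGHIKLMNPQRSTVWYAAA" * 3
        vec = pseaac_encode(seq, PseAACParams(lambda_=0))
        assert vec.shape == (20,)
        assert np.isclose(vec.sum(), 1.0)
        assert np.isclose(vec[0], seq.count("A") / len(seq))

    def test_homopolymer_thetas_vanish(self):
        vec = pseaac_encode("G" * 60, PseAACParams(lambda_=5))
        assert np.allclose(vec[20:], 0.0)
        assert np.isclose(vec[STANDARD_AA.index("G")], 1.0)

    def test_matches_brute_force_oracle(self):
        seq = STANDARD_AA * 3
        for lam in (2, 7):
            assert np.allclose(
                pseaac_encode(seq, PseAACParams(lambda_=lam)),
                pseaac_oracle(seq, lam),
                atol=1e-12,
            )

    def test_vector_sums_to_one(self):
        seq = (STANDARD_AA[::-1] * 5)[:73]
        vec = pseaac_encode(seq, PseAACParams(lambda_=15))
        assert vec.shape == (35,)
        assert np.isclose(vec.sum(), 1.0)

    def test_lambda_too_large_raises(self):
        with pytest.raises(ValueError, match="lambda"):
            pseaac_encode("ACDEF" * 2, PseAACParams(lambda_=10))

    def test_squared_correlation_variant_is_nonnegative(self):
        seq = (STANDARD_AA * 4)[:70]
        vec = pseaac_encode(seq, PseAACParams(lambda_=5, correlation="squared"))
        assert np.all(vec >= 0)
        assert np.isclose(vec.sum(), 1.0)


# ---------------------------------------------------------------------------
# cross-cutting contracts


@pytest.mark.parametrize(
    "technique,expected",
    [("ac", 210), ("ct", 343), ("ld", 630), ("pseaac", 35)],
)
def test_encoding_length_contract(technique, expected):
    assert encoding_length(technique) == expected


def test_encoders_are_pure_functions(rng):
    seq = "".join(rng.choice(list(STANDARD_AA), size=90))
    for enc, kwargs in [
        (ac_encode, {}),
        (ct_encode, {}),
        (ld_encode, {}),
        (pseaac_encode, {}),
    ]:
        a, b = enc(seq, **kwargs), enc(seq, **kwargs)
        assert np.array_equal(a, b)


def test_group_map_partitions_alphabet():
    assert sorted(SEVEN_GROUPS) == sorted(STANDARD_AA)
    assert set(SEVEN_GROUPS.values()) == set(range(1, 8))
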