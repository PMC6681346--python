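"""Group sums, ratios and diversity against independent oracles.

The group-sum oracle is a hand-typed (compound, group) list summed by brute
force, kept deliberately separate from the registry tables it checks.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenotax.features import (
    group_sums,
    proxy_ratios,
    recovery_correct,
    relative_group_abundances,
    shannon_index,
)
from phenotax.registry_io import COMPOUNDS, SampleProfile
from .conftest import make_profile

# Hand-typed oracle of the six defining equations: 17 (compound, group)
# pairs, 4-hydroxybenzoic acid appearing under two groups.
ORACLE_PAIRS = [
    ("4-hydroxybenzaldehyde", "p_hydroxy"),
    ("4-hydroxyacetophenone", "p_hydroxy"),
    ("4-hydroxybenzoic acid", "p_hydroxy"),
    ("vanillin", "vanillyl"),
    ("4-hydroxy-3-methoxyacetophenone", "vanillyl"),
    ("vanillic acid", "vanillyl"),
    ("syringaldehyde", "syringyl"),
    ("3,5-dimethoxy-4-hydroxyacetophenone", "syringyl"),
    ("syringic acid", "syringyl"),
    ("p-coumaric acid", "coumaryl"),
    ("ferulic acid", "coumaryl"),
    ("benzoic acid", "benzoic"),
    ("salicylic acid", "benzoic"),
    ("phthalic acid", "benzoic"),
    ("3-hydroxybenzoic acid", "hydroxy_benzoic"),
    ("4-hydroxybenzoic acid", "hydroxy_benzoic"),
    ("3,5-dihydroxybenzoic acid", "hydroxy_benzoic"),
]


def oracle_group_sums(profile: SampleProfile) -> dict:
    sums = {g: 0.0 for g in ("p_hydroxy", "vanillyl", "syringyl", "coumaryl", "benzoic", "hydroxy_benzoic")}
    for compound, group in ORACLE_PAIRS:
        sums[group] += profile.contents[compound]
    return sums


contents_strategy = st.lists(
    st.floats(min_value=0.0, max_value=100.0, allow_nan=False), min_size=16, max_size=16
)


class TestGroupSums:
    def test_unit_profile_gives_member_counts(self):
        g = group_sums(make_profile(np.ones(16)))
        assert (g.p_hydroxy, g.vanillyl, g.syringyl, g.coumaryl, g.benzoic, g.hydroxy_benzoic) == (
            3.0, 3.0, 3.0, 2.0, 3.0, 3.0,
        )
        assert g.total_phenols == 16.0

    def test_all_zero_profile(self):
        g = group_sums(make_profile(np.zeros(16)))
        assert g.total_phenols == 0.0
        assert sum(g.as_dict().values()) == 0.0

    def test_matches_brute_force_oracle_on_random_profiles(self, rng):
        for _ in range(200):
            profile = make_profile(rng.uniform(0, 10, size=16))
            g = group_sums(profile)
            assert g.as_dict() == pytest.approx(oracle_group_sums(profile))

    @settings(max_examples=100, derandomize=True)
    @given(values=contents_strategy)
    def test_conservation_six_sums_minus_total_is_overlap(self, values):
        profile = make_profile(values)
        g = group_sums(profile)
        overlap = profile.contents["4-hydroxybenzoic acid"]
        assert sum(g.as_dict().values()) - g.total_phenols == pytest.approx(overlap, abs=1e-9)


class TestRelativeAbundances:
    def test_unit_profile_coumaryl_fraction(self):
        rel = relative_group_abundances(group_sums(make_profile(np.ones(16))))
        assert rel.coumaryl == pytest.approx(2.0 / 16.0)

    def test_single_group_profile(self):
        values = np.zeros(16)
        values[COMPOUNDS.index("p-coumaric acid")] = 1.0
        values[COMPOUNDS.index("ferulic acid")] = 2.0
        rel = relative_group_abundances(group_sums(make_profile(values)))
        assert rel.coumaryl == pytest.approx(1.0)
        assert rel.vanillyl == 0.0

    def test_fractions_sum_to_one_plus_overlap_share(self, rng):
        for _ in range(50):
            profile = make_profile(rng.uniform(0.01, 5, size=16))
            g = group_sums(profile)
            rel = relative_group_abundances(g)
            expected = (g.total_phenols + profile.contents["4-hydroxybenzoic acid"]) / g.total_phenols
            assert sum(rel.as_dict().values()) == pytest.approx(expected)

    def test_scale_invariance(self, rng):
        values = rng.uniform(0.01, 5, size=16)
        a = relative_group_abundances(group_sums(make_profile(values)))
        b = relative_group_abundances(group_sums(make_profile(values * 37.5)))
        assert a.as_dict() == pytest.approx(b.as_dict())

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            relative_group_abundances(group_sums(make_profile(np.zeros(16))))


class TestProxyRatios:
    def test_hand_arithmetic(self):
        values = np.zeros(16)
        values[COMPOUNDS.index("vanillin")] = 2.0
        values[COMPOUNDS.index("syringaldehyde")] = 3.0
        values[COMPOUNDS.index("p-coumaric acid")] = 1.0
        r = proxy_ratios(group_sums(make_profile(values)))
        assert r.s_over_v == pytest.approx(1.5)
        assert r.c_over_v == pytest.approx(0.5)

    def test_symmetric_and_zero_cases(self):
        values = np.zeros(16)
        values[COMPOUNDS.index("vanillin")] = 4.0
        values[COMPOUNDS.index("syringic acid")] = 4.0
        r = proxy_ratios(group_sums(make_profile(values)))
        assert r.s_over_v == pytest.approx(1.0)
        assert r.c_over_v == 0.0

    def test_zero_vanillyl_rejected(self):
        values = np.zeros(16)
        values[COMPOUNDS.index("syringic acid")] = 1.0
        with pytest.raises(ValueError, match="vanillyl"):
            proxy_ratios(group_sums(make_profile(values)))


class TestShannonIndex:
    def test_closed_forms(self):
        assert shannon_index(make_profile(np.ones(16))).h == pytest.approx(math.log(16), abs=1e-9)
        single = np.zeros(16)
        single[3] = 5.0
        assert shannon_index(make_profile(single)).h == 0.0
        two = np.zeros(16)
        two[0] = two[7] = 2.5
        assert shannon_index(make_profile(two)).h == pytest.approx(math.log(2), abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(values=contents_strategy, scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_bounds_and_scale_invariance(self, values, scale):
        if sum(values) <= 0:
            return
        h = shannon_index(make_profile(values)).h
        assert 0.0 <= h <= math.log(16) + 1e-12
        h_scaled = shannon_index(make_profile(np.array(values) * scale)).h
        assert h_scaled == pytest.approx(h, abs=1e-9)

    def test_permutation_invariance(self, rng):
        values = rng.uniform(0, 3, size=16)
        h = shannon_index(make_profile(values)).h
        h_perm = shannon_index(make_profile(rng.permutation(values))).h
        assert h_perm == pytest.approx(h, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            shannon_index(make_profile(np.zeros(16)))


class TestRecoveryCorrection:
    def test_simple_division(self):
        profile = make_profile(np.full(16, 10.0), recovery=0.5)
        corrected = recovery_correct(profile)
        assert all(v == pytest.approx(20.0) for v in corrected.contents.values())
        assert corrected.recovery == 1.0

    def test_recovery_one_is_identity(self):
        profile = make_profile(np.arange(16, dtype=float), recovery=1.0)
        corrected = recovery_correct(profile)
        assert corrected.contents == pytest.approx(profile.contents)

    def test_exactly_inverts_simulated_loss(self, rng):
        for _ in range(50):
            true_values = rng.uniform(0.01, 8, size=16)
            r = float(rng.uniform(0.3, 1.0))
            lossy = make_profile(true_values * r, recovery=r)
            restored = recovery_correct(lossy)
            for c, v in zip(make_profile(true_values).contents, true_values):
                assert restored.contents[c] == pytest.approx(v, abs=1e-12)

    def test_missing_recovery_rejected(self):
        with pytest.raises(ValueError, match="no recovery"):
            recovery_correct(make_profile(np.ones(16)))
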