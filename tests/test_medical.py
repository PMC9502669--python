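"""Medical compatibility model: criterion scores, gate, and edge weights."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kepsolve import (
    DEFAULT_CATALOGUE,
    ValidationError,
    WeightConfig,
    abo_compatible,
    abo_score,
    age_score,
    edge_weight,
    hla_crossmatch,
    hla_mismatch_count,
    hla_mismatch_score,
    sex_score,
    weight_score,
)
from kepsolve.hla import LOCUS_GROUPS

from conftest import make_donor, make_recipient


class TestCatalogue:
    def test_default_group_sizes(self):
        sizes = {g: len(DEFAULT_CATALOGUE.groups[g]) for g in LOCUS_GROUPS}
        assert sizes == {"A": 13, "B": 24, "DR": 8, "DQ": 5}
        assert DEFAULT_CATALOGUE.total_size == 50

    def test_codes_unique(self):
        codes = DEFAULT_CATALOGUE.all_codes
        assert len(set(codes)) == len(codes)

    def test_unknown_code_named_in_error(self):
        with pytest.raises(ValidationError, match="A99"):
            DEFAULT_CATALOGUE.validate_codes(["A23", "A99"])


class TestCrossmatch:
    @pytest.mark.parametrize(
        "antigens, antibodies, expected",
        [
            ({"A24"}, {"A24"}, False),                      # direct hit
            ({"A23", "B44", "DR11", "DQ5"}, set(), True),   # empty panel
            ({"A23", "B44"}, {"B45", "DQ9"}, True),         # no overlap
            ({"A23", "B44"}, {"B44"}, False),
        ],
    )
    def test_examples(self, antigens, antibodies, expected):
        assert hla_crossmatch(antigens, antibodies) is expected

    def test_unknown_code_rejected(self):
        with pytest.raises(ValidationError, match="A99"):
            hla_crossmatch({"A99"}, set())

    def test_agrees_with_catalogue_scan_on_random_profiles(self, rng):
        """Set-intersection result must equal the SIMD-style full scan over
        all catalogue entries (per-antigen hits, OR-reduced, inverted)."""
        codes = DEFAULT_CATALOGUE.all_codes
        for _ in range(1000):
            antigens = frozenset(rng.choice(codes, size=rng.integers(0, 9)))
            antibodies = frozenset(rng.choice(codes, size=rng.integers(0, 12)))
            hits = [(c in antigens) and (c in antibodies) for c in codes]
            scan = not any(hits)
            assert hla_crossmatch(antigens, antibodies) == scan


class TestMismatch:
    def test_subset_gives_zero(self):
        donor = {"A": {"A23"}, "B": {"B44"}, "DR": set(), "DQ": set()}
        recip = {"A": {"A23", "A24"}, "B": {"B44"}, "DR": {"DR11"}, "DQ": {"DQ5"}}
        assert hla_mismatch_count(donor, recip) == 0

    def test_per_group_difference(self):
        donor = {"A": {"A23", "A24"}, "B": set(), "DR": set(), "DQ": set()}
        recip = {"A": {"A25", "A26"}, "B": set(), "DR": set(), "DQ": set()}
        assert hla_mismatch_count(donor, recip) == 2

    def test_cap_two_per_group_max_eight(self):
        donor = {"A": {"A23", "A24"}, "B": {"B44", "B45"},
                 "DR": {"DR11", "DR12"}, "DQ": {"DQ5", "DQ6"}}
        recip = {"A": {"A66"}, "B": {"B77"}, "DR": {"DR18"}, "DQ": {"DQ9"}}
        assert hla_mismatch_count(donor, recip) == 8

    @pytest.mark.parametrize("count, expected", [(0, 3), (1, 2), (2, 2),
                                                 (3, 1), (4, 1), (5, 0),
                                                 (6, 0), (7, 0), (8, 0)])
    def test_bin_scores(self, count, expected):
        assert hla_mismatch_score(count) == expected

    def test_score_monotone_nonincreasing(self):
        scores = [hla_mismatch_score(c) for c in range(9)]
        assert scores == sorted(scores, reverse=True)

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            hla_mismatch_score(9)


class TestDemographicScores:
    @pytest.mark.parametrize(
        "donor, recip, expected",
        [("O", "AB", True), ("O", "O", True), ("A", "O", False),
         ("AB", "AB", True), ("B", "AB", True), ("AB", "A", False)],
    )
    def test_abo_table(self, donor, recip, expected):
        assert abo_compatible(donor, recip) is expected

    def test_abo_score_is_penalty_not_exclusion(self):
        assert abo_score("O", "A") == 1
        assert abo_score("B", "A") == 0
        big = WeightConfig(scores_abo=(5, 0))
        assert abo_score("O", "O", big) == 5

    @pytest.mark.parametrize("d_age, r_age, expected",
                             [(40, 40, 2), (70, 70, 2), (40, 70, 1), (70, 40, 0),
                              (55, 55, 2), (54, 55, 1), (55, 54, 0)])
    def test_age_categories(self, d_age, r_age, expected):
        """Exactly 55 counts as senior; intra-category pairings score best."""
        assert age_score(d_age, r_age) == expected

    @pytest.mark.parametrize("d_sex, r_sex, expected",
                             [("M", "M", 2), ("F", "F", 2), ("M", "F", 1), ("F", "M", 0)])
    def test_sex_pairings(self, d_sex, r_sex, expected):
        assert sex_score(d_sex, r_sex) == expected

    @pytest.mark.parametrize("d_wt, r_wt, expected",
                             [(80, 70, 1), (60, 90, 0), (75, 75, 1)])
    def test_weight_rule(self, d_wt, r_wt, expected):
        assert weight_score(d_wt, r_wt) == expected


class TestEdgeWeight:
    def test_crossmatch_gates_to_zero(self, cfg):
        donor = make_donor(a=("A24",))
        recip = make_recipient(antibodies=("A24",))
        assert edge_weight(donor, recip, cfg) == 0

    def test_baseline_only(self):
        """All criterion scores zeroed out: only the baseline remains."""
        cfg = WeightConfig(
            bins_hla=(0, 0, 0, 0), scores_abo=(0, 0), scores_age=(0, 0, 0),
            scores_sex=(0, 0, 0), scores_weight=(0, 0), baseline=1,
        )
        assert edge_weight(make_donor(), make_recipient(), cfg) == 1

    def test_dot_product(self):
        """Scores (3,1,2,2,1) with unit weights and no baseline sum to 9."""
        cfg = WeightConfig(baseline=0)
        donor = make_donor(a=("A23",))   # 0 mismatches -> 3; O->O 1; 40/40 2; M/M 2; 80/80 1
        recip = make_recipient(a=("A23",))
        assert edge_weight(donor, recip, cfg) == 9

    def test_positive_whenever_compatible_with_baseline(self, cfg):
        assert edge_weight(make_donor(), make_recipient(), cfg) > 0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        w=st.lists(st.integers(0, 5), min_size=5, max_size=5),
        baseline=st.integers(0, 3),
        d_age=st.integers(20, 80), r_age=st.integers(20, 80),
    )
    def test_monotone_in_weights(self, w, baseline, d_age, r_age):
        """Raising any criterion weight never lowers a compatible edge."""
        names = ("hla_quality", "abo", "age", "sex", "weight")
        donor = make_donor(age=d_age)
        recip = make_recipient(age=r_age)
        base_cfg = WeightConfig(w=dict(zip(names, w)), baseline=baseline)
        base = edge_weight(donor, recip, base_cfg)
        for i, name in enumerate(names):
            bumped = list(w)
            bumped[i] += 1
            up_cfg = WeightConfig(w=dict(zip(names, bumped)), baseline=baseline)
            assert edge_weight(donor, recip, up_cfg) >= base


class TestProfileValidation:
    def test_three_antigens_per_group_rejected(self):
        with pytest.raises(ValidationError, match="at most two"):
            make_donor(a=("A23", "A24", "A25"))

    def test_wrong_group_membership_rejected(self):
        with pytest.raises(ValidationError, match="B44"):
            make_donor(a=("B44",))

    def test_invalid_abo(self):
        with pytest.raises(ValidationError, match="ABO"):
            make_donor(abo="C")

    def test_config_ordering_enforced(self):
        with pytest.raises(ValidationError):
            WeightConfig(bins_hla=(0, 1, 2, 3))
        with pytest.raises(ValidationError):
            WeightConfig(scores_age=(0, 1, 2))
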