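"""Exact DP core: pattern counts, start matrices, coverage profiles, weighting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fragspace import (
    CoverageKind,
    ModelValidationError,
    PatternSpaceModel,
    count_patterns,
    coverage_vector,
    enumerate_patterns,
    expected_profile,
    log_pattern_count_table,
    normalize,
    pattern_count_table,
    per_length_fragment_counts,
    profile_from_patterns,
    start_matrix,
    weighted_pattern_mass,
    weighted_profile,
)

model_strategy = st.builds(
    lambda T, lengths, R: PatternSpaceModel(T, sorted(set(lengths)), read_length=R),
    st.integers(1, 16),
    st.lists(st.sampled_from([2, 3, 4, 5]), min_size=1, max_size=3),
    st.integers(1, 3),
)


class TestCountPatterns:
    @pytest.mark.parametrize(
        "T, lengths, expected",
        [
            (2, (2,), 1),       # single fragment exactly fills the transcript
            (10, (4,), 7),
            (5, (3, 4), 5),
            (10, (3, 4), 33),
            (17, (1,), 1),      # length-1 fragments tile every position
            (1, (2,), 1),       # transcript shorter than any fragment: empty pattern
        ],
    )
    def test_pinned_counts(self, T, lengths, expected):
        assert count_patterns(PatternSpaceModel(T, lengths)) == expected

    @given(model_strategy)
    def test_count_matches_enumeration(self, model):
        assert count_patterns(model) == len(enumerate_patterns(model))

    def test_count_is_exact_integer_at_large_T(self):
        fp = count_patterns(PatternSpaceModel(3000, [2]))
        assert isinstance(fp, int) and fp > 10**300  # far beyond float range

    def test_base_cases_of_table(self):
        table = pattern_count_table(10, (4,))
        assert table[:5] == [1, 1, 1, 1, 1]  # FP(l) = 1 for 0 <= l <= F_1

    def test_invalid_models_rejected(self):
        with pytest.raises(ModelValidationError):
            PatternSpaceModel(0, [2])
        with pytest.raises(ModelValidationError):
            PatternSpaceModel(10, [])
        with pytest.raises(ModelValidationError):
            PatternSpaceModel(10, [3, 3])  # duplicates rejected
        with pytest.raises(ModelValidationError):
            PatternSpaceModel(10, [4, 3])  # not increasing


class TestStartMatrix:
    def test_single_length_row(self):
        mat = start_matrix(PatternSpaceModel(5, [2]))
        assert list(mat.values[0]) == [2, 1, 1, 2, 0]

    def test_two_length_rows(self):
        mat = start_matrix(PatternSpaceModel(5, [3, 4]))
        assert list(mat.row(3)) == [1, 1, 1, 0, 0]
        assert list(mat.row(4)) == [1, 1, 0, 0, 0]

    def test_T_equals_F_single_pattern(self):
        mat = start_matrix(PatternSpaceModel(7, [7], weights={7: 0.5}))
        assert mat.values[0, 0] == 0.5
        assert np.all(mat.values[0, 1:] == 0)

    @given(model_strategy)
    def test_rows_zero_where_fragment_overhangs(self, model):
        mat = start_matrix(model)
        for j, F in enumerate(model.lengths):
            tail = mat.values[j, max(model.T - F + 1, 0):]
            assert all(v == 0 for v in tail)

    @given(model_strategy)
    def test_row_sums_give_spp(self, model):
        mat = start_matrix(model)
        spp = expected_profile(model, CoverageKind.START_POINT)
        assert list(mat.spp_values()) == list(spp.values)


class TestExpectedProfile:
    def test_spp_T4_F2(self):
        prof = expected_profile(PatternSpaceModel(4, [2]), CoverageKind.START_POINT)
        assert list(prof.values) == [1, 1, 1, 0]

    def test_fcp_T5_F2(self):
        prof = expected_profile(PatternSpaceModel(5, [2]), CoverageKind.FRAGMENT)
        assert list(prof.values) == [2, 3, 2, 3, 2]

    def test_fcp_constant_when_F_equals_T(self):
        prof = expected_profile(PatternSpaceModel(9, [9]), CoverageKind.FRAGMENT)
        assert len(set(prof.values)) == 1

    def test_rcp_equals_fcp_at_half_read_ratio(self):
        model = PatternSpaceModel(1000, [200], read_length=100)
        rcp = expected_profile(model, CoverageKind.READ)
        fcp = expected_profile(model, CoverageKind.FRAGMENT)
        assert np.array_equal(rcp.values, fcp.values)

    def test_rcp_doubles_fcp_when_reads_cover_fragment(self):
        model = PatternSpaceModel(12, [4], read_length=4)
        rcp = expected_profile(model, CoverageKind.READ)
        fcp = expected_profile(model, CoverageKind.FRAGMENT)
        assert list(rcp.values) == [2 * v for v in fcp.values]

    def test_transcript_shorter_than_fragment_warns_zero(self):
        with pytest.warns(RuntimeWarning):
            prof = expected_profile(PatternSpaceModel(3, [5]), CoverageKind.FRAGMENT)
        assert all(v == 0 for v in prof.values)

    def test_spp_uniform_for_unit_fragments(self):
        prof = expected_profile(PatternSpaceModel(50, [1]), CoverageKind.START_POINT)
        assert len(set(prof.values)) == 1

    @pytest.mark.parametrize("F", [501, 700, 900])
    def test_spp_uniform_over_potential_starts_for_large_ratio(self, F):
        prof = expected_profile(PatternSpaceModel(1000, [F]), CoverageKind.START_POINT)
        head = prof.values[: 1000 - F + 1]
        tail = prof.values[1000 - F + 1:]
        assert len(set(head)) == 1 and all(v == 0 for v in tail)

    @given(model_strategy)
    def test_fcp_reversal_symmetric(self, model):
        fcp = expected_profile(model, CoverageKind.FRAGMENT)
        assert list(fcp.values) == list(fcp.values[::-1])

    @given(model_strategy)
    def test_spp_sum_equals_total_fragment_count(self, model):
        spp = expected_profile(model, CoverageKind.START_POINT)
        counts = per_length_fragment_counts(model)
        assert spp.values.sum() == sum(counts.values())

    def test_read_vector_clipping(self):
        assert list(coverage_vector(CoverageKind.READ, 4, 3)) == [1, 2, 2, 1]
        assert list(coverage_vector(CoverageKind.READ, 3, 5)) == [2, 2, 2]
        assert list(coverage_vector(CoverageKind.READ, 6, 2)) == [1, 1, 0, 0, 1, 1]


class TestPerLengthCounts:
    @pytest.mark.parametrize(
        "T, lengths, expected",
        [
            (5, (2,), {2: 6}),
            (5, (3, 4), {3: 3, 4: 2}),
            (6, (6,), {6: 1}),
        ],
    )
    def test_pinned_counts(self, T, lengths, expected):
        assert per_length_fragment_counts(PatternSpaceModel(T, lengths)) == expected


class TestWeighting:
    def test_unit_weights_reproduce_unweighted(self):
        base = PatternSpaceModel(12, [3, 5], read_length=2)
        weighted = base.with_weights({3: 1.0, 5: 1.0})
        for kind in CoverageKind:
            ref = expected_profile(base, kind).as_float()
            got = weighted_profile(weighted, kind).as_float()
            assert np.array_equal(ref, got)

    def test_zero_weight_silences_length(self):
        model = PatternSpaceModel(5, [3, 4], weights={3: 0.0, 4: 1.0})
        prof = weighted_profile(model, CoverageKind.START_POINT)
        assert list(prof.values) == [1.0, 1.0, 0.0, 0.0, 0.0]

    def test_uniform_weights_scale_profile(self):
        base = PatternSpaceModel(5, [3, 4])
        scaled = base.with_weights({3: 2.0, 4: 2.0})
        ref = expected_profile(base, CoverageKind.START_POINT).as_float()
        got = weighted_profile(scaled, CoverageKind.START_POINT).as_float()
        assert np.array_equal(got, 2.0 * ref)

    def test_negative_weight_rejected(self):
        with pytest.raises(ModelValidationError):
            PatternSpaceModel(5, [3], weights={3: -0.1})

    def test_pattern_mode_matches_oracle(self):
        model = PatternSpaceModel(9, [2, 3], weights={2: 0.3, 3: 1.7},
                                  weight_mode="pattern")
        pats = enumerate_patterns(model)
        for kind in CoverageKind:
            oracle = profile_from_patterns(pats, kind, model).as_float()
            got = weighted_profile(model, kind).as_float()
            np.testing.assert_allclose(got, oracle, rtol=1e-12)

    def test_contribution_mode_matches_oracle(self):
        model = PatternSpaceModel(9, [2, 3], weights={2: 0.3, 3: 1.7})
        pats = enumerate_patterns(model)
        for kind in CoverageKind:
            oracle = profile_from_patterns(pats, kind, model).as_float()
            got = weighted_profile(model, kind).as_float()
            np.testing.assert_allclose(got, oracle, rtol=1e-12)


class TestPatternMass:
    def test_unit_weights_equal_count(self):
        model = PatternSpaceModel(10, [4], weights={4: 1.0})
        assert weighted_pattern_mass(model) == count_patterns(model) == 7

    def test_single_pattern_mass_is_weight(self):
        model = PatternSpaceModel(6, [6], weights={6: 0.5})
        assert weighted_pattern_mass(model) == 0.5

    def test_all_zero_weights(self):
        model = PatternSpaceModel(10, [4], weights={4: 0.0})
        assert weighted_pattern_mass(model) == 0.0

    def test_mass_matches_oracle_product_sum(self):
        model = PatternSpaceModel(11, [2, 4], weights={2: 0.4, 4: 2.5})
        total = 0.0
        for pat in enumerate_patterns(model):
            mass = 1.0
            for _, F in pat:
                mass *= model.weight_map()[F]
            total += mass
        assert weighted_pattern_mass(model) == pytest.approx(total, rel=1e-12)


class TestNormalize:
    def test_sum_normalization(self):
        prof = expected_profile(PatternSpaceModel(5, [2]), CoverageKind.START_POINT)
        norm = normalize(prof)
        from fractions import Fraction

        assert list(norm.values) == [Fraction(1, 3), Fraction(1, 6), Fraction(1, 6),
                                     Fraction(1, 3), 0]
        assert sum(norm.values) == 1

    def test_idempotent(self):
        prof = expected_profile(PatternSpaceModel(8, [3]), CoverageKind.FRAGMENT)
        once = normalize(prof)
        twice = normalize(once)
        assert list(once.values) == list(twice.values)

    def test_zero_profile_warns_and_stays(self):
        with pytest.warns(RuntimeWarning):
            prof = expected_profile(PatternSpaceModel(2, [5]), CoverageKind.FRAGMENT)
        with pytest.warns(RuntimeWarning):
            norm = normalize(prof)
        assert not norm.normalized
        assert all(v == 0 for v in norm.values)


class TestFloatPath:
    @pytest.mark.parametrize("lengths", [(2,), (3,), (2, 5), (3, 4, 7)])
    def test_log_table_matches_exact(self, lengths):
        for T in range(1, 61):
            exact = pattern_count_table(T, lengths)
            logs = log_pattern_count_table(T, lengths)
            approx = np.exp(logs)
            rel = np.abs(approx - np.array([float(v) for v in exact])) / np.maximum(
                [float(v) for v in exact], 1.0
            )
            assert rel.max() <= 1e-9

    def test_float_profile_matches_exact(self):
        model = PatternSpaceModel(40, [3, 5], read_length=2)
        for kind in CoverageKind:
            exact = expected_profile(model, kind).as_float()
            approx = expected_profile(model, kind, method="float").as_float()
            np.testing.assert_allclose(approx, exact, rtol=1e-9)
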