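"""Aggregation, normalization and group-comparison statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import mann_whitney_exact_enumeration, welch_t_closed_form
from skinquant import (
    ImageRecord,
    aggregate_mouse,
    compare_groups,
    normalize_migration,
)
from skinquant._errors import InsufficientDataError, ValidationError


def _records(counts, mouse_id="m1"):
    return [ImageRecord(f"f{i}", mouse_id, nf, nm)
            for i, (nm, nf) in enumerate(counts)]


class TestAggregateMouse:
    def test_pooled_ratio(self):
        mm = aggregate_mouse(_records([(10, 320), (6, 320)]))
        assert mm.migration_rate == pytest.approx(16 / 640)
        assert mm.total_follicles == 640 and mm.total_mcsc == 16

    def test_zero_melanocytes(self):
        assert aggregate_mouse(_records([(0, 320)])).migration_rate == 0.0

    def test_follicle_floor_flag(self):
        assert "below_follicle_floor" in aggregate_mouse(
            _records([(1, 320)])).flags
        ok = aggregate_mouse(_records([(1, 320)] * 20))
        assert ok.total_follicles == 6400 and not ok.flags

    def test_mixed_mouse_ids_rejected(self):
        recs = _records([(1, 320)]) + _records([(1, 320)], mouse_id="m2")
        with pytest.raises(ValidationError):
            aggregate_mouse(recs)

    def test_zero_follicles_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_mouse(_records([(0, 0)]))

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 400)),
                    min_size=1, max_size=15))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_pooled_rate_is_follicle_weighted_mean(self, counts):
        """Pooling counts equals weighting per-field rates by follicles."""
        mm = aggregate_mouse(_records(counts))
        weighted = sum(nm for nm, _ in counts) / sum(nf for _, nf in counts)
        per_field = np.array([nm / nf for nm, nf in counts])
        weights = np.array([nf for _, nf in counts], float)
        assert mm.migration_rate == pytest.approx(weighted)
        assert mm.migration_rate == pytest.approx(
            float(np.average(per_field, weights=weights)))

    @given(st.integers(1, 20))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_rate_scale_invariance(self, k):
        base = aggregate_mouse(_records([(3, 100), (5, 200)]))
        scaled = aggregate_mouse(_records([(3 * k, 100 * k), (5 * k, 200 * k)]))
        assert scaled.migration_rate == pytest.approx(base.migration_rate)


class TestNormalize:
    def test_littermate_control(self):
        mm = aggregate_mouse(_records([(4, 200)]))  # rate 0.02
        res = normalize_migration(mm, 0.01, "littermate_control")
        assert res.normalized_rate == pytest.approx(2.0)

    def test_self_normalization_is_one(self):
        mm = aggregate_mouse(_records([(7, 300)]))
        res = normalize_migration(mm, mm.migration_rate, "littermate_control")
        assert res.normalized_rate == pytest.approx(1.0)

    def test_cox2_scheme_composes_with_area_ratio(self):
        from skinquant import area_ratio, generate_section_pair
        stain, dapi, truth = generate_section_pair(256, 256, 0.30, 0.40,
                                                   seed=6, noise_sd=0.0)
        cox2_level = area_ratio(stain, dapi).ratio
        # noise-free: the measured level equals the painted truth ratio
        assert cox2_level == pytest.approx(
            truth.stain_mask_area_px / truth.dapi_mask_area_px)
        mm = aggregate_mouse(_records([(3, 200)]))  # rate 0.015
        res = normalize_migration(mm, cox2_level, "cox2")
        assert res.normalized_rate == pytest.approx(0.015 / cox2_level)

    def test_nonpositive_normalizer_rejected(self):
        mm = aggregate_mouse(_records([(1, 100)]))
        for bad in (0.0, -1.0, float("nan")):
            with pytest.raises(ValidationError):
                normalize_migration(mm, bad, "cox2")


class TestCompareGroups:
    def test_identical_samples_give_p_one(self):
        a = [0.1, 0.2, 0.3]
        res = compare_groups(a, list(a), "welch_t")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_welch_matches_closed_form_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(3, 10))
            b = rng.normal(0.5, 2, rng.integers(3, 10))
            res = compare_groups(a, b, "welch_t")
            t, p = welch_t_closed_form(a, b)
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_mann_whitney_matches_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(2, 7))
            b = rng.normal(1, 1, rng.integers(2, 7))
            res = compare_groups(a, b, "mann_whitney")
            assert res.p_value == pytest.approx(
                mann_whitney_exact_enumeration(a, b), abs=1e-12)

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(14)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 8)
        for test in ("welch_t", "mann_whitney"):
            r1, r2 = compare_groups(a, b, test), compare_groups(b, a, test)
            assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        r1 = compare_groups(a, b, "welch_t")
        r2 = compare_groups(b, a, "welch_t")
        assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-12)

    def test_paired_constant_shift_flags_degenerate_variance(self):
        res = compare_groups([1, 2, 3, 4], [2, 3, 4, 5], "paired_t")
        assert "degenerate_variance" in res.flags
        assert np.isnan(res.p_value)

    def test_paired_ids_realign_group_b(self):
        a, b = [1.0, 2.0, 3.0], [30.0, 10.0, 20.0]
        res = compare_groups(a, b, "paired_t",
                             paired_ids=(["x", "y", "z"], ["z", "x", "y"]))
        aligned = compare_groups(a, [10.0, 20.0, 30.0], "paired_t")
        assert res.p_value == pytest.approx(aligned.p_value)

    def test_sem_reported(self):
        res = compare_groups([1.0, 2.0, 3.0], [4.0, 6.0], "welch_t")
        assert res.group_sems[0] == pytest.approx(np.std([1, 2, 3], ddof=1)
                                                  / np.sqrt(3))

    def test_small_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1.0], [2.0, 3.0], "welch_t")
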