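"""Somatic comparison: exact-test oracle, printed filters, inversion."""

import math

import numpy as np
import pytest

from editscreen.somatic_compare import (
    SomaticCall,
    SomaticThresholds,
    call_somatic,
    coverage_concordance,
    coverage_dropout_check,
    filter_normal_vaf,
    inversion_control,
    somatic_p_value,
    subtract_background_vaf,
    wgs_filter,
)
from editscreen.variant_model import SampleRecord, VariantCall, VariantKey


def hypergeom_tail(a, b, c, d):
    """Independent oracle: P(X >= a), X ~ Hypergeom over the 2x2 margins."""
    n_tumor, n_alt, total = a + b, a + c, a + b + c + d
    num = 0
    for k in range(a, min(n_alt, n_tumor) + 1):
        num += math.comb(n_alt, k) * math.comb(total - n_alt, n_tumor - k)
    return num / math.comb(total, n_tumor)


def test_exact_test_equals_hypergeometric_enumeration():
    """All 2x2 tables with margins <= 30 agree with the enumeration oracle."""
    for tumor_depth in (1, 7, 30):
        for normal_depth in (1, 8, 30):
            for a in range(tumor_depth + 1):
                for c in range(normal_depth + 1):
                    p = somatic_p_value(a, tumor_depth, c, normal_depth)
                    expect = hypergeom_tail(
                        a, tumor_depth - a, c, normal_depth - c
                    )
                    assert p == pytest.approx(expect, rel=1e-9, abs=1e-12)


def _sample(variants, sample_id="T", mec=1000.0):
    return SampleRecord(sample_id, "D1", "AAVS1", 10, 1, variants, mec)


def _mock(variants, mec=1000.0):
    return SampleRecord("N", "D1", "MOCK", 10, 1, variants, mec)


class TestCallSomatic:
    def test_equal_zero_counts_not_somatic(self):
        tumor = _sample([VariantCall("chr1", 5, "A", "G", 0, 100)])
        calls = call_somatic(tumor, _mock([VariantCall("chr1", 5, "A", "G", 0, 100)]))
        assert calls == []

    def test_strong_tumor_signal_called(self):
        tumor = _sample([VariantCall("chr1", 5, "A", "G", 50, 100)])
        normal = _mock([VariantCall("chr1", 5, "A", "G", 0, 100)])
        calls = call_somatic(tumor, normal)
        assert len(calls) == 1
        assert calls[0].p_value < 1e-10

    def test_equal_vaf_never_somatic(self):
        tumor = _sample([VariantCall("chr1", 5, "A", "G", 3, 1000)])
        normal = _mock([VariantCall("chr1", 5, "A", "G", 3, 1000)])
        assert call_somatic(tumor, normal) == []

    def test_absent_site_backfilled_at_mec(self):
        tumor = _sample([VariantCall("chr1", 5, "A", "G", 50, 100)], mec=100)
        calls = call_somatic(tumor, _mock([], mec=250))
        assert calls[0].normal_alt == 0 and calls[0].normal_depth == 250

    def test_absent_site_uses_depth_track_when_given(self):
        tumor = _sample([VariantCall("chr1", 5, "A", "G", 50, 100)])
        calls = call_somatic(
            tumor, _mock([]), normal_depth_track={("chr1", 5): 77}
        )
        assert calls[0].normal_depth == 77


class TestPrintedFilters:
    def _call(self, t_alt, t_depth, n_alt, n_depth):
        return SomaticCall(
            key=VariantKey("chr1", 1, "A", "G"),
            tumor_alt=t_alt,
            tumor_depth=t_depth,
            normal_alt=n_alt,
            normal_depth=n_depth,
            p_value=0.001,
        )

    def test_normal_vaf_boundary_exactly_as_printed(self):
        """Normal VAF 0.01 retained; anything above removed."""
        at_boundary = self._call(100, 1000, 10, 1000)  # normal VAF 0.010
        above = self._call(100, 1000, 20, 1000)  # 0.020
        zero = self._call(100, 1000, 0, 1000)
        kept = filter_normal_vaf([at_boundary, above, zero], 0.01)
        assert kept == [at_boundary, zero]

    def test_wgs_tumor_vaf_floor_and_normal_ceiling(self):
        below_floor = self._call(1, 2000, 0, 1000)  # tumor VAF 0.0005
        noisy_normal = self._call(400, 2000, 20, 1000)  # normal VAF 0.02
        clean = self._call(400, 2000, 0, 1000)
        kept = wgs_filter([below_floor, noisy_normal, clean])
        assert kept == [clean]

    def test_background_subtraction_floors_at_zero(self):
        assert self._call(500, 1000, 500, 1000).adjusted_vaf == 0.0
        assert self._call(500, 1000, 0, 1000).adjusted_vaf == 0.5
        assert self._call(10, 1000, 20, 1000).adjusted_vaf == 0.0
        # membership unchanged by subtraction: counts commute with wgs_filter
        calls = [self._call(400, 2000, 0, 1000), self._call(1, 2000, 0, 1000)]
        assert len(wgs_filter(subtract_background_vaf(calls))) == len(
            wgs_filter(calls)
        )


class TestInversionControl:
    def test_identical_samples_symmetric_zero(self):
        variants = [VariantCall("chr1", 5, "A", "G", 10, 1000)]
        report = inversion_control(_sample(variants), _mock(list(variants)))
        assert report.forward_count == report.reverse_count == 0
        assert report.ratio == 1.0

    def test_planted_edit_appears_forward_only(self):
        edit = VariantCall("chr1", 50, "AT", "A", 300, 1000)
        shared = VariantCall("chr1", 5, "A", "G", 500, 1000)
        tumor = _sample([shared, edit])
        normal = _mock([shared])
        report = inversion_control(tumor, normal)
        assert edit.key in {c.key for c in report.forward_calls}
        assert edit.key not in {c.key for c in report.reverse_calls}


class TestCoverage:
    def test_identical_tracks_perfectly_correlated(self):
        track = np.arange(100, 200).astype(float)
        assert coverage_concordance(track, track) == pytest.approx(1.0)
        assert coverage_concordance(track, -track + 300) == pytest.approx(-1.0)

    def test_independent_tracks_uncorrelated(self):
        rng = np.random.default_rng(0)
        a, b = rng.poisson(100, 1000), rng.poisson(100, 1000)
        assert abs(coverage_concordance(a, b)) < 0.1

    def test_zero_variance_returns_nan_sentinel(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            r = coverage_concordance([5.0] * 10, list(range(10)))
        assert math.isnan(r)

    def test_dropout_ratio_arithmetic(self):
        flat = np.full(1000, 100.0)
        ratio, flagged = coverage_dropout_check(flat, 500, 50)
        assert ratio == pytest.approx(1.0) and not flagged
        zeroed = flat.copy()
        zeroed[449:550] = 0
        ratio, flagged = coverage_dropout_check(zeroed, 500, 50)
        assert ratio == 0.0 and flagged
        at60 = flat.copy()
        at60[449:550] = 60.0
        ratio, flagged = coverage_dropout_check(at60, 500, 50)
        assert ratio == pytest.approx(0.6) and not flagged

    def test_window_outside_track_rejected(self):
        with pytest.raises(ValueError):
            coverage_dropout_check(np.full(100, 50.0), 10, 50)
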