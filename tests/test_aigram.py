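"""AI-Gram STFT processing: region gain, conflicting-band removal, overlap rule."""

import numpy as np
import pytest

import dsirlab as d
from dsirlab.aigram import stft_reconstruct
from dsirlab.core import TFRegion


def db_change(after, before, region):
    return 20 * np.log10(d.region_rms(after, region) / d.region_rms(before, region))


class TestRegionTable:
    def test_ka_and_sa_entries(self):
        table = d.load_region_table()
        assert len(table) == 14
        ka_target, ka_conf = table["ka"]
        assert (ka_target.f_lo, ka_target.f_hi, ka_target.t_lo, ka_target.t_hi) == (1.4, 2.0, 30, 50)
        assert ka_conf == (5.0, 7.8)
        sa_target, sa_conf = table["sa"]
        assert (sa_target.f_lo, sa_target.f_hi, sa_target.t_lo, sa_target.t_hi) == (3.9, 7.8, 80, 115)
        assert sa_conf == (5.4, 7.8)

    def test_unknown_label_raises(self, ka_token):
        with pytest.raises(KeyError):
            d.process_condition(ka_token, "xa", "target")


class TestReconstruction:
    def test_roundtrip_residual_below_minus_60_db(self, ka_token):
        rec = stft_reconstruct(ka_token)
        residual = np.linalg.norm(rec.samples - ka_token.samples)
        assert 20 * np.log10(residual / np.linalg.norm(ka_token.samples)) <= -60

    def test_zero_gain_is_identity_within_tolerance(self, ka_token, registry):
        out = d.apply_region_gain(ka_token, registry["ka"].target_region, 0.0)
        residual = np.linalg.norm(out.samples - ka_token.samples)
        assert 20 * np.log10(residual / np.linalg.norm(ka_token.samples)) <= -60


class TestRegionGain:
    def test_target_gain_six_db_in_region(self, ka_token, registry):
        region = registry["ka"].target_region
        out = d.apply_region_gain(ka_token, region, 6.0)
        assert db_change(out, ka_token, region) == pytest.approx(6.0, abs=1.0)

    def test_out_of_region_bands_unchanged(self, white_token):
        region = TFRegion(2.0, 3.0, 125, 375)  # middle half of a 500-ms token
        out = d.apply_region_gain(white_token, region, 6.0)
        for band in (TFRegion(0.5, 1.5), TFRegion(4.0, 6.0)):
            assert abs(db_change(out, white_token, band)) < 1.0

    def test_gain_additivity(self, ka_token, registry):
        region = registry["ka"].target_region
        twice = d.apply_region_gain(
            d.apply_region_gain(ka_token, region, 3.0), region, 3.0
        )
        once = d.apply_region_gain(ka_token, region, 6.0)
        assert db_change(twice, ka_token, region) == pytest.approx(
            db_change(once, ka_token, region), abs=1.0
        )

    def test_length_preserved(self, ka_token, registry):
        out = d.apply_region_gain(ka_token, registry["ka"].target_region, 6.0)
        assert out.n_samples == ka_token.n_samples

    def test_nonfinite_gain_rejected(self, ka_token, registry):
        with pytest.raises(ValueError, match="finite"):
            d.apply_region_gain(ka_token, registry["ka"].target_region, np.nan)

    def test_region_beyond_token_rejected(self, ka_token):
        with pytest.raises(ValueError, match="duration"):
            d.apply_region_gain(ka_token, TFRegion(1.0, 2.0, 400, 900), 6.0)


class TestRemoveRegion:
    def test_wide_band_removal_depth(self, white_token):
        out = d.remove_region(white_token, (5.0, 7.8))
        assert db_change(out, white_token, TFRegion(5.0, 7.8)) <= -30

    def test_empty_band_is_noop(self, ka_token):
        assert d.remove_region(ka_token, (3.0, 3.0)) is ka_token

    def test_full_band_removal_near_silent(self, ka_token):
        out = d.remove_region(ka_token, (0.0, 8.0))
        assert 20 * np.log10(out.rms() / ka_token.rms()) <= -40

    def test_length_preserved(self, white_token):
        assert d.remove_region(white_token, (5.0, 7.8)).n_samples == white_token.n_samples


class TestOverlapRule:
    @pytest.mark.parametrize("label", ["pa", "ba"])
    def test_conflicting_inside_target_removes_nothing(self, registry, label):
        spec = registry[label]
        target = (spec.target_region.f_lo, spec.target_region.f_hi)
        assert d.removal_bands(target, spec.conflicting_band) == []

    def test_za_partial_overlap_removes_only_sliver(self, registry):
        spec = registry["za"]
        target = (spec.target_region.f_lo, spec.target_region.f_hi)
        bands = d.removal_bands(target, spec.conflicting_band)
        assert bands == [(3.5, 3.6)]

    def test_disjoint_bands_removed_entirely(self, registry):
        spec = registry["ka"]
        target = (spec.target_region.f_lo, spec.target_region.f_hi)
        assert d.removal_bands(target, spec.conflicting_band) == [(5.0, 7.8)]

    def test_straddling_target_splits_in_two(self):
        assert d.removal_bands((2.0, 3.0), (1.0, 4.0)) == [(1.0, 2.0), (3.0, 4.0)]

    @pytest.mark.parametrize("label", d.CONSONANT_LABELS)
    def test_removed_set_never_intersects_target_band(self, registry, label):
        spec = registry[label]
        target = (spec.target_region.f_lo, spec.target_region.f_hi)
        for lo, hi in d.removal_bands(target, spec.conflicting_band):
            assert hi <= target[0] or lo >= target[1]


class TestProcessCondition:
    def test_unprocessed_is_bitwise_identity(self, ka_token):
        out = d.process_condition(ka_token, "ka", "unprocessed")
        assert out is ka_token

    def test_target_condition_boosts_target_region(self, ka_token, registry):
        out = d.process_condition(ka_token, "ka", "target")
        assert db_change(out, ka_token, registry["ka"].target_region) == pytest.approx(6.0, abs=1.0)

    def test_pa_target_conflicting_removes_nothing(self, registry):
        token = d.make_token("pa", seed=2)
        with_target = d.process_condition(token, "pa", "target")
        with_both = d.process_condition(token, "pa", "target_conflicting")
        assert np.allclose(with_target.samples, with_both.samples)

    def test_ka_target_conflicting_removes_conflicting_band(self, ka_token, registry):
        out = d.process_condition(ka_token, "ka", "target_conflicting")
        conflicting = TFRegion(5.0, 7.8)
        assert db_change(out, ka_token, conflicting) <= -20
        # target region still boosted
        assert db_change(out, ka_token, registry["ka"].target_region) == pytest.approx(6.0, abs=1.0)

    def test_za_target_band_untouched_by_removal(self, registry):
        token = d.make_token("za", seed=4)
        out = d.process_condition(token, "za", "target_conflicting")
        # interior of the target band (away from the removed 3.5-3.6 sliver)
        interior = TFRegion(4.0, 7.0, 90, 120)
        assert db_change(out, token, interior) == pytest.approx(6.0, abs=1.5)

    def test_unknown_condition_rejected(self, ka_token):
        with pytest.raises(ValueError):
            d.process_condition(ka_token, "ka", "boosted")

    @pytest.mark.parametrize("condition", ["unprocessed", "target", "target_conflicting"])
    def test_length_preserved_all_conditions(self, ka_token, condition):
        out = d.process_condition(ka_token, "ka", condition)
        assert out.n_samples == ka_token.n_samples
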