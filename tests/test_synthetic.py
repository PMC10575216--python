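"""Generator contracts: determinism, counts, spectral and freeze signatures."""

import dataclasses

import numpy as np
import pytest

from conftest import noise_free
from pdkin import synthetic as syn
from pdkin.errors import InvalidArgumentError
from pdkin.features import freezing_index, power_spectrum
from pdkin.subtyping import classify_subtype


class TestGenerateCohort:
    def test_even_split_of_ten(self):
        cohort = syn.generate_cohort(10, 0.5, 0.0, seed=7)
        labels = [p.phenotype.subtype_label for p in cohort]
        assert labels.count("TD") == 5 and labels.count("PIGD") == 5
        assert all(p.fog_score == 0 for p in cohort)

    def test_imbalanced_cohort_with_fog(self):
        cohort = syn.generate_cohort(56, 0.2, 0.8, seed=1)
        labels = [p.phenotype.subtype_label for p in cohort]
        assert labels.count("TD") == 11 and labels.count("PIGD") == 45
        n_fog = sum(1 for p in cohort if p.fog_score > 0)
        assert n_fog == 36
        assert all(p.phenotype.subtype_label == "PIGD"
                   for p in cohort if p.fog_score > 0)

    def test_determinism_and_unique_ids(self):
        a = syn.generate_cohort(8, 0.4, 0.5, seed=3)
        b = syn.generate_cohort(8, 0.4, 0.5, seed=3)
        assert [dataclasses.asdict(p.phenotype) for p in a] == \
            [dataclasses.asdict(p.phenotype) for p in b]
        ids = [p.participant_id for p in a]
        assert len(set(ids)) == len(ids)

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            syn.generate_cohort(1, 0.5, 0.0, seed=0)
        with pytest.raises(InvalidArgumentError):
            syn.generate_cohort(10, 1.5, 0.0, seed=0)
        with pytest.raises(InvalidArgumentError):
            syn.generate_cohort(10, 0.5, -0.1, seed=0)

    def test_phenotype_invariants_enforced(self):
        with pytest.raises(InvalidArgumentError):
            syn.PhenotypeParams(
                subtype_label="TD", stride_frequency=1.0, stride_length=120,
                step_width=10, arm_swing_amplitude=10, tremor_amplitude=0.0,
                tremor_frequency=5, freeze_rate=0, freeze_duration=0,
                freeze_band_frequency=5, gait_variability_cv=0.03,
                sensor_noise_sd=0.1, height=170)


class TestSynthesizeSession:
    def test_recording_shape_and_rate(self, td_participant):
        rec, _ = syn.synthesize_session(td_participant, "walk_thru",
                                        duration=4.75, seed=1)
        assert rec.data.shape == (570, 11, 3)
        assert rec.sampling_rate == 120.0

    def test_determinism(self, td_participant):
        a, _ = syn.synthesize_session(td_participant, "walk_thru", 4.75, seed=5)
        b, _ = syn.synthesize_session(td_participant, "walk_thru", 4.75, seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_td_wrist_peak_in_tremor_band(self, td_participant):
        rec, _ = syn.synthesize_session(td_participant, "walk_thru",
                                        duration=4.75, seed=1)
        x = rec.channel("L.Wrist", "X")
        f, p = power_spectrum(x - x.mean(), 120.0)
        sel = (f >= 0.3) & (f <= 12.0)
        assert 4.0 <= f[sel][np.argmax(p[sel])] <= 6.0

    def test_clean_pigd_has_no_high_band_peak(self, pigd_participant):
        assert pigd_participant.phenotype.tremor_amplitude == 0
        rec, _ = syn.synthesize_session(pigd_participant, "walk_thru",
                                        duration=4.75, seed=1)
        z = rec.channel("L.Wrist", "Z")  # arm swing carries the gait rhythm
        f, p = power_spectrum(z, 120.0)
        loco_peak = p[(f >= 0.3) & (f <= 3.0)].max()
        high_peak = p[f > 3.0].max()
        assert high_peak < 0.10 * loco_peak

    def test_strike_count_tracks_stride_frequency(self, cohort6):
        for p in cohort6:
            if p.fog_score > 0:
                continue  # freezing pauses stepping
            duration = 10.0
            _, gt = syn.synthesize_session(p, "walk_thru", duration, seed=2)
            expected = duration * p.phenotype.stride_frequency
            assert abs(len(gt.heel_strike_times_left) - expected) <= 1.2

    def test_event_lists_strictly_increasing(self, walk_recording):
        _, gt = walk_recording
        for arr in (gt.heel_strike_times_left, gt.heel_strike_times_right,
                    gt.toe_off_times_left, gt.toe_off_times_right):
            assert np.all(np.diff(arr) > 0)

    def test_strikes_sit_on_heel_extrema_without_noise(self, cohort6):
        for p in cohort6[:3]:
            rec, gt = syn.synthesize_session(noise_free(p), "walk_thru",
                                             duration=10.0, seed=2)
            sig = rec.channel("L.Heel", "Z") - rec.channel("Sacral", "Z")
            for ts in gt.heel_strike_times_left:
                i = int(round(ts * 120.0))
                lo, hi = max(i - 6, 0), min(i + 7, len(sig))
                j = lo + int(np.argmax(sig[lo:hi]))
                assert abs(j - i) <= 1

    def test_errors(self, td_participant):
        with pytest.raises(InvalidArgumentError):
            syn.synthesize_session(td_participant, "moonwalk", 10.0, seed=0)
        with pytest.raises(InvalidArgumentError):
            syn.synthesize_session(td_participant, "walk_thru",
                                   duration=1.0, seed=0)

    def test_tug_starts_with_quiet_stand(self, pigd_participant):
        rec, _ = syn.synthesize_session(pigd_participant, "tug",
                                        duration=30.0, seed=1)
        z = rec.channel("Sacral", "Z")
        stand = abs(z[int(1.5 * 120)] - z[0])
        walk = abs(z[int(10 * 120)] - z[int(5 * 120)])
        assert stand < 5.0 < walk


class TestFreezeRealism:
    def test_intervals_within_duration_and_disjoint(self, pigd_freezer):
        _, gt = syn.synthesize_session(pigd_freezer, "tug", duration=40.0,
                                       seed=5)
        assert gt.freeze_intervals
        last_end = 0.0
        for s, e in gt.freeze_intervals:
            assert 0.0 <= s < e <= 40.0
            assert s >= last_end
            last_end = e

    def test_forward_displacement_collapses(self, pigd_freezer):
        rec, gt = syn.synthesize_session(pigd_freezer, "walk_thru",
                                         duration=20.0, seed=5)
        assert gt.freeze_intervals
        z = rec.channel("Sacral", "Z")
        x = rec.channel("Sacral", "X")
        step = 60  # 0.5 s coarse differencing suppresses sensor noise
        inside, outside = [], []
        for k in range(0, len(z) - step, step):
            t0, t1 = k / 120.0, (k + step) / 120.0
            r = np.hypot(z[k + step] - z[k], x[k + step] - x[k]) / 0.5
            if any(s + 0.3 <= t0 and t1 <= e - 0.3
                   for s, e in gt.freeze_intervals):
                inside.append(r)
            elif all(t1 < s - 0.3 or t0 > e + 0.3
                     for s, e in gt.freeze_intervals):
                outside.append(r)
        assert np.median(inside) < 0.2 * np.median(outside)

    def test_shank_freeze_band_power_rises_inside_episodes(self, pigd_freezer):
        rec, gt = syn.synthesize_session(pigd_freezer, "walk_thru",
                                         duration=20.0, seed=5)
        s0, e0 = gt.freeze_intervals[0]
        i0, i1 = int((s0 + 0.3) * 120), int((e0 - 0.3) * 120)
        fi_inside = []
        fi_walking = []
        for marker in ("L.Shank", "R.Shank"):
            sig = rec.channel(marker, "Z")
            fi_inside.append(freezing_index(sig[i0:i1], 120.0))
            # a same-length walking stretch clear of every episode
            w0 = 0
            while any(w0 / 120 < e + 0.5 and (w0 + (i1 - i0)) / 120 > s - 0.5
                      for s, e in gt.freeze_intervals):
                w0 += 120
            fi_walking.append(freezing_index(sig[w0:w0 + (i1 - i0)], 120.0))
        assert np.mean(fi_inside) > np.mean(fi_walking)


def test_spectral_separation_over_cohort():
    """Mean wrist 4-6 Hz band power is strictly greater for TD than PIGD."""
    cohort = syn.generate_cohort(50, 0.5, 0.5, seed=21)
    band = {"TD": [], "PIGD": []}
    for p in cohort:
        rec, _ = syn.synthesize_session(p, "walk_thru", duration=4.75, seed=3)
        for marker in ("L.Wrist", "R.Wrist"):
            for ax in ("X", "Y"):
                f, pw = power_spectrum(rec.channel(marker, ax), 120.0)
                band[p.phenotype.subtype_label].append(
                    pw[(f >= 4.0) & (f <= 6.0)].sum())
    assert np.mean(band["TD"]) > np.mean(band["PIGD"])


class TestSynthesizeUpdrs:
    def test_td_ratio_at_zero_noise(self, td_participant):
        scores = syn.synthesize_updrs(td_participant, noise_level=0.0, seed=1)
        res = classify_subtype(scores)
        assert res.ratio >= 1.15
        assert res.label == "TD"

    def test_pigd_ratio_at_zero_noise(self, pigd_participant):
        res = classify_subtype(
            syn.synthesize_updrs(pigd_participant, noise_level=0.0, seed=1))
        assert res.ratio <= 0.90
        assert res.label == "PIGD"

    def test_items_are_integers_in_range(self, cohort6):
        for p in cohort6:
            s = syn.synthesize_updrs(p, noise_level=0.3, seed=2)
            for v in {**s.tremor_items, **s.gait_items}.values():
                assert float(v).is_integer() and 0 <= v <= 4

    def test_label_agreement_under_noise(self):
        cohort = syn.generate_cohort(100, 0.5, 0.5, seed=5)
        agree = sum(
            classify_subtype(syn.synthesize_updrs(p, 0.2, seed=5)).label
            == p.phenotype.subtype_label for p in cohort)
        assert agree >= 95

    def test_gait_items_increase_with_freeze_rate(self, pigd_participant):
        base = pigd_participant.phenotype
        lo = dataclasses.replace(base, freeze_rate=1.0, freeze_duration=2.0)
        hi = dataclasses.replace(base, freeze_rate=5.0, freeze_duration=2.0)
        p_lo = syn.VirtualParticipant("A", lo, 1)
        p_hi = syn.VirtualParticipant("B", hi, 4)
        s_lo = syn.synthesize_updrs(p_lo, 0.0, seed=1)
        s_hi = syn.synthesize_updrs(p_hi, 0.0, seed=1)
        assert sum(s_hi.gait_items.values()) > sum(s_lo.gait_items.values())

    def test_fog_invariant(self, cohort6):
        for p in cohort6:
            assert (p.fog_score > 0) == (p.phenotype.freeze_rate > 0)

    def test_invalid_noise_level(self, td_participant):
        with pytest.raises(InvalidArgumentError):
            syn.synthesize_updrs(td_participant, noise_level=1.5, seed=0)
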