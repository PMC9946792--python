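"""Generator properties: determinism, spectral shape, injected tones,
effect sizes, and schedule structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sp_signal

from gammamap import (
    BAND_BY_NAME,
    DEFAULT_BANDS,
    EffectSpec,
    SessionPlan,
    ValidationError,
    bandpass_bank,
    bipolar_rereference,
    instantaneous_power,
    make_parcellation,
    make_session,
    make_strips,
    segment_trials,
)
from gammamap.condition_power import condition_mean_power
from conftest import FAST_BANDS


def small_session(seed, effects=None, fs=600.0, labels=None, strips=None, plan=None):
    """Compact session on the low-rate band table for fast tests."""
    if strips is None:
        strips = make_strips(1, 4, 10.0, placement=[(0.0, 30.0, 30.0)], seed=seed)
    if labels is None:
        affine = np.diag([4.0, 4.0, 4.0, 1.0])
        affine[:3, 3] = [-80.0, -80.0, -80.0]
        labels = make_parcellation((40, 40, 40), affine, [("FPN", (0.0, 30.0, 30.0), 30.0)])
    plan = plan or SessionPlan(n_trials={"rest": 0, "count": 3, "switch": 3})
    effects = effects or EffectSpec()
    return make_session(plan, effects, strips, labels, fs=fs, seed=seed, bands=FAST_BANDS)


class TestMakeParcellation:
    def test_blob_radius_rule(self):
        vol = make_parcellation((20, 20, 20), np.diag([2.0, 2.0, 2.0, 1.0]),
                                [("FPN", (20.0, 20.0, 20.0), 10.0)])
        mm, labs = vol.labelled_voxel_mm()
        d = np.linalg.norm(mm - np.array([20.0, 20.0, 20.0]), axis=1)
        assert (d <= 10.0).all()
        assert set(labs) == {1}
        assert vol.label_names[1] == "FPN"

    def test_empty_spec_all_background(self):
        vol = make_parcellation((5, 5, 5), np.eye(4), [])
        assert vol.labels_present == set()

    def test_overlap_first_listed_wins(self):
        vol = make_parcellation((10, 10, 10), np.eye(4), [
            ("FPN", (4.0, 4.0, 4.0), 3.0),
            ("DMN", (5.0, 4.0, 4.0), 3.0),
        ])
        # voxel (4,4,4) is inside both blobs; FPN listed first
        assert vol.grid[4, 4, 4] == 1
        assert vol.label_names[vol.grid[4, 4, 4]] == "FPN"

    def test_out_of_grid_blob_warns(self):
        with pytest.warns(UserWarning, match="clip"):
            make_parcellation((5, 5, 5), np.eye(4), [("FPN", (100.0, 0.0, 0.0), 2.0)])


class TestMakeStrips:
    def test_pitch_10mm_between_consecutive_contacts(self):
        table = make_strips(1, 4, 10.0, seed=0)
        coords = table.coords
        d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        np.testing.assert_allclose(d, 10.0)

    def test_contact_count(self):
        assert len(make_strips(3, 4, 10.0, seed=0)) == 12

    def test_seed_determinism(self):
        a = make_strips(5, 4, 10.0, seed=9)
        b = make_strips(5, 4, 10.0, seed=9)
        pd.testing.assert_frame_equal(a.contacts, b.contacts)

    def test_per_strip_contact_counts(self):
        table = make_strips(3, [4, 3, 2], 10.0, seed=1)
        sizes = [len(g) for g in table.strips().values()]
        assert sorted(sizes) == [2, 3, 4]


class TestMakeSession:
    def test_seed_determinism_bit_identical(self):
        rec1, ev1, gt1 = small_session(5)
        rec2, ev2, gt2 = small_session(5)
        np.testing.assert_array_equal(rec1.data, rec2.data)
        pd.testing.assert_frame_equal(ev1.trials, ev2.trials)
        assert gt1["schedule"] == gt2["schedule"]

    def test_fs_too_low_for_top_band(self):
        with pytest.raises(ValidationError, match="band"):
            small_session(0, fs=120.0)  # cannot resolve the 70 Hz band edge
        with pytest.raises(ValidationError):
            strips = make_strips(1, 4, 10.0, seed=0)
            make_session(SessionPlan(), EffectSpec(), strips, None, fs=400.0,
                         seed=0, bands=DEFAULT_BANDS)

    def test_spectral_slope_matches_configured_exponent(self):
        """With all-ones modulation and no band components or tones, the
        average periodogram slope over 4-200 Hz matches the configured
        1/f exponent within 0.2."""
        eff = EffectSpec(band_component_std_uv={}, line_noise_uv={},
                         artifact_tone_uv=0.0, common_mode_uv=0.0,
                         background_exponent=2.0)
        strips = make_strips(1, 4, 10.0, placement=[(0.0, 30.0, 30.0)], seed=3)
        rec, _, _ = small_session(3, effects=eff, fs=600.0, strips=strips)
        f, pxx = sp_signal.welch(rec.data, fs=rec.fs, nperseg=4096, axis=1)
        sel = (f >= 4.0) & (f <= 200.0)
        slope = -np.polyfit(np.log(f[sel]), np.log(pxx[:, sel].mean(axis=0)), 1)[0]
        assert abs(slope - 2.0) < 0.2

    def test_artifact_tone_is_max_peak_in_70_90(self):
        rec, _, _ = small_session(7)
        f, pxx = sp_signal.periodogram(rec.data[0], fs=rec.fs)
        sel = (f >= 70.0) & (f <= 90.0)
        peak = f[sel][np.argmax(pxx[sel])]
        assert abs(peak - 79.0) < 0.5

    def test_null_effects_no_condition_modulation(self):
        """All-ones effect spec: switch/count band power ratio close to 1."""
        rec, events, _ = small_session(11)
        band = BAND_BY_NAME["beta"]
        br = bandpass_bank(rec, [band])[0]
        bp = instantaneous_power(br, band)
        segs = segment_trials(bp, events)
        m_sw, _ = condition_mean_power(bp.power[0], segs, "switch")
        m_ct, _ = condition_mean_power(bp.power[0], segs, "count")
        assert 0.7 < m_sw / m_ct < 1.4

    def test_injected_ratio_recovered_across_sessions(self):
        """A x2 low-gamma switch/count modulation on FPN contacts shows up
        as an empirical bipolar band power ratio of ~2 when averaged over
        20 seeded sessions (within 10%)."""
        eff = EffectSpec(modulation={("FPN", "LG", "switch"): 2.0},
                         line_noise_uv={}, artifact_tone_uv=0.0)
        band = BAND_BY_NAME["LG"]
        ratios = []
        for seed in range(20):
            strips = make_strips(1, 4, 10.0, placement=[(0.0, 30.0, 30.0)], seed=seed)
            rec, events, _ = small_session(seed, effects=eff, strips=strips)
            rec_b, _ = bipolar_rereference(rec, strips)
            bp = instantaneous_power(bandpass_bank(rec_b, [band])[0], band)
            segs = segment_trials(bp, events)
            for ch in range(rec_b.n_channels):
                m_sw, _ = condition_mean_power(bp.power[ch], segs, "switch")
                m_ct, _ = condition_mean_power(bp.power[ch], segs, "count")
                ratios.append(m_sw / m_ct)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.10)

    def test_common_mode_cancels_under_bipolar(self):
        eff = EffectSpec(common_mode_uv=100.0, line_noise_uv={}, artifact_tone_uv=0.0,
                         band_component_std_uv={}, background_std_uv=0.0)
        strips = make_strips(1, 4, 10.0, placement=[(0.0, 30.0, 30.0)], seed=2)
        rec, _, _ = small_session(2, effects=eff, strips=strips)
        rec_b, _ = bipolar_rereference(rec, strips)
        # channels are pure common mode: the bipolar derivation wipes them out
        assert np.abs(rec_b.data).max() <= 1e-9 * max(np.abs(rec.data).max(), 1e-12)

    def test_ground_truth_records_modulations(self):
        eff = EffectSpec(modulation={("FPN", "HG", "switch"): 1.5})
        strips = make_strips(1, 4, 10.0, placement=[(0.0, 30.0, 30.0)], seed=4)
        affine = np.diag([4.0, 4.0, 4.0, 1.0])
        affine[:3, 3] = [-80.0, -80.0, -80.0]
        labels = make_parcellation((40, 40, 40), affine, [("FPN", (0.0, 30.0, 30.0), 30.0)])
        rec, events, gt = make_session(SessionPlan(n_trials={"rest": 0, "count": 2, "switch": 2}),
                                       eff, strips, labels, fs=2000.0, seed=4)
        assert all(c["network"] == "FPN" for c in gt["channels"])
        assert gt["channels"][0]["gains"]["HG:switch"] == 1.5


class TestSessionPlan:
    def test_schedule_counts_and_order(self):
        plan = SessionPlan()
        rng = np.random.default_rng(0)
        sched = plan.draw_schedule(rng)
        counts = sched["condition"].value_counts()
        assert counts["rest"] == 1 and counts["count"] == 4 and counts["switch"] == 4
        assert sched["condition"].iloc[0] == "rest"
        assert (sched["onset_s"].diff().dropna() > 0).all()

    def test_durations_respect_floors_and_ranges(self):
        plan = SessionPlan()
        rng = np.random.default_rng(1)
        for _ in range(20):
            sched = plan.draw_schedule(rng)
            dur = sched["offset_s"] - sched["onset_s"]
            for cond, floor in plan.min_duration_s.items():
                sel = sched["condition"] == cond
                assert (dur[sel] >= floor - 1e-9).all()
            rest = dur[sched["condition"] == "rest"]
            assert ((rest >= 120.0) & (rest <= 180.0)).all()

    def test_alternation_mostly_strict(self):
        plan = SessionPlan(n_trials={"rest": 0, "count": 20, "switch": 20},
                           repeat_probability=0.0)
        sched = plan.draw_schedule(np.random.default_rng(2))
        conds = sched["condition"].tolist()
        assert all(a != b for a, b in zip(conds, conds[1:]))


class TestPsdContrastOnSyntheticEffect:
    def test_doubled_high_band_power_shows_plus_100_percent(self):
        """x2 power modulation in the top band appears as ~+100% in the
        per-frequency switch/count contrast across that band's bins."""
        from gammamap import psd_contrast
        from gammamap.condition_power import ExclusionRule

        eff = EffectSpec(modulation={("FPN", "LG", "switch"): 2.0},
                         line_noise_uv={}, artifact_tone_uv=0.0,
                         background_std_uv=3.0, common_mode_uv=0.0,
                         band_component_std_uv={"LG": 10.0})
        plan = SessionPlan(n_trials={"rest": 0, "count": 4, "switch": 4})
        strips = make_strips(1, 4, 10.0, placement=[(0.0, 30.0, 30.0)], seed=6)
        rec, events, _ = small_session(6, effects=eff, strips=strips, plan=plan)
        out = psd_contrast(rec, events, ("switch", "count"))
        sel = (out["frequency_hz"] >= 35.0) & (out["frequency_hz"] <= 65.0)
        mean_pct = out.loc[sel, "percent_change"].mean()
        assert mean_pct == pytest.approx(100.0, abs=20.0)
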