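"""Synthetic cohort generator: scoring rules, demographics, audio, round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frailvoice import cohort as ch


class TestKFrailRules:
    @pytest.mark.parametrize(
        "score,category",
        [(0, "robust"), (1, "prefrail"), (2, "prefrail"), (3, "frail"),
         (4, "frail"), (5, "frail")],
    )
    def test_categorize(self, score, category):
        assert ch.kfrail_categorize(score) == category

    @pytest.mark.parametrize("bad", [-1, 6, 2.5, 100])
    def test_categorize_domain_error(self, bad):
        with pytest.raises(ValueError):
            ch.kfrail_categorize(bad)

    @pytest.mark.parametrize(
        "category,label", [("robust", 0), ("prefrail", 1), ("frail", 1)]
    )
    def test_binary_label(self, category, label):
        assert ch.binary_label(category) == label

    @given(score=st.integers(min_value=0, max_value=5))
    @settings(deadline=None)
    def test_category_label_consistency(self, score):
        """label = 1 iff score >= 1; frail iff score >= 3; total on [0,5]."""
        cat = ch.kfrail_categorize(score)
        lab = ch.binary_label(cat)
        assert lab == (1 if score >= 1 else 0)
        assert (cat == "frail") == (score >= 3)


class TestGenerateCohort:
    def test_positive_count_matches_study_prevalence(self):
        cohort = ch.generate_cohort(ch.CohortSpec(n=127, positive_prevalence=0.512))
        labels = [p.label for p in cohort]
        assert sum(labels) == 65
        assert len(labels) - sum(labels) == 62

    def test_item_sum_and_category_invariants(self):
        for p in ch.generate_cohort(ch.CohortSpec(n=60, seed=5)):
            assert sum(p.kfrail_items) == p.kfrail_score
            assert ch.kfrail_categorize(p.kfrail_score) == p.category
            assert ch.binary_label(p.category) == p.label
            assert 50 <= p.age <= 95

    def test_seeded_determinism_and_seed_sensitivity(self):
        a = ch.generate_cohort(ch.CohortSpec(n=50, seed=11))
        b = ch.generate_cohort(ch.CohortSpec(n=50, seed=11))
        c = ch.generate_cohort(ch.CohortSpec(n=50, seed=12))
        assert a == b
        assert a != c

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ch.generate_cohort(ch.CohortSpec(n=10, positive_prevalence=0.01))

    def test_class_conditional_age_means(self):
        """At n=2000 the class age means sit within 3 SE of 64.9 / 73.4 years."""
        cohort = ch.generate_cohort(ch.CohortSpec(n=2000, seed=21))
        ages = np.array([p.age for p in cohort])
        labels = np.array([p.label for p in cohort])
        for target_mean, sd, mask in [
            (64.9, 9.26, labels == 0),
            (73.4, 10.84, labels == 1),
        ]:
            se = sd / np.sqrt(mask.sum())
            assert abs(ages[mask].mean() - target_mean) < 3 * se
        diff = ages[labels == 1].mean() - ages[labels == 0].mean()
        assert diff > 0
        se_diff = np.sqrt(
            9.26**2 / (labels == 0).sum() + 10.84**2 / (labels == 1).sum()
        )
        assert abs(diff - 8.5) < 3 * se_diff


def _rms_pause_fraction(samples, sr, frame_ms=25.0, hop_ms=10.0):
    """Independent frame-RMS silence detector used as the pause oracle."""
    fl, hop = int(frame_ms * sr / 1000), int(hop_ms * sr / 1000)
    frames = np.lib.stride_tricks.sliding_window_view(samples, fl)[::hop]
    rms = np.sqrt(np.mean(frames**2, axis=1))
    return float(np.mean(rms < 0.05 * rms.max()))


class TestSynthesizeSpeech:
    def test_sample_count_matches_duration(self):
        p = ch.Participant("X", 70, "female", (0,) * 5, 0, "robust", 0)
        rec = ch.synthesize_speech(
            p, ch.AudioClassParams(duration=10.0, sample_rate=48_000), seed=1
        )
        assert len(rec.samples) == 480_000

    def test_amplitude_and_finiteness(self, short_clip):
        assert np.max(np.abs(short_clip.samples)) <= 1.0
        assert np.all(np.isfinite(short_clip.samples))

    def test_bit_identical_under_fixed_seed(self):
        p = ch.Participant("X", 70, "male", (0,) * 5, 0, "robust", 0)
        params = ch.AudioClassParams(duration=1.5)
        a = ch.synthesize_speech(p, params, seed=4)
        b = ch.synthesize_speech(p, params, seed=4)
        c = ch.synthesize_speech(p, params, seed=5)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_nonpositive_duration_rejected(self):
        p = ch.Participant("X", 70, "male", (0,) * 5, 0, "robust", 0)
        with pytest.raises(ValueError):
            ch.synthesize_speech(p, ch.AudioClassParams(duration=0.0), seed=1)

    def test_severe_clips_pause_more_than_robust(self):
        """Severity gradient: score-5 clips show a larger RMS-detected pause
        fraction than score-0 clips, batch means compared with an oracle
        detector independent of the feature module."""
        base = ch.AudioClassParams(duration=3.0)
        rob = ch.Participant("R", 65, "male", (0,) * 5, 0, "robust", 0)
        frail = ch.Participant("F", 80, "male", (1,) * 5, 5, "frail", 1)
        pf = {0: [], 5: []}
        for seed in range(50):
            for score, person in [(0, rob), (5, frail)]:
                rec = ch.synthesize_speech(
                    person, ch.severity_params(base, score), seed=1000 + seed
                )
                pf[score].append(
                    _rms_pause_fraction(rec.samples, rec.sample_rate)
                )
        assert np.mean(pf[5]) > np.mean(pf[0])


class TestWriteReadCohort:
    def test_round_trip(self, tmp_path):
        cohort = ch.generate_cohort(
            ch.CohortSpec(n=10, audio_params=ch.AudioClassParams(duration=0.8), seed=3)
        )
        manifest = ch.write_cohort(
            cohort, tmp_path, base_params=ch.AudioClassParams(duration=0.8), seed=3
        )
        assert manifest.exists()
        assert len(list(tmp_path.glob("*.wav"))) == 10
        back = ch.read_cohort(manifest)
        assert len(back) == 10
        for orig, rt in zip(cohort, back):
            assert (orig.id, orig.age, orig.sex) == (rt.id, rt.age, rt.sex)
            assert orig.kfrail_items == rt.kfrail_items
            assert orig.kfrail_score == rt.kfrail_score == sum(rt.kfrail_items)
            assert (orig.category, orig.label) == (rt.category, rt.label)
            assert rt.recording_path is not None

    def test_wav_amplitude_round_trip(self, tmp_path, short_clip):
        p = ch.Participant("P0", 65, "male", (0,) * 5, 0, "robust", 0)
        ch.write_cohort([p], tmp_path, recordings={"P0": short_clip})
        rec = ch.load_recording(tmp_path / "P0.wav", "P0")
        assert rec.sample_rate == short_clip.sample_rate
        assert np.max(np.abs(rec.samples - short_clip.samples)) < 1.5 / 32768
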