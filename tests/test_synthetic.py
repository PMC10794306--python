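import numpy as np
import pandas as pd
import pytest
from scipy.signal import periodogram
from scipy.stats import spearmanr

from eegtda import (ConfigurationError, StudyConfig, SubjectProfile,
                    generate_recording, generate_study, inject_artifacts,
                    sample_moca)


def make_profile(group="healthy", severity=0.0, moca=28):
    return SubjectProfile(subject_id="sub-00", group=group,
                          severity=severity, moca=moca, age_years=70.0)


class TestStudyConfig:
    def test_default_design_yields_72_displays(self):
        cfg = StudyConfig()
        assert cfg.displays_per_session == 9
        assert cfg.events_per_subject == 72

    @pytest.mark.parametrize("kwargs", [
        dict(n_subjects=3, n_mci=5),
        dict(n_mci=-1),
        dict(sampling_rate_hz=0),
        dict(effect_size=1.5),
        dict(artifact_rate_per_min=-2),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            StudyConfig(**kwargs)

    def test_moca_outside_range_rejected(self):
        with pytest.raises(ValueError):
            make_profile(moca=31)


class TestGenerateStudy:
    def test_cohort_composition(self):
        cfg = StudyConfig(n_subjects=23, n_mci=16, n_sessions=1,
                          master_seed=1)
        study = generate_study(cfg)
        assert len(study) == 23
        assert sum(p.group == "mci" for p, _ in study) == 16
        for p, _ in study:
            ok = p.moca >= 26 if p.group == "healthy" else p.moca < 26
            assert ok

    def test_empty_study(self):
        assert generate_study(StudyConfig(n_subjects=0, n_mci=0)) == []

    def test_same_seed_bitwise_identical(self):
        cfg = StudyConfig(n_subjects=2, n_mci=1, n_sessions=1, master_seed=5)
        a = generate_study(cfg)
        b = generate_study(cfg)
        for (pa, ra), (pb, rb) in zip(a, b):
            assert pa == pb
            assert np.array_equal(ra.data, rb.data)
            pd.testing.assert_frame_equal(ra.events, rb.events)


class TestEventGrammar:
    def test_session_roles_and_categories(self):
        cfg = StudyConfig(master_seed=2)
        rec = generate_recording(make_profile(), cfg)
        ev = rec.events
        assert len(ev) == 72
        assert ev["onset_sample"].is_monotonic_increasing
        assert ev["onset_sample"].is_unique
        for _, sess in ev.groupby("session"):
            roles = sess["role"].value_counts()
            assert roles["cue"] == 1
            assert roles["target"] == 1
            assert roles["ignored"] == 7
            stream = sess[sess["role"] != "cue"]
            assert sorted(stream["image_id"]) == list(range(8))
            assert (stream["category"] == "reminiscent").sum() == 4
        counts = ev["role"].value_counts()
        assert counts.to_dict() == {"ignored": 56, "cue": 8, "target": 8}

    def test_epoch_windows_fit_recording(self):
        cfg = StudyConfig(master_seed=3)
        rec = generate_recording(make_profile(), cfg)
        epoch_len = int(2.0 * cfg.sampling_rate_hz)
        assert rec.events["onset_sample"].max() + epoch_len <= rec.n_samples


class TestSignalModel:
    def band_power(self, rec, onsets, fs, fmin=8.0, fmax=12.0):
        """Periodogram oracle: mean post-stimulus alpha power over epochs."""
        powers = []
        n = int(2 * fs)
        for onset in onsets:
            seg = rec.data[:, onset:onset + n]
            f, pxx = periodogram(seg, fs=fs, axis=1)
            band = (f >= fmin) & (f <= fmax)
            powers.append(pxx[:, band].sum())
        return np.mean(powers)

    def test_alpha_power_decreases_with_severity(self):
        cfg = StudyConfig(effect_size=1.0, master_seed=7)
        healthy = generate_recording(make_profile("healthy", 0.0), cfg)
        mci = generate_recording(make_profile("mci", 1.0, moca=15), cfg)
        assert len(healthy.events) >= 50
        ph = self.band_power(healthy, healthy.events["onset_sample"],
                             cfg.sampling_rate_hz)
        pm = self.band_power(mci, mci.events["onset_sample"],
                             cfg.sampling_rate_hz)
        assert ph > 2 * pm

    def test_null_effect_makes_groups_identical(self):
        cfg = StudyConfig(effect_size=0.0, n_sessions=1, master_seed=9)
        healthy = generate_recording(make_profile("healthy", 0.0), cfg)
        mci = generate_recording(make_profile("mci", 1.0, moca=15), cfg)
        ph = self.band_power(healthy, healthy.events["onset_sample"],
                             cfg.sampling_rate_hz)
        pm = self.band_power(mci, mci.events["onset_sample"],
                             cfg.sampling_rate_hz)
        # same seed, zero effect: the signal model ignores severity entirely
        assert np.allclose(ph, pm, rtol=1e-12)


class TestMoca:
    def test_range_contracts(self, rng):
        assert sample_moca("healthy", 0.0, rng) in range(26, 31)
        assert sample_moca("mci", 1.0, rng) < 26

    def test_monotone_link_in_severity(self, rng):
        severities = rng.uniform(0.35, 1.0, size=1000)
        scores = [sample_moca("mci", s, rng) for s in severities]
        rho, _ = spearmanr(severities, scores)
        assert rho < -0.5


class TestArtifacts:
    def setup_method(self):
        self.cfg = StudyConfig(n_sessions=1, master_seed=4)
        self.rec = generate_recording(make_profile(), self.cfg)

    def test_zero_rate_is_noop(self):
        out = inject_artifacts(self.rec, 0.0, 200.0, seed=0)
        assert out is not self.rec
        assert np.array_equal(out.data, self.rec.data)

    def test_blinks_exceed_threshold_frontally(self):
        out = inject_artifacts(self.rec, 10.0, 200.0, seed=0)
        fz = out.data[list(out.channel_names).index("Fz")]
        assert np.max(np.abs(fz)) > 150.0
        assert np.array_equal(self.rec.data,
                              generate_recording(make_profile(),
                                                 self.cfg).data)

    def test_seeds_move_artifact_onsets(self):
        a = inject_artifacts(self.rec, 10.0, 200.0, seed=0)
        b = inject_artifacts(self.rec, 10.0, 200.0, seed=1)
        assert not np.array_equal(a.data, b.data)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            inject_artifacts(self.rec, 1.0, -5.0, seed=0)
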