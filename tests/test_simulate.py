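"""Synthetic-cohort generator: determinism, GCS structure, planted effects."""

import numpy as np
import pandas as pd
import pytest

from comascope.eeg import compute_spectrogram
from comascope.gaze import compute_heatmap, normalize_heatmap
from comascope.simulate import (
    ParticipantRecord,
    SessionSpec,
    SimulationConfig,
    generate_cohort,
    generate_session_dataset,
    synthesize_eeg,
    synthesize_gaze,
)


class TestCohort:
    def test_cohort_size_and_gcs_sum_identity(self):
        cfg = SimulationConfig(n_participants=33, seed=0)
        cohort = generate_cohort(cfg)
        assert len(cohort) == 33
        for p in cohort:
            assert p.gcs_sum == p.gcs_eye + p.gcs_motor + p.gcs_verbal
            assert 2 <= p.gcs_eye <= 4
            assert 1 <= p.gcs_motor <= 4
            assert 1 <= p.gcs_verbal <= 3

    def test_minimum_component_scores_sum_to_five(self):
        p = ParticipantRecord("X", (21, 30), "Fall", 6, 2, 1, 2)
        assert p.gcs_sum == 5

    def test_same_seed_same_cohort(self):
        cfg = SimulationConfig(n_participants=10, seed=42)
        assert generate_cohort(cfg) == generate_cohort(cfg)

    def test_invalid_gcs_range_rejected(self):
        with pytest.raises(ValueError, match="clinical"):
            SimulationConfig(gcs_ranges={"eye": (0, 4), "motor": (1, 4), "verbal": (1, 3)})
        with pytest.raises(ValueError, match="clinical range"):
            ParticipantRecord("X", (21, 30), "Fall", 6, 5, 1, 1)


class TestEEGSynthesis:
    def test_shape_matches_headset_and_duration(self, participant, sim_config):
        e5 = synthesize_eeg(participant, 5, 12.0, sim_config, seed=0)
        assert e5.samples.shape == (5, 1536)  # 12 s x 128 Hz
        e14 = synthesize_eeg(participant, 14, 24.0, sim_config, seed=0)
        assert e14.samples.shape == (14, 3072)
        assert len(e14.channel_labels) == 14

    def test_unknown_headset_rejected(self, participant, sim_config):
        with pytest.raises(ValueError, match="headset"):
            synthesize_eeg(participant, 7, 12.0, sim_config, seed=0)

    def test_zero_rate_gives_no_atypical_epochs(self, participant):
        cfg = SimulationConfig(atypical_rate_map={participant.gcs_sum: 0.0}, seed=1)
        e = synthesize_eeg(participant, 5, 120.0, cfg, seed=5)
        assert e.atypical_epochs.sum() == 0

    def test_atypical_fraction_tracks_configured_rate(self):
        """Empirical atypical fractions within 3 binomial sd of the rates."""
        n_epochs = 200
        records = {
            5: ParticipantRecord("X", (31, 40), "Stroke", 6, 2, 2, 1),
            11: ParticipantRecord("Y", (31, 40), "Stroke", 6, 4, 4, 3),
        }
        for gcs, rate in ((5, 0.02), (11, 0.3)):
            p = records[gcs]
            assert p.gcs_sum == gcs
            cfg = SimulationConfig(atypical_rate_map={gcs: rate}, seed=2)
            e = synthesize_eeg(p, 5, n_epochs * 12.0, cfg, seed=77)
            frac = e.atypical_epochs.mean()
            sd = np.sqrt(rate * (1 - rate) / n_epochs)
            assert abs(frac - rate) < 3 * sd

    def test_atypical_band_power_shift(self, participant):
        """Planted template raises band power vs typical epochs."""
        cfg = SimulationConfig(atypical_rate_map={participant.gcs_sum: 0.5}, seed=3)
        e = synthesize_eeg(participant, 5, 100 * 12.0, cfg, seed=8)
        flags = e.atypical_epochs
        assert 25 < flags.sum() < 75
        band_power = []
        for k in range(100):
            seg = e.samples[:, k * 1536 : (k + 1) * 1536]
            s = compute_spectrogram(seg)
            band = (s.frequency_axis >= cfg.atypical_band[0]) & (
                s.frequency_axis <= cfg.atypical_band[1]
            )
            band_power.append(s.values[:, band].mean())
        band_power = np.array(band_power)
        assert band_power[flags].mean() > 2 * band_power[~flags].mean()

    def test_determinism(self, participant, sim_config):
        a = synthesize_eeg(participant, 5, 24.0, sim_config, seed=9)
        b = synthesize_eeg(participant, 5, 24.0, sim_config, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.atypical_epochs, b.atypical_epochs)


class TestGazeSynthesis:
    def test_sample_count(self, participant, sim_config):
        g = synthesize_gaze(participant, 12.0, sim_config, seed=0)
        assert len(g.timestamps) == 720  # 12 s x 60 Hz

    def test_degenerate_single_fixation(self, participant):
        cfg = SimulationConfig(
            gaze_gcs_link=False,
            n_fixation_targets=1,
            fixation_dispersion_px=0.0,
            tracking_loss_rate=0.1,
            seed=4,
        )
        g = synthesize_gaze(participant, 12.0, cfg, seed=6)
        on = (g.x >= 0) & (g.x < cfg.screen_size[0]) & (g.y >= 0) & (g.y < cfg.screen_size[1])
        assert on.sum() > 0
        assert np.unique(g.x[on]).size == 1
        assert np.unique(g.y[on]).size == 1

    def test_more_targets_increase_heatmap_entropy(self, participant):
        """Scanning five targets spreads gaze mass over more cells."""

        def mean_entropy(n_targets):
            vals = []
            for seed in range(20):
                cfg = SimulationConfig(
                    gaze_gcs_link=False, n_fixation_targets=n_targets, seed=seed
                )
                g = synthesize_gaze(participant, 12.0, cfg, seed=seed)
                h = normalize_heatmap(compute_heatmap(g.x, g.y, cfg.screen_size))
                p = h.grid[h.grid > 0]
                vals.append(float(-(p * np.log(p)).sum()))
            return np.mean(vals)

        assert mean_entropy(5) > mean_entropy(1)

    def test_non_positive_screen_rejected(self, participant):
        with pytest.raises(ValueError):
            SimulationConfig(screen_size=(0, 1080))


class TestSessionDataset:
    def test_file_counts_and_headset_layout(self, tmp_path):
        cfg = SimulationConfig(
            n_participants=2,
            sessions=(SessionSpec("B", (5, 14)),),
            session_duration=60.0,
            seed=5,
        )
        layout = generate_session_dataset(cfg, tmp_path / "ds")
        # session B uses both headsets: 2 participants x 2 headsets
        assert len(layout.eeg_paths) == 4
        assert len(layout.gaze_paths) == 2
        assert layout.cohort_path.exists()
        names = {p.name for p in layout.eeg_paths}
        assert "eeg_P01_B_5.csv" in names and "eeg_P01_B_14.csv" in names

    def test_ground_truth_conserves_atypical_counts(self, tmp_path):
        cfg = SimulationConfig(
            n_participants=2,
            sessions=(SessionSpec("A", (5,)),),
            session_duration=120.0,
            atypical_rate_map={g: 0.5 for g in range(3, 16)},
            seed=6,
        )
        layout = generate_session_dataset(cfg, tmp_path / "ds")
        gt = pd.read_csv(layout.ground_truth_path)
        cohort = generate_cohort(cfg)
        for s_idx, session in enumerate(cfg.sessions):
            for p_idx, p in enumerate(cohort):
                from comascope.simulate import _mix

                e = synthesize_eeg(
                    p, 5, cfg.session_duration, cfg,
                    seed=_mix([cfg.seed & 0x7FFFFFFF, s_idx, p_idx], 10 + 5),
                )
                sub = gt[(gt.participant_id == p.participant_id) & (gt.headset == 5)]
                assert sub.is_atypical.sum() == e.atypical_epochs.sum()

    def test_metadata_byte_identical_on_rerun(self, tmp_path):
        cfg = SimulationConfig(n_participants=3, session_duration=24.0, seed=7)
        a = generate_session_dataset(cfg, tmp_path / "a")
        b = generate_session_dataset(cfg, tmp_path / "b")
        assert a.cohort_path.read_bytes() == b.cohort_path.read_bytes()
        assert a.ground_truth_path.read_bytes() == b.ground_truth_path.read_bytes()
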