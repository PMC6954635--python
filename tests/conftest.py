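import numpy as np
import pytest

from comascope.io import EventLog, GazeRecording, RawEEGRecording, align_session
from comascope.simulate import ParticipantRecord, SessionSpec, SimulationConfig, synthesize_eeg, synthesize_gaze


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    """Small single-session study used across tests."""
    return SimulationConfig(
        n_participants=2,
        sessions=(SessionSpec("A", (5,)),),
        session_duration=36.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def participant() -> ParticipantRecord:
    return ParticipantRecord("P01", (41, 50), "Stroke", 12, 3, 3, 2)


@pytest.fixture(scope="session")
def session_bundle(sim_config, participant):
    """One aligned 36-s session (5-electrode headset) -> 3 epochs."""
    e = synthesize_eeg(participant, 5, sim_config.session_duration, sim_config, seed=3)
    g = synthesize_gaze(participant, sim_config.session_duration, sim_config, seed=3)
    eeg = RawEEGRecording(
        samples=e.samples,
        channel_labels=e.channel_labels,
        sampling_rate=e.sampling_rate,
        participant_id=participant.participant_id,
        session_label="A",
    )
    gaze = GazeRecording(
        timestamps=g.timestamps, x=g.x, y=g.y, screen_size=g.screen_size
    )
    return align_session(eeg, gaze, EventLog())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
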