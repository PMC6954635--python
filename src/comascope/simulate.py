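"""Synthetic cohort and biosignal generator.

Real recordings of acquired-brain-injury patients interacting with a
therapist are not publicly available, so this module produces a simulated
cohort with the statistical structure the downstream analysis assumes:

* participants with Glasgow Coma Scale (GCS) component scores drawn within
  clinically observed ranges (eye 2-4, motor 1-4, verbal 1-3);
* multi-channel EEG at 128 Hz from either the 5- or the 14-electrode
  headset, modelled as 1/f background noise plus theta/alpha oscillations
  plus Poisson-arriving spike artifacts (sudden electrode-contact loss);
* rare "atypical" 12-s epochs that follow a distinct spectral template
  (flattened background slope plus a band-limited component replacing the
  usual oscillations); their occurrence probability is a configurable
  function of the GCS sum.  This encodes the working hypothesis that rare
  signal states drive the embedding-variance differences between GCS
  groups, and is the planted effect that recovery tests look for;
* an eye-gaze stream (>= 60 samples/s) generated as a fixation-saccade
  process whose number of fixation targets and dispersion are optionally
  modulated by GCS;
* therapist event logs and a cohort metadata table.

All randomness flows from one root seed through per-stream derived seeds
(`numpy.random.SeedSequence`), so any stage can be regenerated
independently and identical configurations yield identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .channels import HEADSET_CHANNELS

__all__ = [
    "ParticipantRecord",
    "SessionSpec",
    "SimulationConfig",
    "default_atypical_rates",
    "generate_cohort",
    "synthesize_eeg",
    "synthesize_gaze",
    "generate_events",
    "generate_session_dataset",
]

#: Clinical bounds of the GCS components.
GCS_BOUNDS = {"eye": (1, 4), "motor": (1, 6), "verbal": (1, 5)}

#: Ranges observed in the study cohort (used as simulation defaults).
DEFAULT_GCS_RANGES = {"eye": (2, 4), "motor": (1, 4), "verbal": (1, 3)}

#: Aetiology labels with cohort-like frequencies.
CAUSES = ("Sudden cardiac arrest", "Traffic accident", "Stroke", "Fall")
CAUSE_WEIGHTS = (16 / 33, 9 / 33, 4 / 33, 4 / 33)

EPOCH_LENGTH_S = 12.0


@dataclass(frozen=True)
class ParticipantRecord:
    """One row of the cohort table: demographics plus GCS assessment."""

    participant_id: str
    age_range: tuple[int, int]
    cause: str
    interval_post_ictus: int  # months
    gcs_eye: int
    gcs_motor: int
    gcs_verbal: int

    @property
    def gcs_sum(self) -> int:
        return self.gcs_eye + self.gcs_motor + self.gcs_verbal

    def __post_init__(self) -> None:
        for comp, value in (
            ("eye", self.gcs_eye),
            ("motor", self.gcs_motor),
            ("verbal", self.gcs_verbal),
        ):
            lo, hi = GCS_BOUNDS[comp]
            if not lo <= value <= hi:
                raise ValueError(
                    f"GCS {comp} score {value} outside clinical range [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class SessionSpec:
    """A data-acquisition session: label plus the headsets employed."""

    label: str
    headsets: tuple[int, ...] = (5,)

    def __post_init__(self) -> None:
        for h in self.headsets:
            if h not in HEADSET_CHANNELS:
                raise ValueError(f"unknown headset {h!r}; expected 5 or 14")


def default_atypical_rates() -> dict[int, float]:
    """Default per-epoch atypical-state probability as a function of GCS sum.

    Monotone non-decreasing in GCS (the recovery hypothesis): 0.02 at the
    floor of the scale, rising by 0.03 per GCS point, capped at 0.5.
    """
    return {g: min(0.5, 0.02 + 0.03 * (g - 3)) for g in range(3, 16)}


@dataclass
class SimulationConfig:
    """Full description of a simulated study.

    The defaults mirror the acquisition setup: 128 Hz EEG, a 60 Hz gaze
    stream on a 1920x1080 screen, 12-s epochs, and three sessions (A with
    the 5-electrode headset, B with both, C with the 14-electrode one).
    """

    n_participants: int = 33
    sessions: tuple[SessionSpec, ...] = (
        SessionSpec("A", (5,)),
        SessionSpec("B", (5, 14)),
        SessionSpec("C", (14,)),
    )
    session_duration: float = 360.0  # seconds
    sampling_rate_eeg: float = 128.0
    sampling_rate_gaze: float = 60.0
    screen_size: tuple[int, int] = (1920, 1080)

    # GCS simulation ranges (inclusive), per component.
    gcs_ranges: dict = field(default_factory=lambda: dict(DEFAULT_GCS_RANGES))

    # Atypical-state mechanism: epochs flagged atypical swap the 1/f
    # background for a flatter spectral template (more high-frequency
    # power) and add a band-limited oscillation, a qualitatively distinct
    # spectral profile rather than a marginal perturbation.
    atypical_rate_map: dict = field(default_factory=default_atypical_rates)
    atypical_band: tuple[float, float] = (18.0, 24.0)
    atypical_amplitude: float = 30.0  # uV, amplitude of the band component
    background_exponent: float = 1.0  # 1/f power slope of typical epochs
    atypical_exponent: float = 0.0  # flat (white) slope during atypical epochs

    # Background / artifact parameters (amplitudes in uV).
    noise_level: float = 10.0
    oscillation_amplitude: float = 5.0
    spike_rate: float = 0.05  # spikes per second per channel
    spike_amplitude: float = 80.0

    # Gaze process.
    gaze_gcs_link: bool = True
    n_fixation_targets: int = 3  # used when gaze_gcs_link is False
    fixation_dispersion_px: float = 30.0
    min_dwell_s: float = 0.3
    mean_dwell_s: float = 1.0
    tracking_loss_rate: float = 0.02

    write_edf: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")
        if self.screen_size[0] <= 0 or self.screen_size[1] <= 0:
            raise ValueError("screen size must be positive")
        for comp, (lo, hi) in self.gcs_ranges.items():
            blo, bhi = GCS_BOUNDS[comp]
            if lo > hi or lo < blo or hi > bhi:
                raise ValueError(
                    f"GCS {comp} simulation range [{lo}, {hi}] outside "
                    f"clinical bounds [{blo}, {bhi}]"
                )
        for g, p in self.atypical_rate_map.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"atypical rate for GCS {g} not in [0, 1]: {p}")
        if not 0.0 <= self.tracking_loss_rate <= 1.0:
            raise ValueError("tracking_loss_rate must be in [0, 1]")

    def atypical_rate(self, gcs_sum: int) -> float:
        return float(self.atypical_rate_map.get(gcs_sum, 0.0))

    def derived_rng(self, *stream: int) -> np.random.Generator:
        """Generator for an independent stream keyed by integers."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, *map(int, stream)])
        )


# stream identifiers for derived seeds
_STREAM_COHORT = 1
_STREAM_EEG = 2
_STREAM_GAZE = 3
_STREAM_EVENTS = 4


def generate_cohort(config: SimulationConfig) -> list[ParticipantRecord]:
    """Draw a cohort of participants with GCS scores in the configured ranges.

    Deterministic given ``config.seed``; component scores are uniform within
    their ranges and the GCS sum is their exact sum.
    """
    rng = config.derived_rng(_STREAM_COHORT)
    records = []
    for i in range(config.n_participants):
        decade = int(rng.integers(1, 7))  # age decades 11-20 .. 61-70
        eye = int(rng.integers(*config.gcs_ranges["eye"], endpoint=True))
        motor = int(rng.integers(*config.gcs_ranges["motor"], endpoint=True))
        verbal = int(rng.integers(*config.gcs_ranges["verbal"], endpoint=True))
        records.append(
            ParticipantRecord(
                participant_id=f"P{i + 1:02d}",
                age_range=(decade * 10 + 1, (decade + 1) * 10),
                cause=str(rng.choice(CAUSES, p=CAUSE_WEIGHTS)),
                interval_post_ictus=int(rng.integers(4, 44)),
                gcs_eye=eye,
                gcs_motor=motor,
                gcs_verbal=verbal,
            )
        )
    return records


def _pink_noise(
    rng: np.random.Generator, n: int, fs: float, level: float, exponent: float = 1.0
) -> np.ndarray:
    """1/f^exponent power-shaped Gaussian noise, std scaled to ``level``."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.empty_like(freqs)
    shape[0] = 0.0
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) * shape
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd > 0:
        x *= level / sd
    return x


@dataclass
class EEGSynthesis:
    """Raw synthetic EEG plus the ground-truth atypical-epoch flags."""

    samples: np.ndarray  # channels x time, uV
    channel_labels: tuple[str, ...]
    sampling_rate: float
    atypical_epochs: np.ndarray  # bool per complete 12-s epoch


def synthesize_eeg(
    participant: ParticipantRecord,
    headset: int,
    duration: float,
    config: SimulationConfig,
    seed: int,
) -> EEGSynthesis:
    """Simulate a multi-channel EEG recording for one participant.

    Each complete 12-s epoch is independently flagged atypical with
    probability ``config.atypical_rate(participant.gcs_sum)``; atypical
    epochs follow a distinct spectral template — a flattened background
    slope (``atypical_exponent`` instead of ``background_exponent``) plus
    a band-limited oscillation inside ``config.atypical_band`` with
    amplitude ``config.atypical_amplitude`` on every channel.  Background
    noise, theta/alpha oscillations and spike artifacts are drawn per
    epoch so that epochs are exchangeable apart from the planted atypical
    effect.
    """
    if headset not in HEADSET_CHANNELS:
        raise ValueError(f"unknown headset {headset!r}; expected 5 or 14")
    if duration <= 0:
        raise ValueError("duration must be positive")
    labels = HEADSET_CHANNELS[headset]
    fs = config.sampling_rate_eeg
    n_total = int(round(duration * fs))
    n_chan = len(labels)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _STREAM_EEG]))

    samples = np.zeros((n_chan, n_total))
    epoch_samples = int(round(EPOCH_LENGTH_S * fs))
    n_epochs = n_total // epoch_samples
    rate = config.atypical_rate(participant.gcs_sum)
    atypical = rng.random(n_epochs) < rate if n_epochs else np.zeros(0, bool)

    t_full = np.arange(n_total) / fs
    # Segment boundaries: complete epochs, then a trailing remainder.
    bounds = [(k * epoch_samples, (k + 1) * epoch_samples) for k in range(n_epochs)]
    if n_epochs * epoch_samples < n_total:
        bounds.append((n_epochs * epoch_samples, n_total))

    for k, (lo, hi) in enumerate(bounds):
        t = t_full[lo:hi]
        n_seg = hi - lo
        is_atypical = k < n_epochs and bool(atypical[k])
        # per-epoch oscillation parameters, shared phase offsets per channel.
        # Atypical epochs swap the whole oscillatory profile: theta/alpha
        # vanish and a strong component inside the atypical band appears,
        # over a flattened background slope — a distinct spectral template
        # rather than a perturbation of the usual one.
        f_theta = rng.uniform(4.0, 7.0)
        f_alpha = rng.uniform(8.0, 12.0)
        amp_theta = config.oscillation_amplitude * rng.lognormal(0.0, 0.3)
        amp_alpha = config.oscillation_amplitude * rng.lognormal(0.0, 0.3)
        f_atyp = rng.uniform(*config.atypical_band) if is_atypical else 0.0
        if is_atypical:
            amp_theta = amp_alpha = 0.0
        exponent = config.atypical_exponent if is_atypical else config.background_exponent
        for c in range(n_chan):
            x = _pink_noise(rng, n_seg, fs, config.noise_level, exponent)
            x += amp_theta * np.sin(2 * np.pi * f_theta * t + rng.uniform(0, 2 * np.pi))
            x += amp_alpha * np.sin(2 * np.pi * f_alpha * t + rng.uniform(0, 2 * np.pi))
            if is_atypical:
                x += config.atypical_amplitude * np.sin(
                    2 * np.pi * f_atyp * t + rng.uniform(0, 2 * np.pi)
                )
            # spike artifacts: Poisson arrivals, exponential-decay transients
            n_spikes = rng.poisson(config.spike_rate * n_seg / fs)
            for _ in range(n_spikes):
                i0 = int(rng.integers(0, n_seg))
                tail = min(n_seg - i0, int(0.25 * fs))
                kernel = np.exp(-np.arange(tail) / (0.05 * fs))
                x[i0 : i0 + tail] += rng.choice((-1.0, 1.0)) * config.spike_amplitude * kernel
            samples[c, lo:hi] = x

    return EEGSynthesis(
        samples=samples,
        channel_labels=labels,
        sampling_rate=fs,
        atypical_epochs=atypical,
    )


@dataclass
class GazeSynthesis:
    """Synthetic gaze stream: sample times and on-screen pixel coordinates."""

    timestamps: np.ndarray  # seconds
    x: np.ndarray  # pixels
    y: np.ndarray  # pixels
    screen_size: tuple[int, int]


def synthesize_gaze(
    participant: ParticipantRecord,
    duration: float,
    config: SimulationConfig,
    seed: int,
) -> GazeSynthesis:
    """Simulate an eye-tracker stream as a fixation-saccade process.

    Fixation centers are drawn in the central region of the screen; dwell
    times are exponential with a configurable floor; within-fixation jitter
    is isotropic Gaussian.  When ``gaze_gcs_link`` is on, higher GCS yields
    more fixation targets and tighter dispersion (more structured,
    multi-target scanning); otherwise the target count is fixed by
    ``n_fixation_targets``.  Samples are lost to tracking dropout with
    probability ``tracking_loss_rate``, in which case the coordinate is
    placed off-screen.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    w, h = config.screen_size
    if w <= 0 or h <= 0:
        raise ValueError("screen size must be positive")
    fs = config.sampling_rate_gaze
    n = int(round(duration * fs))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _STREAM_GAZE]))

    if config.gaze_gcs_link:
        gcs = participant.gcs_sum
        n_targets = int(np.clip(1 + (gcs - 3) // 2, 1, 6))
        dispersion = config.fixation_dispersion_px * (1.5 - 0.75 * (gcs - 3) / 12.0)
    else:
        n_targets = max(1, int(config.n_fixation_targets))
        dispersion = config.fixation_dispersion_px

    targets = np.column_stack(
        [rng.uniform(0.1 * w, 0.9 * w, n_targets), rng.uniform(0.1 * h, 0.9 * h, n_targets)]
    )

    x = np.empty(n)
    y = np.empty(n)
    i = 0
    current = int(rng.integers(n_targets))
    while i < n:
        dwell = max(config.min_dwell_s, rng.exponential(config.mean_dwell_s))
        n_fix = min(n - i, max(1, int(round(dwell * fs))))
        cx, cy = targets[current]
        x[i : i + n_fix] = cx + (rng.standard_normal(n_fix) * dispersion if dispersion > 0 else 0.0)
        y[i : i + n_fix] = cy + (rng.standard_normal(n_fix) * dispersion if dispersion > 0 else 0.0)
        i += n_fix
        if n_targets > 1:
            nxt = int(rng.integers(n_targets - 1))
            current = nxt if nxt < current else nxt + 1

    lost = rng.random(n) < config.tracking_loss_rate
    x[lost] = -100.0
    y[lost] = -100.0
    t = np.arange(n) / fs
    return GazeSynthesis(timestamps=t, x=x, y=y, screen_size=(w, h))


def generate_events(
    duration: float, config: SimulationConfig, seed: int, activity_duration: float = 60.0
) -> pd.DataFrame:
    """Therapist event log: activity blocks plus session start/end markers."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _STREAM_EVENTS]))
    rows = [{"timestamp_s": 0.0, "event_label": "session_start", "activity_id": ""}]
    t = 0.0
    while t < duration:
        rows.append(
            {
                "timestamp_s": round(t, 3),
                "event_label": "activity_start",
                "activity_id": int(rng.integers(1, 9)),
            }
        )
        t += activity_duration
    rows.append({"timestamp_s": round(duration, 3), "event_label": "session_end", "activity_id": ""})
    return pd.DataFrame(rows, columns=["timestamp_s", "event_label", "activity_id"])


@dataclass
class DatasetLayout:
    """Paths and bookkeeping for a generated on-disk dataset."""

    root: Path
    cohort_path: Path
    ground_truth_path: Path
    eeg_paths: list[Path]
    gaze_paths: list[Path]
    event_paths: list[Path]
    manifest: pd.DataFrame  # one row per (participant, session, headset)


def generate_session_dataset(config: SimulationConfig, out_dir: str | Path) -> DatasetLayout:
    """Write a complete simulated study to ``out_dir``.

    Produces per-(participant, session, headset) EEG CSVs (optionally EDF),
    per-(participant, session) gaze and event-log CSVs, a cohort metadata
    table mirroring the clinical summary (age range, cause, interval
    post-ictus, GCS components and sum), and a ground-truth sidecar listing
    the atypical flag of every complete 12-s epoch for recovery tests.
    """
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)

    cohort_df = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in cohort],
            "age_range": [f"{p.age_range[0]}-{p.age_range[1]}" for p in cohort],
            "cause": [p.cause for p in cohort],
            "interval_post_ictus": [p.interval_post_ictus for p in cohort],
            "gcs_eye": [p.gcs_eye for p in cohort],
            "gcs_motor": [p.gcs_motor for p in cohort],
            "gcs_verbal": [p.gcs_verbal for p in cohort],
            "gcs_sum": [p.gcs_sum for p in cohort],
        }
    )
    cohort_path = root / "cohort.csv"
    cohort_df.to_csv(cohort_path, index=False)

    eeg_paths: list[Path] = []
    gaze_paths: list[Path] = []
    event_paths: list[Path] = []
    gt_rows = []
    manifest_rows = []

    for s_idx, session in enumerate(config.sessions):
        for p_idx, participant in enumerate(cohort):
            base_seed = [config.seed & 0x7FFFFFFF, s_idx, p_idx]
            gaze = synthesize_gaze(
                participant,
                config.session_duration,
                config,
                seed=_mix(base_seed, 0),
            )
            gpath = root / f"gaze_{participant.participant_id}_{session.label}.csv"
            pd.DataFrame(
                {"timestamp_s": gaze.timestamps, "x_px": gaze.x, "y_px": gaze.y}
            ).to_csv(gpath, index=False, float_format="%.4f")
            gaze_paths.append(gpath)

            events = generate_events(
                config.session_duration, config, seed=_mix(base_seed, 1)
            )
            epath = root / f"events_{participant.participant_id}_{session.label}.csv"
            events.to_csv(epath, index=False)
            event_paths.append(epath)

            for headset in session.headsets:
                eeg = synthesize_eeg(
                    participant,
                    headset,
                    config.session_duration,
                    config,
                    seed=_mix(base_seed, 10 + headset),
                )
                name = f"eeg_{participant.participant_id}_{session.label}_{headset}"
                csv_path = root / f"{name}.csv"
                pd.DataFrame(eeg.samples.T, columns=list(eeg.channel_labels)).to_csv(
                    csv_path, index=False, float_format="%.4f"
                )
                eeg_paths.append(csv_path)
                if config.write_edf:
                    from .io import write_edf

                    write_edf(
                        root / f"{name}.edf",
                        eeg.samples,
                        list(eeg.channel_labels),
                        eeg.sampling_rate,
                    )
                for k, flag in enumerate(eeg.atypical_epochs):
                    gt_rows.append(
                        {
                            "participant_id": participant.participant_id,
                            "session": session.label,
                            "headset": headset,
                            "epoch_index": k,
                            "is_atypical": int(flag),
                        }
                    )
                manifest_rows.append(
                    {
                        "participant_id": participant.participant_id,
                        "session": session.label,
                        "headset": headset,
                        "eeg_path": csv_path.name,
                        "gaze_path": gpath.name,
                        "events_path": epath.name,
                        "gcs_eye": participant.gcs_eye,
                        "gcs_motor": participant.gcs_motor,
                        "gcs_verbal": participant.gcs_verbal,
                        "gcs_sum": participant.gcs_sum,
                    }
                )

    gt_path = root / "ground_truth.csv"
    pd.DataFrame(
        gt_rows,
        columns=["participant_id", "session", "headset", "epoch_index", "is_atypical"],
    ).to_csv(gt_path, index=False)
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(root / "sessions.csv", index=False)

    return DatasetLayout(
        root=root,
        cohort_path=cohort_path,
        ground_truth_path=gt_path,
        eeg_paths=eeg_paths,
        gaze_paths=gaze_paths,
        event_paths=event_paths,
        manifest=manifest,
    )


def _mix(base: Sequence[int], extra: int) -> int:
    """Fold a seed path into a single non-negative 31-bit integer."""
    h = 0
    for v in (*base, extra):
        h = (h * 1000003 + int(v) + 1) & 0x7FFFFFFF
    return h
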