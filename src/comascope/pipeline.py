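"""End-to-end pipeline: simulate -> ingest -> featurize -> train -> encode -> analyze.

One :class:`PipelineConfig` drives every stage with paper-anchored feature
defaults (12-s epochs, FFT 256 with 90% overlap and a Tukey(0.25) window,
64 x 64 gaze grid, 32-d embedding) and a single root seed from which every
stage derives its own stream.  ``run_pipeline`` executes the stages in
order, trains one autoencoder per headset present in the data, and returns
a :class:`RunReport` carrying per-stage counts, training histories and the
fitted variance analysis; tabular outputs are written to the configured
directory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import EmbeddingVarianceModel, EmbeddingVarianceResults
from .autoencoder import AutoencoderConfig, MultimodalAutoencoder, TrainingHistory
from .eeg import compute_spectrogram, cut_epochs, harmonize_channels, standardize_spectrogram
from .gaze import compute_heatmap, normalize_heatmap
from .io import EventLog, GazeRecording, RawEEGRecording, align_session, read_eeg, read_gaze
from .simulate import SimulationConfig, _mix, generate_cohort, generate_session_dataset, synthesize_eeg, synthesize_gaze

__all__ = ["FeatureConfig", "PipelineConfig", "RunReport", "run_pipeline", "featurize_bundle"]


@dataclass
class FeatureConfig:
    """Feature-extraction parameters shared by both modalities."""

    epoch_length: float = 12.0
    fft_size: int = 256
    overlap: float = 0.9
    tukey_alpha: float = 0.25
    log_power: bool = False
    grid_size: tuple[int, int] = (64, 64)


@dataclass
class PipelineConfig:
    """Composition of all stage configurations plus run-level options."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    ae: AutoencoderConfig = field(default_factory=AutoencoderConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    out_dir: str | Path = "comascope_run"
    seed: int = 0
    write_dataset: bool = True  # round-trip the dataset through disk
    make_figures: bool = False

    def __post_init__(self) -> None:
        # the root seed flows into the simulation and the model seeds
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def desk(cls, **overrides) -> "PipelineConfig":
        """Small-cohort CPU profile used for testing and quick runs."""
        defaults = dict(
            sim=SimulationConfig(
                n_participants=4,
                sessions=(SimulationConfig().sessions[0],),
                session_duration=120.0,
            ),
            ae=AutoencoderConfig.desk(),
        )
        defaults.update(overrides)
        return cls(**defaults)


def featurize_bundle(bundle, features: FeatureConfig, meta: dict | None = None):
    """Turn one aligned session bundle into per-epoch feature arrays.

    Returns ``(eeg_tensors, heatmaps, rows)`` where the tensors are
    standardized spectrograms (epochs x 15 x F x T), the heatmaps are
    normalized gaze grids (epochs x H x W) and ``rows`` is per-epoch
    provenance for the manifest.
    """
    pairs = cut_epochs(bundle, epoch_length=features.epoch_length)
    eeg_out, egt_out, rows = [], [], []
    screen = bundle.gaze.screen_size
    for pair in pairs:
        spec = compute_spectrogram(
            pair.eeg,
            sampling_rate=bundle.eeg.sampling_rate,
            fft_size=features.fft_size,
            overlap=features.overlap,
            tukey_alpha=features.tukey_alpha,
            log_power=features.log_power,
        )
        spec = standardize_spectrogram(spec)
        hm = normalize_heatmap(
            compute_heatmap(pair.gaze_x, pair.gaze_y, screen, features.grid_size)
        )
        eeg_out.append(spec.values)
        egt_out.append(hm.grid)
        row = {
            "epoch_id": pair.epoch_id,
            "participant_id": pair.participant_id,
            "session": pair.session_label,
            "headset": pair.headset,
            "epoch_index": pair.epoch_index,
            "start_s": pair.start,
            "n_gaze": len(pair.gaze_t),
            "n_offscreen": hm.n_offscreen,
        }
        row.update(meta or {})
        rows.append(row)
    if not pairs:
        return np.empty((0,)), np.empty((0,)), rows
    return np.stack(eeg_out), np.stack(egt_out), rows


@dataclass
class RunReport:
    """Everything a pipeline run produced, with per-stage bookkeeping."""

    config: PipelineConfig
    cohort: pd.DataFrame
    manifest: pd.DataFrame
    epoch_counts: dict[int, int]
    histories: dict[int, TrainingHistory]
    embeddings: pd.DataFrame
    results: EmbeddingVarianceResults | None
    notes: list[str] = field(default_factory=list)
    outputs: dict[str, Path] = field(default_factory=dict)


def _session_recordings(config: SimulationConfig, dataset_dir: Path | None):
    """Yield (participant, session, headset, eeg, gaze, events) per recording.

    Reads back from a written dataset when ``dataset_dir`` is given
    (exercising the file formats); otherwise synthesizes in memory with
    the identical derived seeds.
    """
    cohort = generate_cohort(config)
    for s_idx, session in enumerate(config.sessions):
        for p_idx, participant in enumerate(cohort):
            base = [config.seed & 0x7FFFFFFF, s_idx, p_idx]
            if dataset_dir is not None:
                gaze = read_gaze(
                    dataset_dir / f"gaze_{participant.participant_id}_{session.label}.csv",
                    screen_size=config.screen_size,
                    participant_id=participant.participant_id,
                    session_label=session.label,
                )
            else:
                g = synthesize_gaze(participant, config.session_duration, config, seed=_mix(base, 0))
                gaze = GazeRecording(
                    timestamps=g.timestamps,
                    x=g.x,
                    y=g.y,
                    screen_size=g.screen_size,
                    participant_id=participant.participant_id,
                    session_label=session.label,
                )
            for headset in session.headsets:
                if dataset_dir is not None:
                    eeg = read_eeg(
                        dataset_dir
                        / f"eeg_{participant.participant_id}_{session.label}_{headset}.csv",
                        participant_id=participant.participant_id,
                        session_label=session.label,
                    )
                    eeg.sampling_rate = config.sampling_rate_eeg
                else:
                    e = synthesize_eeg(
                        participant,
                        headset,
                        config.session_duration,
                        config,
                        seed=_mix(base, 10 + headset),
                    )
                    eeg = RawEEGRecording(
                        samples=e.samples,
                        channel_labels=e.channel_labels,
                        sampling_rate=e.sampling_rate,
                        participant_id=participant.participant_id,
                        session_label=session.label,
                    )
                yield participant, session, headset, eeg, gaze, EventLog()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order and return the run report.

    Any stage failure propagates with the stage name prepended, so a run
    aborts loudly rather than producing partial tables.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    notes: list[str] = []

    # -- simulate ---------------------------------------------------------
    dataset_dir = None
    if config.write_dataset:
        layout = generate_session_dataset(config.sim, out_dir / "dataset")
        dataset_dir = layout.root
        cohort_df = pd.read_csv(layout.cohort_path)
    else:
        cohort = generate_cohort(config.sim)
        cohort_df = pd.DataFrame(
            {
                "participant_id": [p.participant_id for p in cohort],
                "gcs_eye": [p.gcs_eye for p in cohort],
                "gcs_motor": [p.gcs_motor for p in cohort],
                "gcs_verbal": [p.gcs_verbal for p in cohort],
                "gcs_sum": [p.gcs_sum for p in cohort],
            }
        )
    gcs_by_pid = cohort_df.set_index("participant_id")[
        ["gcs_eye", "gcs_motor", "gcs_verbal", "gcs_sum"]
    ].to_dict("index")

    # -- ingest + featurize ----------------------------------------------
    per_headset: dict[int, dict[str, list]] = {}
    try:
        for participant, session, headset, eeg, gaze, events in _session_recordings(
            config.sim, dataset_dir
        ):
            bundle = align_session(harmonize_channels(eeg), gaze, events)
            meta = dict(gcs_by_pid[participant.participant_id])
            eeg_t, egt_t, rows = featurize_bundle(bundle, config.features, meta=meta)
            if not rows:
                notes.append(
                    f"featurize: no epochs for {participant.participant_id}/"
                    f"{session.label}/{headset}"
                )
                continue
            store = per_headset.setdefault(headset, {"eeg": [], "egt": [], "rows": []})
            store["eeg"].append(eeg_t)
            store["egt"].append(egt_t)
            store["rows"].extend(rows)
    except Exception as exc:  # pragma: no cover - defensive context
        raise RuntimeError(f"stage featurize failed: {exc}") from exc

    for headset in (5, 14):
        if headset not in per_headset:
            notes.append(f"train: no {headset}-electrode sessions; model skipped")

    # -- train + encode ----------------------------------------------------
    histories: dict[int, TrainingHistory] = {}
    emb_frames = []
    epoch_counts = {}
    for headset, store in sorted(per_headset.items()):
        eeg_all = np.concatenate(store["eeg"])
        egt_all = np.concatenate(store["egt"])
        manifest_rows = pd.DataFrame(store["rows"])
        epoch_counts[headset] = len(manifest_rows)
        ae_cfg = dataclasses.replace(
            config.ae, seed=_mix([config.seed & 0x7FFFFFFF, headset], 500)
        )
        model = MultimodalAutoencoder(
            ae_cfg, eeg_shape=eeg_all.shape[1:], egt_shape=egt_all.shape[1:]
        )
        try:
            histories[headset] = model.fit(eeg_all, egt_all)
        except Exception as exc:
            raise RuntimeError(f"stage train (headset {headset}) failed: {exc}") from exc
        z = model.encode(eeg_all, egt_all)
        emb = pd.DataFrame(z, columns=[f"e{i + 1}" for i in range(z.shape[1])])
        emb_frames.append(pd.concat([manifest_rows.reset_index(drop=True), emb], axis=1))
        histories[headset].records.to_csv(out_dir / f"history_{headset}.csv", index=False)

    if not emb_frames:
        raise RuntimeError("stage train failed: no epochs were produced by any session")
    embeddings = pd.concat(emb_frames, ignore_index=True)
    manifest = embeddings.drop(
        columns=[c for c in embeddings.columns if c.startswith("e") and c[1:].isdigit()]
    )

    # -- analyze ------------------------------------------------------------
    results = None
    try:
        results = EmbeddingVarianceModel.from_frame(
            embeddings.drop(
                columns=["epoch_index", "start_s", "n_gaze", "n_offscreen", "session", "epoch_id"]
            )
        ).fit()
    except Exception as exc:
        raise RuntimeError(f"stage analyze failed: {exc}") from exc

    # -- write outputs -------------------------------------------------------
    outputs: dict[str, Path] = {}
    emb_path = out_dir / "embeddings.csv"
    embeddings.to_csv(emb_path, index=False)
    outputs["embeddings"] = emb_path
    vt_path = out_dir / "variance_table.csv"
    results.variance_table.to_csv(vt_path, index=False)
    outputs["variance_table"] = vt_path
    test_rows = []
    for (headset, comp), t in sorted(results.tests.items()):
        for a in t.pairwise_p.index:
            for b in t.pairwise_p.columns:
                test_rows.append(
                    {
                        "headset": headset,
                        "gcs_component": comp,
                        "bf_statistic": t.bf_statistic,
                        "bf_p": t.bf_p,
                        "group_a": a,
                        "group_b": b,
                        "pairwise_p": t.pairwise_p.loc[a, b],
                    }
                )
    tests_path = out_dir / "variance_tests.csv"
    pd.DataFrame(test_rows).to_csv(tests_path, index=False)
    outputs["variance_tests"] = tests_path
    (out_dir / "report.txt").write_text(results.summary() + "\n")
    outputs["report"] = out_dir / "report.txt"

    if config.make_figures and len(embeddings) >= 3:
        import matplotlib.pyplot as plt

        for color_by in ("gcs_sum", "gcs_eye", "gcs_motor", "gcs_verbal", "headset"):
            if color_by in embeddings.columns:
                _, fig = results.pca(color_by=color_by)
                fig_path = out_dir / f"pca_{color_by}.png"
                fig.savefig(fig_path, dpi=120)
                plt.close(fig)
                outputs[f"pca_{color_by}"] = fig_path

    return RunReport(
        config=config,
        cohort=cohort_df,
        manifest=manifest,
        epoch_counts=epoch_counts,
        histories=histories,
        embeddings=embeddings,
        results=results,
        notes=notes,
        outputs=outputs,
    )
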