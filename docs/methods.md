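# Methods

This note documents the models, parameters and numerical choices behind
`comascope`, what the synthetic-data generator does and does not emulate,
and the limits of what the test suite can show.

## Signal representations

**EEG.** Both supported headsets sample at 128 Hz. The 5-electrode
device records AF3, AF4, P7, P8, Pz; the 14-electrode device records
AF3, AF4, F7, F3, FC5, T7, P7, O1, O2, P8, T8, FC6, F4, F8. Every
recording is padded to the 15-channel union (fixed order AF3, AF4, F3,
F4, F7, F8, FC5, FC6, O1, O2, P7, P8, Pz, T7, T8) with zero placeholder
signals, so a single network architecture serves both devices: 10
placeholders for the 5-electrode headset, 1 (Pz) for the 14-electrode
one.

Sessions are cut into non-overlapping 12-s epochs starting at the left
edge of the EEG/gaze overlap window; the trailing remainder is dropped.
Gaze samples are assigned to epochs by half-open membership
`[start, end)`, making the partition exact. Per channel and epoch we
compute `scipy.signal.spectrogram` with `nperseg=256`,
`noverlap=floor(0.9*256)=230` (hop 26) and a Tukey window with shape
0.25 — the library's default window — in power-spectral-density mode.
A 1536-sample epoch yields 129 frequency bins x 50 time frames. Each
channel's spectrogram is z-scored over all its (f, t) cells using the
population standard deviation. Choices worth flagging:

* magnitudes are **not** log-transformed before standardization
  (``log_power`` flag available); the z-score already removes the scale,
  and the default keeps the representation closest to the raw PSD;
* zero-variance channels (the placeholders) standardize to all zeros
  rather than dividing by zero, keeping them neutral for the network;
* standardization is idempotent to float precision.

**Eye gaze.** Gaze epochs become 64 x 64 fixation-frequency grids over
the screen (x rightward, y downward, row-major indexing, half-open cell
bounds). A per-pixel map would be needlessly large as a network input;
64 x 64 keeps about 30 x 17 screen pixels per cell on a 1920 x 1080
display. Off-screen samples (tracking loss) are excluded and counted,
not clamped: clamping would pile artificial mass on the borders. Grids
are normalized to unit mass; the x/y projections (column/row sums) are
exact marginals of the grid and are carried as auxiliary features — the
network consumes the 2-D grid.

## The multimodal autoencoder

Encoder: one convolutional branch per modality — 3 blocks of 3x3
convolutions with stride 2 and ReLU (`ceil(n/2)` downsampling per block)
— whose flattened outputs are concatenated and reduced by a linear dense
layer to the 32-dimensional embedding. Decoder: a ReLU dense expansion
back to the concatenated feature size, split per branch, then 3 blocks
of nearest-neighbour 2x upsampling + 3x3 convolution, a linear output
convolution, and a crop to the exact input shape. Placeholder EEG
channels participate in the loss with their zero-filled targets. The
exact filter counts are configuration, not architecture: the reference
profile uses (8, 16, 16) filters.

Training minimizes `w_eeg * MSE(EEG) + w_egt * MSE(EGT)` with
`w_eeg = 1`, `w_egt = 100`, using ADAM at learning rate 1e-4, batch 128,
for 200 passes over a 90/10 train/validation split drawn with a seeded
shuffle. One "iteration" is one full pass over the training set. The
network never sees GCS labels. The implementation is plain NumPy
(im2col convolutions with hand-written reverse-mode gradients, float32
by default with a float64 mode used by the gradient tests); runs are
bit-reproducible given the seed, and batched inference matches per-item
inference to float32 summation tolerance (~1e-6).

**Desk profile.** For CPU-scale work (tests, examples) the `desk`
profile shrinks the model to (4, 8, 8) filters, batch 16, 20 iterations
at learning rate 3e-3. The higher rate compensates for the short
schedule: training passes through an early phase in which the decoder is
still uninformative and the loss is best reduced by shrinking embedding
variance — a phase that (dis)places rare inputs unpredictably — before
reaching the regime where reconstruction requires encoding input
structure and rare patterns land far from the embedding bulk. Twenty
desk iterations at 3e-3 reach that regime; the same iteration count at
1e-4 does not. The paper-scale profile is untouched by this choice.

## Variance-based separability analysis

Embeddings of one headset's epochs form one cluster; its center is the
coordinatewise mean, and each epoch's statistic is the Euclidean
distance to that center in the full 32-d space (PCA is used only for
plots). Per headset and GCS component, groups are the unique label
values; we report the sample variance (divisor n-1) and size of each
group. Groups with fewer than two points are flagged and excluded from
testing.

The omnibus test transforms each group by `x <- |x - x̄|` and applies a
one-way ANOVA F test to the transformed values, with p from
F(k-1, N-k). The transform uses the **group mean** as center — the
form the analysis is defined with here — while `center="median"`
selects the classical Brown–Forsythe variant; with a mean center the
procedure is algebraically Levene's test, and the test suite pins it to
`scipy.stats.levene(center="mean")` on random data. If every
transformed value is identical the degenerate case reports (F=0, p=1).

The post-hoc is Dunn's procedure on the same transformed values: pooled
average ranks with the standard tie correction, pairwise z statistics
`(R̄_i - R̄_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))`, and
two-sided normal p values. Raw p values are reported by default (the
matrices are meant to be read cell by cell, flagged at 0.05); Holm's
step-down correction is available. Pearson correlations relate
per-participant distance variance to GCS.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes,
not realistic neurophysiology:

* **Cohort.** GCS components drawn uniformly within the clinically
  observed simulation ranges (eye 2–4, motor 1–6 capped at 4, verbal
  1–3); the sum is the exact component sum (4–11 under the defaults).
  Age decade, aetiology (cardiac arrest, traffic accident, stroke,
  fall, with cohort-like frequencies) and months post-ictus are
  decorative metadata.
* **EEG.** Per epoch: 1/f-power background noise (10 uV), theta
  (4–7 Hz) and alpha (8–12 Hz) oscillations (5 uV, lognormal amplitude
  jitter), and Poisson spike artifacts (0.05/s per channel, 80 uV,
  50-ms exponential decay) imitating electrode-contact loss. All
  per-epoch parameters are redrawn each epoch, so epochs are
  exchangeable apart from the planted effect — this is what makes the
  null calibration of the end-to-end test meaningful.
* **Atypical states.** Each complete epoch is flagged atypical with a
  probability given by `atypical_rate_map[gcs_sum]` (default monotone:
  0.02 + 0.03·(GCS-3), capped at 0.5). Atypical epochs follow a
  *distinct spectral template*: the background slope flattens (exponent
  0 instead of 1), the theta/alpha profile vanishes, and a 30 uV
  component appears inside 18–24 Hz. Distinctness matters more than
  amplitude: per-channel standardization makes every epoch tensor unit
  scale, so what separates an atypical epoch from a typical one is the
  decorrelation of their spectral shapes, not absolute power. A
  ground-truth sidecar records every flag for recovery tests, and the
  rate map can be made flat (or the gaze link switched off) to produce
  null datasets.
* **Gaze.** A fixation–saccade process: targets drawn in the central
  80 % of the screen, exponential dwell times with a 0.3-s floor,
  Gaussian within-fixation jitter, 2 % tracking dropout placed
  off-screen. With the GCS link on, higher GCS gives more fixation
  targets (1–6) and tighter dispersion — more structured scanning; the
  link has an off switch for null cohorts.

All randomness flows from one root seed through derived
`SeedSequence` streams, so identical configurations give identical
datasets (byte-identical CSVs) and each stage can be regenerated
independently.

What the generator does **not** emulate: real ABI spectral signatures,
inter-subject physiological variability, non-stationarity within
epochs, realistic artifact morphology beyond spikes and broadband
noise, or any causal link between gaze behaviour and EEG content.
Passing recovery tests therefore shows that the pipeline detects the
planted variance mechanism under its own assumptions — not that the
mechanism exists in patients.

## The end-to-end recovery study

`comascope.experiments.run_recovery_replicate` runs the whole chain —
generator, featurization, desk-profile training, encoding, variance
analysis — under fixed conditions: three participants at GCS sums
5/8/11, one 360-s 5-electrode session each (30 epochs per group),
atypical rates 0.05/0.25/0.45 under the effect condition, constant 0.25
with the gaze link off under the null. The effect condition is expected
to produce non-decreasing per-GCS distance variance and a Brown–Forsythe
rejection at alpha 0.05 in nearly all replicates; the null condition is
expected to reject at about the nominal rate. Problem sizes here (three
participants, 90 epoch pairs, the desk model) are the package's
CPU-scale choice; the mechanism is scale-free and the paper-scale
profile can be substituted via `ae_config`.

## Numerical choices and degenerate inputs

* Epoch boundaries use a 1e-9 s tolerance before flooring, so a
  nominally exact 120-s window yields exactly 10 epochs.
* EDF output is 16-bit with per-signal physical scaling over 1-s
  records; round-trips are exact to one quantization step. CSV floats
  are written at 1e-4 precision.
* Gaze readers enforce strictly increasing timestamps by greedy prefix
  selection and count every dropped row; EEG readers reject rather than
  repair malformed values.
* `brown_forsythe` requires every group n >= 2 and k >= 2;
  `group_variances` flags smaller groups instead of testing them.
* The PCA view zero-fills the second coordinate when the input has
  fewer than two usable components.

## Known limitations

* The desk-profile autoencoder is a small early-schedule model; its
  embeddings are not converged representations, and embedding-space
  geometry at this scale is sensitive to the optimizer trajectory (see
  the desk-profile discussion above).
* The EGT branch contributes little to the embedding under the default
  scaling (unit-mass heatmaps are small against z-scored spectrograms);
  the 100x loss weight compensates on the reconstruction side, as
  specified, but most embedding variance is EEG-driven at desk scale.
* The variance statistic is descriptive: no per-patient diagnostic
  score, no causal interpretation, and no multiplicity control across
  the (headset x component) table unless Holm is requested.
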