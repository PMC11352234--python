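# Methods

## Problem setting

A therapy session yields three single-channel EEG recordings per subject
— before (≈ 60 s), during (≈ 5 min), and after (≈ 60 s) — from the fp1
electrode of a consumer biosensor at 512 samples/s. The scientific
question is whether brain activity during the therapy differs measurably
from resting activity, and by how much. The package answers it two ways:
descriptively (band powers, self-affine crossovers) and with a learned
similarity metric whose output is converted to a decibel biomarker.

## Synthetic cohorts

No recordings from this protocol are publicly available, so cohorts are
synthesized with the structure the pipeline assumes. Each recording is a
sum of

- five band-limited components, one per rhythm (δ 0.5–4, θ 4–8, α 8–12,
  β 12–30, γ 30–60 Hz), each Gaussian white noise band-pass filtered to
  its range and scaled to a requested RMS amplitude in µV (a
  pure-sinusoid mode places tones at band centers for analytic tests);
- a 1/f^k background (default exponent k = 1, "pink"), generated by
  spectral shaping of white noise;
- additive white measurement noise;

plus a poor-signal series reading 200 for the first 0.5 s and 0 after,
emulating sensor stabilization. Phase durations default to the protocol
(60/300/60 s) at 512 samples/s. Subject i, phase p uses seed
`master + 1000·i + p`, so any single recording can be regenerated alone.

The default resting profile is α-dominant (δ4, θ3, α6, β2, γ1 µV over a
3 µV pink background, 1 µV white noise). There is no published
quantitative account of how the therapy shifts band powers, so the
default therapy profile is a documented placeholder: β and γ boosted
(6 and 4 µV), α suppressed (2 µV) — a shift toward faster rhythms under
external stimulation. What the synthetic cohorts do **not** model:
blink/EMG artifacts (only an amplitude threshold exists downstream),
non-stationarity within a phase, inter-subject variability of band
profiles (all subjects share the two profiles, differing only in noise
realization), and volume-conduction or multi-channel structure. Passing
tests therefore demonstrate that the pipeline recovers a band-structure
difference when one exists — not that real therapy sessions contain one.

## Preprocessing

Zero-phase (forward–backward) 4th-order Butterworth band-pass, default
0.5–60 Hz. Forward–backward filtering is used so event-related
waveforms keep their latencies. The filtfilt edge extension is
even-symmetric with padding sized to the slow low-frequency corner
(3·fs/low samples): with the conventional odd extension, the 0.5 Hz
pole rings across recordings of a few seconds and leaks stop-band tones
at several percent RMS; the even extension keeps stop-band leakage near
the filter's design attenuation. Mains interference is removed with an
IIR notch (default 60 Hz, Q = 30; 50 Hz configurable). Epoching cuts
maximal equal-length windows (default 4 s, no overlap; 2 s is used in
the examples and acceptance runs to double the training-set size at the
same record length); epochs exceeding ±100 µV are rejected as
artifacts. Samples before the poor-signal flag first reaches ≤ 51 are
dropped by default.

## Spectral analysis

Welch PSD with 2 s Hann segments at 50% overlap (0.5 Hz resolution at
512 samples/s; the protocol's sampling rate is 4.3× the 120 samples/s
the sampling theorem requires for 60 Hz content). Band powers integrate
the PSD by the trapezoidal rule on a grid augmented with the exact band
edges, so the five bands tile 0.5–60 Hz and their absolute powers sum
exactly to the broadband power; relative powers are fractions of that
sum. Adjacent bands share edge frequencies; the shared point is a
measure-zero boundary of the integral, equivalent to the half-open
binning convention for any continuous PSD.

## Self-affine analysis

The fluctuation analysis integrates the mean-removed signal to a
profile, splits it into windows of length s for ~32 log-spaced scales
between 4 samples and N/4, linearly detrends each window, and records
the RMS residual F(s). Uncorrelated noise gives slope ≈ 0.5 in log–log
coordinates (random-walk profile), which the tests verify. The
"crossover" of a curve is where it crosses a reference line — the
curve's own least-squares fit by default, or the zero line — reported
either as the first sign-change index or as the count of sign changes;
exact zeros carry the previous sign. Constant signals produce a
degenerate (all-zero-fluctuation) curve that is flagged rather than
raised mid-pipeline. The published per-session crossover values are
reproduced only at the level of the S_BA/S_DR arithmetic (from their
printed counts); the underlying curves cannot be reproduced without the
original recordings, and whether those counts are scale indices or
crossing counts is not documented — both modes are provided.

S_BA uses the absolute difference |C_A − C_B|: the defining prose calls
it an absolute distance and all published values are non-negative, so
the absolute value is taken even though the bare formula is sometimes
printed without bars.

## Encoder and losses

The shared encoder is the smallest architecture that trains quickly on
a CPU and respects the convolutional-for-signals guidance: three conv
blocks (kernel 7, stride 2, channels 16→32→64, ReLU), global average
pooling, linear projection to n = 64, and L2 normalization of the
output (default on). Normalization bounds the retrieval distance by 2,
which the similarity index relies on. The network and its
backpropagation are hand-written numpy; gradients are checked against
central finite differences to ~1e-7 relative error in the test suite.
Adam (lr 1e-3, β = 0.9/0.999), batch 32, 50 epochs by default (10 in
the examples and acceptance run — the loss reaches its floor within a
few epochs on the synthetic cohorts). Per-epoch z-scoring of inputs
removes amplitude scale, so the encoder must discriminate on spectral
shape.

Contrastive convention: the loss places the D² attraction on same-class
pairs (Y = 1) and the hinge max(0, m−D)² on different-class pairs, per
the stated intent of minimizing distances within a class; the published
equation as literally printed swaps the two roles, and an
`as_printed=True` switch reproduces that variant. For triplets the
anchor–negative distance uses the negative input x_n as the equation
defines (surrounding prose contains a typo). Pair/triplet sampling is
uniform with a seeded generator; hard-negative mining is out of scope.
Training is deterministic given the config seed; identical seeds yield
bit-identical weights.

## Similarity index and QB_DAT

The retrieval stage computes D = ‖Net(query) − Net(reference)‖₂ with the
shared trained weights. A raw Euclidean distance is 0 for identical
inputs, yet the published similarity figures treat 1 as identical
(≈ 0.92 at rest versus ≈ 0.17 during therapy), so the biomarker is
defined on the similarity index S = clamp(1 − D/2, 10⁻⁶, 1) of
unit-normalized embeddings, and QB_DAT = 10·log₁₀(1/S) dB. This
preserves the published qualitative mapping exactly: S → 1 gives
QB → 0 dB (no therapy effect measurable), S → 0 gives large QB; the
10⁻⁶ clamp caps QB at 60 dB. Whether cohort averages should be taken
over per-pair dB values or as dB of the mean similarity is ambiguous
(the two differ by Jensen's inequality); both are always reported, with
mean-of-dB as the headline.

## Evaluation design and problem sizes

The two-stage design trains the triplet encoder on all but the held-out
subjects (pooled across subjects; rest = class 0, during = class 1) and
scores the held-out subjects' resting epochs as queries against the
training database, giving rest-vs-rest and rest-vs-DAT pair
similarities. The directional claim — resting activity is more similar
to the resting database than to the during-therapy database, hence
mean QB(rest-vs-DAT) > mean QB(rest-vs-rest) — is tested on a
seed-fixed 4-subject cohort at protocol durations, 2 s epochs, 10
training epochs, with a 1000-draw one-sided permutation test on the
similarity gap (add-one corrected). Pair similarities sharing a query
epoch are not independent; the permutation test is over pooled pair
values and should be read as a strong-effect screen, not a calibrated
cohort-level inference.

## Reproducibility

A single master seed fans out to per-stage seeds via
`(seed·100003 + crc32(stage)) mod 2³¹`. The pipeline writes a manifest
(config SHA-256, seed, library versions) sufficient to reproduce every
output byte-identically; reruns of the same config are verified
identical in the tests.

## I/O formats

The CSV dialect (header lines `# fs=…`, `# channel=…`, `# phase=…`,
`# subject=…`, then `uV[,poor_signal]` rows) round-trips floats via
`repr`, hence bit-exactly. EDF export quantizes to the format's 16-bit
grid over a symmetric physical range covering the recording (documented
step = range/65535), uses 1 s records, requires whole-second recordings
at integer rates, and does not carry the poor-signal series; the
hand-written codec is cross-checked against an independent EDF reader
in the tests.

## Known limitations

- The synthetic therapy profile is a placeholder; effect sizes on real
  data are unknown and could be far smaller than the synthetic gap.
- Single channel only; no topographic or connectivity analyses.
- The self-affine crossover is sensitive to the choice of reference
  line; published crossover magnitudes are not comparable across
  implementations.
- No artifact modeling beyond amplitude thresholding; no ICA.
- The encoder is intentionally small; no claim of architectural
  optimality is made, and alternative distances (L1, cosine) are not
  tuned.
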