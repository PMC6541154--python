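# Methods

## The problem and the analysis

Four static thumb-opposition postures (P1–P4: thumb tip opposing the base of
digit 2, 3, 4, 5) are held isometrically at 30% MVC while HD-sEMG is recorded
from two 13×5 grids (8 mm inter-electrode distance, one corner masked, 64
active channels) over the anterior and posterior forearm.  The working
hypothesis is that posture modulates the *amplitude* of the spatial EMG
pattern, not the location of activity, and that this amplitude image is
classifiable.  The pipeline quantifies that claim twice: unsupervised
(a self-organizing feature map clustering per-electrode amplitude profiles,
classified via unit labels) and supervised (a small feed-forward network).

## Synthetic session generator

No recordings of this protocol are deposited, so the package ships a
generator that produces sessions with the statistical structure the analysis
assumes.  It is an interference-pattern surrogate, deliberately not a
motor-unit simulation.

Per channel c and posture p the signal is

```
x_c(t) = g_c(p) · e(t) · [ n_c(t) + κ · n_cm(t) ] + σ0 · w_c(t) + line_c(t)
```

* `n_c` — independent zero-mean Gaussian noise band-limited to 20–450 Hz
  (inside the 3–900 Hz acquisition band) and energy-normalized, the standard
  surrogate for interference-pattern surface EMG;
* `n_cm` — one shared band-limited source, weighted κ = 0.1 (common-mode
  coupling across channels);
* `e(t)` — the force envelope: ramp (0.5 s), hold (5 s), release, multiplied
  by (1 + slow tracking jitter, 1.5% CV low-passed at 1 Hz) — the
  visual-feedback error of a human holding 30% MVC;
* `σ0` — white instrument noise, 0.02 mV;
* `line_c` — 50 Hz and harmonics up to 350 Hz (fundamental 0.015 mV, decaying
  0.6 per harmonic, per-channel coupling 0.7–1.3), so the notch stage is
  exercised.

The spatial gain `g_c(p)` is built from two Gaussian sources per grid
(σ = 12 mm, centers jittered once per session and then **shared by all four
postures**) over a flat background (35% of peak):

```
g_c(p) = A · L_p · [ 0.35 + Σ_s w_s · (1 + δ_{p,s}) · exp(−d(c,s)² / 2σ²) ]
```

with peak amplitude A = 0.35 mV, source weights w = (1.0, 0.75), and
region-specific posture levels L: posterior (1.00, 0.80, 0.63, 0.47) —
monotonically decreasing from P1 to P4 — and anterior (0.85, 1.00, 0.72,
0.55).  The per-source deviations δ (≤ 12%) keep the two sources from moving
in lockstep; posterior P4 pulls them toward similar strengths.  Both L and
(1 + δ) are raised to the power `effect_scale`, so `effect_scale = 0`
collapses all four postures onto one map (the null model) and 1 gives the
default separation.  Because the source centers never move, posture changes
only amplitudes: the strongest channel near each source is the same in every
posture.  No quantitative per-channel amplitudes are published for this
protocol, so the levels are calibrated qualitatively (clear monotone
posterior ordering, distinct anterior ordering, overlap-free normalized
amplitude ratios between adjacent postures at roughly 2–4× the window-RMS
sampling noise).

What the generator does **not** emulate: motor-unit recruitment and firing
statistics, volume-conductor physics, electrode-skin impedance drift,
movement artifact, inter-subject anatomy.  Consequently, passing recovery
tests show that the *pipeline* recovers amplitude-coded posture structure
when it exists; they say nothing about whether real forearm EMG carries that
structure — that is the empirical question the original experiment addresses.

## Preprocessing

Zero-phase (forward–backward) filtering throughout, applied per channel
before segmentation: a 4th-order Butterworth band-pass 3–900 Hz, then a notch
comb at 50–350 Hz.  Each comb tooth has a constant 6 Hz absolute bandwidth
(per-harmonic Q): a constant-Q comb either leaves >1% of a 50 Hz tone or
costs >1 dB at 60 Hz, while constant bandwidth satisfies both and keeps
higher teeth narrow.  Filtering pads with up to 1 s of reflected signal so
the notch ring-down settles inside the extension.

The analyzed segment is the **central 2.8 s** of each 5 s hold.  The window
scheme is 300 ms windows advanced by 250 ms (i.e. 50 ms overlap); only fully
contained windows are kept, never zero-padded.  2.8 s is the unique segment
length for which this scheme yields exactly 11 windows, the number the
analysis is built around; the windowed RMS of channel c is the feature
series.  Grand-averaging window RMS over windows and the 30 repetitions gives
one 64-channel iso-potential amplitude map per posture and grid.

## Features, normalization, splits

One feature vector per (electrode, trial) holding the 11 window-RMS values —
the only reading consistent with 1,920 = 64 × 30 vectors per posture.  To
keep any single electrode from dominating the Euclidean clustering, each
channel is divided by its maximum window RMS over the *training* rows of the
current split; the factors are frozen and reapplied to held-out rows, so
training values lie in [0, 1] and no test statistics leak into the scaling.
Splits are stratified by posture with seeded shuffling and largest-remainder
allocation, making part sizes a deterministic function of the counts
(7,680 → 4,608/3,072 at 60/40; 2,304/2,688/2,688 at 30/35/35).

## Self-organizing feature map

Batch Kohonen training on a 10×10 rectangular lattice: every epoch assigns
samples to their best-matching unit (BMU; ties to the lowest unit index) and
replaces each codebook vector with the Gaussian-neighborhood-weighted mean of
the data.  The radius anneals linearly 5→1 over 20 coarse epochs, then 1→0.5
over 30 fine epochs.  Batch updates plus principal-plane initialization (the
map spans ±2 SD of the training data's first two principal components) make
training deterministic; a radius of zero degenerates exactly to k-means
(Lloyd) iteration, which the tests exploit as an independent oracle.

Map quality: quantization error = mean sample→BMU distance; topographic
error = fraction of samples whose first and second BMUs are not 4-neighbors
on the lattice; combined error (Kaski–Lagus) = BMU distance plus the shortest
codebook-space path from BMU to second BMU stepping only between
lattice-adjacent units (all-pairs shortest paths via Dijkstra on the lattice
graph).  By construction combined ≥ quantization; quantization and combined
scale with the data, topographic error is scale-free.  Raw errors are
reported; no rescaling onto a 0–100% scale is applied (no defined mapping
exists for it).

Classification: units take the majority posture of their training hits;
hitless units inherit the nearest labeled unit's label (lattice distance,
ties to the lowest index); a test FV gets its BMU's label.  Performance is
reported per grid and per session, never pooled across grids.

## Supervised arm

One hidden layer of 20 tanh units, 4-way output.  Two objectives: softmax +
cross-entropy trained by full-batch Adam (default), and linear output + MSE
on one-hot targets trained by damped least-squares (Levenberg–Marquardt)
steps with an analytic Jacobian when the parameter count permits (else
first-order descent).  Both stop early on the validation objective with
patience 10 (max 500 epochs) and restore the best parameters, so the returned
model's validation objective never exceeds its value at initialization.
Reports always include total cross-entropy, % error,
accuracy/misclassification (summing to 100% per split) and confusion
matrices whose rows sum to the per-class counts.

## Known limitation: FV-level splits leak repetition identity

The protocol splits *feature vectors*, so the 64 FVs of one repetition land
on both sides of a split.  They share trial-level variability — force
tracking jitter and common-mode noise — which gives each repetition a weak
amplitude fingerprint.  On null sessions (`effect_scale = 0`) a flexible
classifier exploits it: the supervised net scores ≈28% instead of 25% on
held-out FVs, and the SOFM sits at the edge of the chance band (≈26–27.6%).
The package includes `features.trial_disjoint_split`, which partitions whole
repetitions; under it the null accuracies return to chance, demonstrating
that the excess is split leakage rather than posture signal.  Any protocol
with realistic trial-to-trial force variability and FV-level splits will
show this effect; accuracies measured with FV-level splits should therefore
be read as very slightly optimistic.

## Reduced profile and problem sizes

Unit tests run on a reduced profile (512 Hz, 3–220 Hz band, 3 s holds, 8
repetitions per posture — still 11 windows per trial) and on a micro profile
(3×3 grids, 256 Hz, 1 s holds) for structural checks.  The acceptance suite
and `scripts/acceptance.py` use the full default protocol (2,048 Hz, 5 s
holds, 120 trials) for every count-based and recovery quantity, with the
null-model control run at the same size.

## Numerical conventions

Seeds are explicit everywhere (sessions from a master seed via a seed
sequence; splits, SOM init and MLP init take their own seeds), making the
entire chain bit-reproducible.  BMU ties break to the lowest unit index,
majority-label ties to the lowest class index, split remainders by largest
fractional part then part order.  EMG is stored as float32 (≈7 significant
digits, far below the noise floor); session directories hold JSON metadata
plus one matrix file per trial (`bin` float32 or `csv`).
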