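# Methods

## The classification problem

One training example is a 5.5 s window of skin conductance (2,816 samples at
512 Hz) recorded around a calibrated heat stimulus; the label is the
stimulus class T0..T4, where T0 is the pain-free baseline (32 °C), T1 the
subject's pain threshold `T_P` and T4 the tolerance `T_T`. The tasks are
binary: T0 against a single pain level, or T0 against all pain levels
pooled. Evaluation is always subject-level leave-one-out so that a model
can never exploit subject identity.

### Temperature calibration

Stage temperatures are spaced by `γ = (T_T − T_P)/4` with stage 1 pinned to
`T_P`. The stage formula `T_i = T_P + (i−1)γ` read literally puts stage 4
at `T_P + 3γ`, which contradicts the definition of stage 4 as the tolerance
temperature; this package anchors stage 4 to `T_T`, so the stages are
`[32, T_P, T_P+γ, T_P+2γ, T_T]` and the final step is `2γ`. The anchoring
choice only affects the metadata attached to simulated subjects, not the
class labels or signals.

## Architecture

Feature maps are `(batch N, length L, channels C)` throughout.

**MSCN.** Three branches with first-layer kernels 1,024 / 512 / 50 (the 2 s,
1 s and 0.1 s windows at 512 Hz; the short kernel is fixed at 50). Kernel
sizes are the only constrained quantities; strides, pool sizes and channel
widths are free design parameters here, chosen so that every branch emits at
least 75 time steps from a 2,816-sample segment (branch outputs 77 / 96 / 89
with the default strides 6 / 6 / 5 and pools). Branch outputs are
left-cropped to the common target length 75 — the encoder's per-position
feature width — and concatenated channel-wise. Interior convolutions
(kernel 8) use 'same' zero padding; the first large-kernel convolution is
un-padded so the nominal receptive window is honest. Each convolution is
followed by batch normalization (eps 1e-5, momentum 0.1) and the exact-erf
GELU; dropout sits after the first pooling of each branch (default rate 0.5,
0.2 in the desk-scale preset).

**SEResNet.** Two 1×1 convolutions with ReLU (ReLU rather than GELU inside
this block, which converges better here) produce `V`; global average
pooling squeezes `V` to per-channel statistics; a `C/r` bottleneck
(`r = 16` by default, 4 in the desk-scale preset) with ReLU then a sigmoid
produce the gates; the gated map is added to the block input
(`X̃ = X + α ⊗ V`). Two deliberate choices:

- The squeeze averages **per example over length** (`1/L`), not over the
  batch (`1/(N·L)`). The batch-coupled form makes inference depend on batch
  composition, which breaks eval-mode determinism; a `batch_squeeze` flag
  reproduces the literal form for equation-level checks, and the test suite
  exercises both.
- The residual adds the block input `X` (a `residual_source="v"` switch adds
  the convolution output instead).

**Encoder.** After SE recalibration the map is transposed: channels index
attention positions and the 75-step temporal axis is the per-position
feature vector. Query, key and value are produced by three separate causal
convolutions (kernel 7, left padding K−1, length-preserving), so position
*t* is a function of positions ≤ *t* only. Heads are full-width: each of
the H = 5 heads applies its own 75×75 projections to the shared Q/K/V
paths, attends, and the H×75 = 375-wide concatenation is projected back to
width 75 (a split-width mode, 75/5 = 15 per head, is available but off by
default). The attention score scale is `1/√L` by default; the literal `1/L`
variant is selectable via `score_scale="linear"`. Softmax rows are
stabilized by max subtraction (value unchanged). The first residual adds
the query-path causal-conv output (switchable to the raw encoder input);
then layer-norm, a feed-forward block (hidden width 120), a second residual
layer-norm, and a two-layer fully connected head with softmax. One encoder
block is used.

## Training

Adam with the full-scale recipe batch 128, 100 epochs, learning rate 1e-3,
weight decay 1e-3 (L2-coupled), betas (0.9, 0.999), eps 1e-8. No inner
validation split is described for the protocol, so the **final-epoch model**
is used — no best-epoch selection. Inputs are centered per segment (removes
the subject-specific tonic level) and scaled by the training-set global
standard deviation. The loss is unweighted cross-entropy by default; a
class-weighting flag exists for the 1:4-imbalanced T0-vs-all task but is
off, matching the observed behaviour of unweighted training on that task.
One master seed fans out per-fold seeds through `SeedSequence`; fold
reports record their seeds, and eval-mode inference is a pure function
(frozen batch statistics, dropout off).

Metrics are computed on the **pooled** held-out predictions of all folds
(per-fold averaging is available as `metric_mode="per_fold_mean"`).
Sensitivity is recall on the pain class, specificity recall on the
pain-free class; AUC uses the trapezoid rule over the threshold sweep and
equals the midrank Mann–Whitney statistic; AUC is reported as NaN when the
truth is single-class.

## Synthetic cohorts

The generator emulates the stimulation protocol end to end: per subject a
continuous session is synthesized — 20 repetitions of each of the 5 classes
in shuffled order, 4 s stimuli, Uniform(8, 12) s pain-free gaps — and
stimulus-locked 5.5 s windows are cut with the onset 0.5 s into the window
(a 4.5 s alternative dialect is supported). The signal model is

`gsr(t) = tonic(t) + phasic(t) + noise(t)`

- **tonic**: level ~ U(2, 12) µS, linear drift ~ U(−0.005, 0.005) µS/s, plus
  a slow sinusoid (0.15 µS, 90 s period, random phase);
- **phasic**: each class-c ≥ 1 stimulus elicits an SCR — a bi-exponential
  kernel (rise 0.75 s, decay 3.0 s, analytically peak-normalized) with
  amplitude `separation × 0.2 µS × c × scr_gain × jitter` (lognormal jitter,
  σ = 0.25, unit mean) at latency ~ U(1.2, 2.8) s (±0.2 s per event);
  spontaneous SCRs (1.5/min, 0.1 µS × scr_gain) are label-independent;
- **noise**: i.i.d. Gaussian, sd ~ U(0.03, 0.08) µS.

Subject heterogeneity enters through `scr_gain` (lognormal, σ = 0.4), the
tonic parameters, latency, noise level, and the temperature calibration
(`T_P ~ N(42.5, 1)` clipped to [40, 45], `T_T = T_P + U(3.5, 5.5)` capped at
50.5 °C). 90 profiles are drawn and the last 3 dropped, mirroring the
study's exclusions. The 25-minute nominal trial length is not enforced;
the generator uses the stated per-stimulus timing, which yields ~24 min
sessions.

`separation` scales the class-amplitude spacing: 0 makes the labels carry
no information (the chance-calibration condition); 1 is the default
"realistic" spacing (0.2 µS per class step, comparable to typical
event-related SCR amplitudes); ≥3 is an easy, high-contrast regime.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: movement and electrode artifacts, non-stationary
habituation across the session, age/gender effects on pain perception,
nonlinear SCR superposition, or any coupling between temperature and tonic
level. Synthetic results validate the pipeline's mechanics (geometry,
gradients, splits, metrics, learnability, calibration), not clinical
performance; headline accuracies on the real heat-pain database require
that external dataset and are out of scope here.

## Desk-scale study sizes

Simulation studies run on 5-subject cohorts with the `small_model_config`
preset (identical architecture, branch channels (8, 8, 8) for 24
concatenated channels, SE ratio 4, feed-forward width 64) and
`small_train_config` (batch 16, 10 epochs). These sizes were chosen as the
smallest at which the qualitative phenomena are stable: chance-level pooled
accuracy at separation 0, ≥ 90 % pooled accuracy on T0-vs-T4 at high
separation, and accuracy nondecreasing in separation under paired seeds.

## Numerical choices

- He initialization for convolutions and hidden linear layers; unit-gain
  initialization for attention projections and output layers.
- Batch-norm eps 1e-5 guards zero-variance channels; layer-norm eps 1e-5.
- Softmax (attention and loss) uses row-max subtraction.
- Max-pool backward routes gradients to the arg-max sample (first maximum on
  exact ties).
- Branch harmonization crops from the left (the windows share their start);
  a branch shorter than the 75-step target is a configuration error, raised
  at model construction.
- All layers keep float32 end to end; the test suite re-runs every backward
  pass in float64 against central finite differences (tolerance 1e-4
  relative, with parameters jittered off exact ReLU/max kinks, where
  subgradients are ambiguous).
- AUC ties use the midrank convention.

## Known limitations

- The NumPy training loop is single-threaded and unsuitable for full-scale
  (87-subject × 100-epoch) runs; the harness is routinely exercised at desk
  scale. The architecture, splits and metrics are identical at both scales.
- Checkpoints store parameters and batch-norm statistics with the exact
  model configuration, but not optimizer state; training cannot resume
  mid-run.
- The T0-vs-all task is 1:4 imbalanced and unweighted by default; expect
  near-zero specificity when the pain classes dominate, which is the known
  behaviour of this configuration.
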