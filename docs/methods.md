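# Methods

## Problem and signal model

Wood-boring beetle larvae (the emerald ash borer, *Agrilus planipennis*,
is the motivating species) produce substrate-borne vibrations while
feeding and moving inside trunks. A piezoelectric probe drilled into the
wood records these as a mono waveform, but field recordings are corrupted
by forest ambience. The observation model is additive:

    y(t) = s(t) + d(t)

with `s` the clean boring vibration, `d` environmental noise, and the
task is to estimate `ŝ ≈ s` from `y` alone — single-channel, time-domain
enhancement, structurally identical to monaural speech enhancement.

## Corpus construction

Recordings (nominally 32 kHz) are segmented into 3 s windows every 2 s
(1 s overlap); trailing partial windows are dropped. Items are split
90/10 into train/test with a seeded permutation, and 5% of train is held
out for validation; `floor()` sizing reproduces the published corpus
counts (29,948 segments → 26,953/2,995; 426 noise segments → 383/43).
Noisy inputs are built by adding a noise segment scaled by

    g = sqrt( (Σs² / Σd²) · 10^(−SNR/10) )

so the mixture attains the target SNR *exactly* (machine precision, the
test suite checks 1e−6 dB) under the energy-ratio definition of SNR used
throughout. The clean signal is never rescaled, keeping the regression
target identical across the five mixing SNRs (0, −2.5, −5, −7.5, −10 dB).
How clean segments are matched to (noise, SNR) conditions is not fully
determined by the published counts; this package draws one seeded uniform
(noise, SNR) pair per clean segment, which matches the stated number of
training examples, and records provenance per mixture so any pairing is
reproducible.

## Architecture

`tcenv.model.TCENV` is a time-domain U-Net with a Conformer bottleneck:

- **Encoder** — 8 layers of dilated Conv1d (kernel 15, stride 2) →
  BatchNorm → LeakyReLU(0.1); output channels 16, 32, 64, 64, 128, 128,
  256, 256. Dilation schedule 1, 2, 4, 8, 1, 2, 4, 8 (dilations are not
  pinned down by the published description and do not change parameter
  counts; this schedule grows the receptive field smoothly). Padding is
  `7·dilation` so every layer halves the length exactly — a fixed padding
  of 7 is only length-preserving at dilation 1, and exact halving is
  required for the concatenation skips to align.
- **Bottleneck** — one 256→256 kernel-15 conv (+BN+LeakyReLU) between
  encoder and Conformer stack, present in all variants. A literal
  encoder+decoder reading gives ≈3.24 M parameters, 0.98 M short of the
  published 4.23 M for the conformer-free variant; the gap equals exactly
  one 256→256 kernel-15 conv layer, and with it the per-layer increments
  across all published variants become mutually consistent.
- **Conformer blocks** (×2 by default) — macaron pre-norm structure:
  half-step FFN → self-attention (4 heads) → convolution module
  (pointwise ×2 expansion → GLU → depthwise kernel 31 → BN → swish →
  pointwise) → half-step FFN → final LayerNorm. No positional encoding
  (self-attention over ≤375-step latents; the depthwise convolution
  provides local order information).
- **Decoder** — 8 ConvTranspose1d layers (kernel 5, stride 2, padding 2,
  output-padding 1 so each layer exactly doubles the length) → BN →
  LeakyReLU; each consumes the channel concatenation of the running
  decoder state and the matching encoder output (hence 2× input
  channels). The last layer projects to 1 channel with no normalization
  or activation: the output is an unconstrained waveform, and an
  activation there would bias the signed samples.

### Parameter-count calibration

Everything above fixes the count except the Conformer feed-forward
hidden width. `scripts/calibrate_conformer.py` scans widths; any of
1284–1286 reproduces the published sizes

| variant | M params |
|---|---|
| encoder-decoder only | 4.23 |
| + 1 Conformer layer | 6.02 |
| + 2 | 7.81 |
| + 3 | 9.60 |
| + 4 | 11.39 |

after 2-decimal rounding (the published table's 11.04 for the 4-layer
variant is inconsistent with its own constant per-layer increment; the
accompanying text's "11.4 M" matches). The default is the midpoint 1286,
giving 1,791,756 parameters per block. A closed-form count oracle in the
test suite verifies the framework count tensor-by-tensor, exactly.

## Numerical engine

No deep-learning framework is assumed: `tcenv.nn` is a small reverse-mode
autograd engine over numpy (float32 activations). Convolutions are
im2col/einsum with hand-written backward passes; every primitive is
verified against central finite differences in the test suite. The
optimizer is standard Adam (β = 0.9/0.999, ε = 1e−8). Weight
initialization is Kaiming-uniform `U(±1/√fan_in)` from a single seeded
generator, so model construction is bit-reproducible.

## Losses and training protocol

Three objectives over (clean, estimate): MSE, L1, and negative SNR
`−10·log10(Σy²/(Σ(y−ŷ)²+ε))` with ε = 1e−8 guarding the denominator
during training (ε = 0 recovers the evaluation metric exactly; batched
inputs average per-item SNRs). Training: Adam at 1e−3; the LR is halved
after 3 consecutive epochs without strict validation-loss improvement,
and training stops after 6. The two stagnation counters run
independently — halving resets only the halving counter — and no halving
fires on the epoch that triggers the stop, so a flat run halves exactly
once. Whether the halving counter should reset after a halving event is
not specified anywhere; resetting it (as here) is the reading under which
repeated halvings remain possible during long plateaus. Batch size 16 and
max 100 epochs are package defaults (unstated in the source protocol).

## Evaluation metrics

- **SNR** `10·log10(Σy²/Σ(y−ŷ)²)` over the whole signal; +∞ sentinel for
  exact reconstruction.
- **SegSNR** — the same ratio per non-overlapping 1024-sample frame
  (32 ms at 32 kHz; frame length is a package choice within the 20–40 ms
  norm for segmental measures), averaged. Frames with zero clean energy
  are excluded; exactly-reconstructed frames contribute a +99 dB cap
  rather than propagating ∞. No clamping by default; a `clamp_db=(−10, 35)`
  flag provides the speech-literature convention.
- **LLR** — per frame, `log10( ā^T R ā / a^T R a )` where `a`/`ā` are
  order-16 LPC coefficient vectors of the clean/enhanced frame and `R` is
  the clean frame's autocorrelation matrix. LPC uses the autocorrelation
  method: Hamming window, biased autocorrelation, Levinson–Durbin (all
  configurable; the source description fixes none of them, and these are
  the standard choices). Because `a` minimizes the quadratic form, the
  per-frame LLR is non-negative up to round-off — which means the
  published *negative* average LLR reported for the unprocessed noisy
  condition cannot arise from this formula with a clean-optimal
  denominator; the formula is implemented literally and that discrepancy
  is simply noted. The log base is likewise unstated; base 10 is the
  default with the base exposed as an argument.

## Synthetic surrogate data

The field recordings are not deposited, so `tcenv.synthetic` generates
structurally similar stand-ins:

- **Boring vibrations** — Poisson click trains (default 8 clicks/s) of
  exponentially damped sinusoids `exp(−t/τ)·sin(2πft)` with per-click
  resonance `f ~ U(1.5, 6) kHz`, decay `τ ~ U(2, 10) ms`, log-normal
  amplitudes, over a Gaussian floor at −40 dB; peak-normalized to 0.9.
  The click parameters are plausible for broadband larval pulses but are
  placeholders: no quantitative description of the real click spectra is
  available.
- **Environmental noise** — power-weighted sum of pink noise, low-passed
  wind rumble (<120 Hz), an amplitude-modulated cicada-like tone
  (3.5–6 kHz carrier, 25–55 Hz modulation), and band-limited traffic
  noise (40–350 Hz); unit RMS, scaled down if the peak exceeds 0.99.

Every generator is a pure function of (spec, seed); corpus item seeds are
`master_seed + index` so subsets are stable. What passing tests on this
data do **not** show: robustness to real wood-propagation filtering,
reverberation, sensor nonlinearity, or non-stationary noise onsets —
the surrogates are stationary in regime and spectrally simple.

## Desk-scale training demonstration

`tcenv.training.demo_experiment` trains a reduced variant — 4 encoder
layers at channels (4, 8, 16, 16), one Conformer block (2 heads, FFN 32,
depthwise 15) — on 200 synthetic mixtures at −5 dB, 1 s clips at 8 kHz
(click resonances moved below the reduced Nyquist), 15 epochs, and
evaluates mean SNR on 24 held-out clips. These sizes are the package's
own desk-scale choice: large enough that the network must actually
separate clicks from noise (note that outputting silence would score
exactly 0 dB, i.e. a trivial +5 dB over −5 dB input; the trained model
reaches ≈+3.5 to +5.7 dB output SNR, clearly beyond both that and the
≈+1.2 dB optimum of a single global gain), small enough for a single
CPU. The published absolute test-set figures (e.g. 17.84 dB at 0 dB
input) require the original field recordings and GPU-scale training and
are not reproduced here; the acceptance suite asserts only the ≥5 dB
mean improvement property and logs the loss-function ranking
informationally.

## Known limitations

- BatchNorm statistics are computed per batch without any distributed or
  ghost-batch handling; very small batches give noisy estimates.
- The autograd engine holds the whole graph of a batch in memory; it is
  sized for desk-scale experiments, not for training the full 7.81 M
  model on a real corpus (the forward path of the full model works fine
  and is what the parameter and shape checks exercise).
- WAV I/O supports mono PCM16/float32 only; resampling is out of scope.
- The clean-to-noise pairing rule and several metric details (frame
  length, LPC order, log base) are under-determined by the published
  description; all are exposed as parameters and the defaults documented
  above.
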