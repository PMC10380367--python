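# tcenv — time-domain enhancement of wood-borer vibration signals

Acoustic detection of trunk-boring insect larvae (e.g. the emerald ash
borer, *Agrilus planipennis*) records substrate vibrations with a
piezoelectric probe; in the field those recordings are buried in forest
noise. `tcenv` implements a complete denoising pipeline for such
signals: SNR-controlled corpus construction, a time-domain
Conformer-augmented convolutional encoder-decoder (T-CENV), three
training objectives, and the SNR / SegSNR / LLR evaluation metrics —
plus a synthetic-signal module so everything runs and is testable
without field recordings.

The observation model is additive, `y(t) = s(t) + d(t)`; the network
maps the noisy waveform `y` directly to an estimate `ŝ` of the clean
boring vibration. Mixtures are constructed at exact target SNRs by
scaling only the noise:

    g = sqrt( (Σs² / Σd²) · 10^(−SNR/10) ),   y = s + g·d

The network is a U-Net over raw samples: 8 dilated-conv downsampling
layers (kernel 15, stride 2, channels 16…256), a 256→256 bottleneck
conv, a stack of Conformer blocks (macaron FFN pair around
self-attention and a GLU/depthwise convolution module) on the latent
sequence, and 8 transposed-conv upsampling layers fed by concatenation
skips. Training follows the published protocol: Adam at 1e−3, LR halved
after 3 stagnant validation epochs, early stop after 6. Everything runs
on a small numpy autograd engine (`tcenv.nn`) — no deep-learning
framework required.

## Worked example

```python
import numpy as np
from tcenv.corpus import Segment, mix_at_snr
from tcenv.metrics import snr_db
from tcenv.model import TCENV, REFERENCE_CONFIG, count_parameters
from tcenv.synthetic import ClickTrainSpec, NoiseSpec, gen_boring_vibration, gen_noise
from tcenv.training import demo_experiment

# 1. a clean click train and a forest-noise surrogate, mixed at -5 dB
clean = gen_boring_vibration(3.0, 32000, ClickTrainSpec(seed=1))
noise = gen_noise(3.0, 32000, NoiseSpec(seed=2))
rec = mix_at_snr(Segment(clean.samples), Segment(noise.samples), -5.0)
print(round(snr_db(rec.clean.samples, rec.mixture.samples), 6))  # -5.0

# 2. the reference architecture reproduces the published sizes
print(count_parameters(TCENV(REFERENCE_CONFIG)).millions)        # 7.81

# 3. desk-scale training: tiny variant, 200 synthetic -5 dB mixtures
res = demo_experiment(seed=0)
print(round(res["noisy_snr_db"], 2), round(res["enhanced_snr_db"], 2))
# -5.0 3.49   (held-out mean SNR: +8.5 dB improvement)
```

The first block shows the mixing construction is exact: measuring the
energy-ratio SNR of the mixture against its clean reference returns the
requested −5 dB to machine precision. The second instantiates the full
two-Conformer-layer network and counts 7.81 M trainable parameters. The
third trains the reduced demonstration model for a few CPU-minutes and
lifts held-out SNR from −5 dB to about +3.5 dB.

## Command line

```sh
tcenv synth --n-clean 50 --n-noise 10 --out data/        # synthetic WAVs
tcenv mix --clean-dir data/clean --noise-dir data/noise \
          --snrs 0,-2.5,-5,-7.5,-10 --seed 1 --out mixtures/
tcenv train --config cfg.yaml --data mixtures/manifest.tsv --out run/
tcenv enhance --model run/checkpoint.npz --in noisy.wav --out clean.wav
tcenv eval --clean ref.wav --enhanced clean.wav
tcenv params --layers 2                                  # per-block counts
```

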