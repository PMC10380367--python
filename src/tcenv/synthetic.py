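"""Synthetic surrogate signals: larval boring vibrations and forest noise.

Wood-boring larvae produce sparse trains of broadband clicks — short
damped resonances excited by mandible strikes and body movements — over a
low instrumentation noise floor.  Forest ambience around infested trees is
dominated by colored (roughly pink) broadband noise, low-frequency wind
rumble, amplitude-modulated insect tones (cicadas) and band-limited
traffic noise.  The generators here emulate that structure so the whole
enhancement pipeline can be exercised and tested without field
recordings; they make no claim to species-specific fidelity.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .io_wav import Waveform

__all__ = [
    "ClickTrainSpec",
    "NoiseSpec",
    "NOISE_COMPONENTS",
    "gen_boring_vibration",
    "gen_noise",
    "gen_corpus",
]


@dataclass(frozen=True)
class ClickTrainSpec:
    """Parameters of the surrogate boring-vibration generator.

    rate
        Poisson intensity of click arrivals, clicks per second.
    resonance_hz
        Range of per-click resonance frequencies (Hz); each click draws
        uniformly from it.  Must lie below Nyquist.
    decay_s
        Range of exponential decay time constants (s).
    amplitude_sigma
        Log-normal sigma of per-click amplitudes (median amplitude 1).
    floor_db
        Gaussian instrumentation-floor RMS relative to the unit click
        amplitude, in dB (default -40 dB).
    """

    rate: float = 8.0
    resonance_hz: tuple[float, float] = (1500.0, 6000.0)
    decay_s: tuple[float, float] = (0.002, 0.010)
    amplitude_sigma: float = 0.5
    floor_db: float = -40.0
    seed: int = 0

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if not (0 < self.resonance_hz[0] <= self.resonance_hz[1]):
            raise ValueError("invalid resonance range")
        if not (0 < self.decay_s[0] <= self.decay_s[1]):
            raise ValueError("invalid decay range")


NOISE_COMPONENTS = ("pink", "wind_lowpass", "am_tone", "traffic_band")


@dataclass(frozen=True)
class NoiseSpec:
    """Weighted mixture of environmental-noise components.

    Components: ``pink`` (1/f broadband), ``wind_lowpass`` (low-passed
    rumble), ``am_tone`` (amplitude-modulated cicada-like tone),
    ``traffic_band`` (band-limited low-frequency noise).  Weights are
    normalized to sum to one.
    """

    components: dict = field(
        default_factory=lambda: {c: 1.0 for c in NOISE_COMPONENTS}
    )
    seed: int = 0

    def __post_init__(self):
        if not self.components:
            raise ValueError("at least one noise component required")
        unknown = set(self.components) - set(NOISE_COMPONENTS)
        if unknown:
            raise ValueError(f"unknown noise components: {sorted(unknown)}")
        if any(w < 0 for w in self.components.values()):
            raise ValueError("weights must be nonnegative")
        total = sum(self.components.values())
        if total <= 0:
            raise ValueError("weights must not all be zero")
        object.__setattr__(
            self, "components", {k: v / total for k, v in self.components.items()}
        )


def _click_kernel(sr: int, f_hz: float, decay_s: float) -> np.ndarray:
    """Exponentially damped sinusoid exp(-t/tau) * sin(2 pi f t)."""
    n = max(int(round(8 * decay_s * sr)), 8)
    t = np.arange(n) / sr
    return np.exp(-t / decay_s) * np.sin(2 * np.pi * f_hz * t)


def gen_boring_vibration(
    duration_s: float, sr: int, spec: ClickTrainSpec
) -> Waveform:
    """Generate a sparse click train over a Gaussian noise floor.

    Clicks arrive as a Poisson process; each is a damped sinusoid with
    random resonance and decay drawn from the spec.  The result is
    peak-normalized to 0.9 and is deterministic given ``spec.seed``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if spec.resonance_hz[1] >= sr / 2:
        raise ValueError("resonance range extends to or above Nyquist")
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration_s * sr))
    floor_rms = 10.0 ** (spec.floor_db / 20.0)
    x = rng.normal(0.0, floor_rms, n)
    n_clicks = rng.poisson(spec.rate * duration_s)
    starts = np.sort(rng.integers(0, n, size=n_clicks))
    for s0 in starts:
        amp = rng.lognormal(0.0, spec.amplitude_sigma)
        f = rng.uniform(*spec.resonance_hz)
        tau = rng.uniform(*spec.decay_s)
        k = _click_kernel(sr, f, tau)
        end = min(s0 + k.size, n)
        x[s0:end] += amp * k[: end - s0]
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 0.9 / peak
    return Waveform(x, sr)


def _unit_rms(x: np.ndarray) -> np.ndarray:
    r = np.sqrt(np.mean(x**2))
    return x / r if r > 0 else x


def _component(name: str, n: int, sr: int, rng: np.random.Generator) -> np.ndarray:
    if name == "pink":
        # shape white noise to 1/sqrt(f) magnitude in the frequency domain
        white = rng.normal(size=n)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, 1 / sr)
        f[0] = f[1] if n > 1 else 1.0
        spec /= np.sqrt(f)
        return _unit_rms(np.fft.irfft(spec, n))
    if name == "wind_lowpass":
        sos = sps.butter(4, 120.0, btype="low", fs=sr, output="sos")
        return _unit_rms(sps.sosfilt(sos, rng.normal(size=n)))
    if name == "am_tone":
        t = np.arange(n) / sr
        carrier = rng.uniform(3500.0, min(6000.0, 0.45 * sr))
        mod = rng.uniform(25.0, 55.0)
        env = 0.5 * (1 + np.sin(2 * np.pi * mod * t + rng.uniform(0, 2 * np.pi)))
        return _unit_rms(env * np.sin(2 * np.pi * carrier * t))
    if name == "traffic_band":
        hi = min(350.0, 0.4 * sr)
        sos = sps.butter(4, (40.0, hi), btype="band", fs=sr, output="sos")
        return _unit_rms(sps.sosfilt(sos, rng.normal(size=n)))
    raise ValueError(f"unknown component {name!r}")


def gen_noise(duration_s: float, sr: int, spec: NoiseSpec) -> Waveform:
    """Generate environmental noise: weighted sum of components, unit RMS.

    Component amplitudes are ``sqrt(weight)`` so the weights are power
    fractions; the sum is re-normalized to unit RMS exactly, then scaled
    down if the peak would exceed 0.99.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration_s * sr))
    x = np.zeros(n)
    for name in NOISE_COMPONENTS:  # fixed order for reproducibility
        w = spec.components.get(name, 0.0)
        if w > 0:
            x += np.sqrt(w) * _component(name, n, sr, rng)
    x = _unit_rms(x)
    peak = np.max(np.abs(x))
    if peak > 0.99:
        x *= 0.99 / peak
    return Waveform(x, sr)


def gen_corpus(
    n_clean: int,
    n_noise: int,
    duration_s: float,
    sr: int,
    seed: int,
    clean_spec: ClickTrainSpec | None = None,
    noise_spec: NoiseSpec | None = None,
) -> tuple[list[Waveform], list[Waveform]]:
    """Generate ``n_clean`` click trains and ``n_noise`` noise waveforms.

    Per-item seeds are derived as ``seed + index`` (noise seeds offset by
    ``n_clean``) so corpora stay reproducible under subsetting.
    """
    clean_spec = clean_spec or ClickTrainSpec()
    noise_spec = noise_spec or NoiseSpec()
    clean = [
        gen_boring_vibration(duration_s, sr, replace(clean_spec, seed=seed + i))
        for i in range(n_clean)
    ]
    noise = [
        gen_noise(duration_s, sr, replace(noise_spec, seed=seed + n_clean + j))
        for j in range(n_noise)
    ]
    return clean, noise
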