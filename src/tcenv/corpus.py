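"""Dataset construction: segmentation, splitting, SNR-controlled mixing.

The corpus recipe mirrors common practice in single-channel enhancement:
recordings are cut into fixed windows with overlap, split into train/test
(and a validation subset of train), and each clean segment is corrupted by
adding a noise segment scaled to a prescribed signal-to-noise ratio.  The
clean signal is never rescaled, so the regression target is identical
across SNR conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_wav import Waveform

__all__ = [
    "Segment",
    "SplitPlan",
    "MixtureRecord",
    "segment_waveform",
    "make_split",
    "mixing_gain",
    "mix_at_snr",
    "build_noisy_set",
    "DEFAULT_SNRS_DB",
    "ZeroEnergyError",
]

#: Mixing SNRs used for corpus construction (dB).
DEFAULT_SNRS_DB = (0.0, -2.5, -5.0, -7.5, -10.0)


class ZeroEnergyError(ValueError):
    """A segment needed for mixing has zero energy."""

    def __init__(self, which: str):
        super().__init__(f"{which} segment has zero energy")
        self.which = which


@dataclass(frozen=True)
class Segment:
    """A fixed-length window of a parent waveform.

    ``offset`` is the 0-based start sample; the window is half-open
    ``[offset, offset + len)``.
    """

    samples: np.ndarray
    source_id: str = ""
    offset: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float64)
        )

    def __len__(self):
        return self.samples.size

    def energy(self) -> float:
        return float(np.sum(self.samples**2))


@dataclass(frozen=True)
class SplitPlan:
    """Train/test partition with a validation subset of train."""

    train_ids: tuple[int, ...]
    test_ids: tuple[int, ...]
    val_ids: tuple[int, ...]
    seed: int

    def __post_init__(self):
        train, test, val = set(self.train_ids), set(self.test_ids), set(self.val_ids)
        if train & test:
            raise ValueError("train and test overlap")
        if not val <= train:
            raise ValueError("val must be a subset of train")


@dataclass(frozen=True)
class MixtureRecord:
    """A clean/noise pair mixed at a target SNR, with provenance."""

    clean: Segment
    noise: Segment
    snr_db: float
    gain: float
    mixture: Segment


def segment_waveform(
    w: Waveform, window_s: float = 3.0, step_s: float = 2.0, source_id: str = ""
) -> list[Segment]:
    """Cut *w* into windows of ``window_s`` seconds every ``step_s`` seconds.

    With the 3 s / 2 s defaults adjacent segments overlap by 1 s.  The
    trailing partial window is discarded; a recording shorter than one
    window yields an empty list.
    """
    if window_s <= 0 or step_s <= 0:
        raise ValueError("window_s and step_s must be > 0")
    wlen = int(round(window_s * w.sample_rate))
    step = int(round(step_s * w.sample_rate))
    n = len(w)
    if n < wlen:
        return []
    count = (n - wlen) // step + 1
    return [
        Segment(w.samples[i * step : i * step + wlen], source_id, i * step)
        for i in range(count)
    ]


def make_split(
    n_items: int,
    train_frac: float = 0.9,
    val_frac_of_train: float = 0.05,
    seed: int = 0,
) -> SplitPlan:
    """Seeded permutation split: floor(train_frac * n) train, rest test.

    The validation subset is the first floor(val_frac_of_train * |train|)
    items of the shuffled train list.  floor() reproduces the published
    corpus counts (e.g. 29,948 -> 26,953 / 2,995).
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_items)
    n_train = int(np.floor(train_frac * n_items))
    train = perm[:n_train]
    test = perm[n_train:]
    n_val = int(np.floor(val_frac_of_train * n_train))
    return SplitPlan(
        train_ids=tuple(int(i) for i in train),
        test_ids=tuple(int(i) for i in test),
        val_ids=tuple(int(i) for i in train[:n_val]),
        seed=seed,
    )


def mixing_gain(clean: Segment, noise: Segment, snr_db: float) -> float:
    """Noise gain g so that clean + g*noise attains the target SNR.

    SNR(clean, clean + g*noise) = 10 log10(E_clean / (g^2 E_noise)), hence
    g = sqrt((E_clean / E_noise) * 10^(-snr_db / 10)).
    """
    e_clean = clean.energy()
    e_noise = noise.energy()
    if e_clean <= 0:
        raise ZeroEnergyError("clean")
    if e_noise <= 0:
        raise ZeroEnergyError("noise")
    return float(np.sqrt((e_clean / e_noise) * 10.0 ** (-snr_db / 10.0)))


def mix_at_snr(clean: Segment, noise: Segment, snr_db: float) -> MixtureRecord:
    """Additively corrupt *clean* with *noise* scaled to *snr_db*.

    The clean segment is left untouched; only the noise is scaled.
    """
    if len(clean) != len(noise):
        raise ValueError(
            f"length mismatch: clean {len(clean)} vs noise {len(noise)}"
        )
    g = mixing_gain(clean, noise, snr_db)
    mixture = Segment(
        clean.samples + g * noise.samples,
        source_id=f"{clean.source_id}+{noise.source_id}@{snr_db:g}dB",
        offset=clean.offset,
    )
    return MixtureRecord(clean=clean, noise=noise, snr_db=snr_db, gain=g, mixture=mixture)


def build_noisy_set(
    clean_segments: list[Segment],
    noise_segments: list[Segment],
    snrs_db: tuple[float, ...] = DEFAULT_SNRS_DB,
    pairing_seed: int = 0,
) -> tuple[list[MixtureRecord], int]:
    """Assign each clean segment one seeded-random (noise, SNR) pair.

    Returns the mixture records plus the number of distinct noisy
    environments, i.e. ``len(noise_segments) * len(snrs_db)`` available
    (noise recording, SNR) combinations.
    """
    if not clean_segments or not noise_segments or not snrs_db:
        raise ValueError("clean_segments, noise_segments and snrs_db must be non-empty")
    rng = np.random.default_rng(pairing_seed)
    records = []
    for clean in clean_segments:
        noise = noise_segments[rng.integers(len(noise_segments))]
        snr = snrs_db[rng.integers(len(snrs_db))]
        records.append(mix_at_snr(clean, noise, float(snr)))
    n_environments = len(noise_segments) * len(snrs_db)
    return records, n_environments
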