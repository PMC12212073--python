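"""Synthetic ONT-like raw signal generator.

Emulates the statistics that matter to an integer time-series codec: a
piecewise-constant level sequence (pore current dwelling on discrete levels
as bases translocate), levels drawn from a two-component Gaussian mixture on
the ADC scale (the aggregate value distribution of real nanopore runs is
bimodal), geometric segment dwell times, additive Gaussian noise, and
quantisation to the instrument's ADC depth (11 bits PromethION, 13 MinION).

An optional "spike" injector reproduces the converter artifact seen in real
frequency distributions: excess counts at values whose two least-significant
bits transition 11 -> 00 (i.e. just below a multiple of 4). It displaces a
sample ending in binary 11 upward by one with probability spike_rate, piling
mass onto the next multiple of 4. The injector is phenomenological — the
hardware mechanism of the real artifact is unknown — but it lives entirely
in the two lowest bits, so 2-bit degradation must erase it, which is the
property the analysis experiments exercise.

This generator makes no attempt at k-mer-level realism (no pore model); the
spike artifact in real data is unrelated to the sample's k-mer profile, and
codec behaviour depends only on the level/dwell/noise statistics modelled
here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .container import SignalRead

#: PromethION-typical calibration used for generated reads
DEFAULT_DIGITISATION = 2048.0
DEFAULT_RANGE = 748.5801
DEFAULT_OFFSET = -240.0
DEFAULT_SAMPLING_RATE = 5000.0


@dataclass(frozen=True)
class SyntheticModel:
    """Parameters of the ONT-like signal simulator (ADC-count units).

    Defaults target an 11-bit PromethION: mixture means at 35% and 65% of
    the ADC range with standard deviations of 6% of the range, equal
    weights, mean dwell of 10 samples per segment, and sample-level noise
    of 1.5% of the range.
    """

    adc_bits: int = 11
    level_means: tuple[float, float] = None  # type: ignore[assignment]
    level_sds: tuple[float, float] = None  # type: ignore[assignment]
    level_weight: float = 0.5  # weight of the first component
    dwell_mean: float = 10.0
    noise_sd: float = None  # type: ignore[assignment]
    spike_rate: float = 0.0

    def __post_init__(self) -> None:
        full = self.adc_max + 1
        if self.level_means is None:
            object.__setattr__(self, "level_means", (0.35 * full, 0.65 * full))
        if self.level_sds is None:
            object.__setattr__(self, "level_sds", (0.06 * full, 0.06 * full))
        if self.noise_sd is None:
            object.__setattr__(self, "noise_sd", 0.015 * full)
        if not 1 <= self.adc_bits <= 15:
            raise ValueError(f"adc_bits must be in 1..15, got {self.adc_bits}")
        for m in self.level_means:
            if not 0 <= m <= self.adc_max:
                raise ValueError(f"level mean {m} outside ADC range")
        if any(sd <= 0 for sd in self.level_sds) or self.noise_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if not 0 <= self.level_weight <= 1:
            raise ValueError("level_weight must be in [0, 1]")
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1 sample")
        if not 0 <= self.spike_rate <= 1:
            raise ValueError("spike_rate must be in [0, 1]")

    @property
    def adc_max(self) -> int:
        return (1 << self.adc_bits) - 1


def _segment_levels(model: SyntheticModel, n: int, rng: np.random.Generator):
    comp = rng.random(n) >= model.level_weight
    means = np.where(comp, model.level_means[1], model.level_means[0])
    sds = np.where(comp, model.level_sds[1], model.level_sds[0])
    return rng.normal(means, sds)


def simulate_samples(
    model: SyntheticModel, num_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Raw ADC sample vector for one read (int16)."""
    if num_samples < 1:
        raise ValueError("num_samples must be >= 1")
    # draw enough geometric dwells to cover the read, then trim
    n_seg = max(1, int(2 * num_samples / model.dwell_mean) + 16)
    dwells = rng.geometric(1.0 / model.dwell_mean, size=n_seg)
    while dwells.sum() < num_samples:
        dwells = np.concatenate(
            [dwells, rng.geometric(1.0 / model.dwell_mean, size=n_seg)]
        )
    levels = _segment_levels(model, dwells.size, rng)
    signal = np.repeat(levels, dwells)[:num_samples]
    signal = signal + rng.normal(0.0, model.noise_sd, size=num_samples)
    adc = np.clip(np.rint(signal), 0, model.adc_max).astype(np.int64)
    if model.spike_rate > 0:
        low11 = (adc & 3) == 3
        hit = low11 & (rng.random(num_samples) < model.spike_rate)
        adc[hit] += 1  # lands on the next multiple of 4 (low bits 00)
        np.clip(adc, 0, model.adc_max, out=adc)
    return adc.astype(np.int16)


def simulate_read(
    model: SyntheticModel,
    num_samples: int,
    seed: int | np.random.Generator = 0,
    read_id: str = "synth-0",
) -> SignalRead:
    """One synthetic read with PromethION-typical calibration metadata.

    Deterministic for a fixed seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return SignalRead(
        read_id=read_id,
        digitisation=DEFAULT_DIGITISATION,
        offset=DEFAULT_OFFSET,
        range=DEFAULT_RANGE,
        sampling_rate=DEFAULT_SAMPLING_RATE,
        samples=simulate_samples(model, num_samples, rng),
    )


def simulate_dataset(
    model: SyntheticModel,
    num_reads: int,
    read_length_mean: float = 5000.0,
    seed: int = 0,
    read_length_sd: float = 0.0,
) -> list[SignalRead]:
    """Independent reads; lengths Gaussian around read_length_mean (min 10)."""
    if num_reads < 1:
        raise ValueError("num_reads must be >= 1")
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(num_reads):
        if read_length_sd > 0:
            n = max(10, int(rng.normal(read_length_mean, read_length_sd)))
        else:
            n = max(1, int(read_length_mean))
        reads.append(
            simulate_read(model, n, seed=rng, read_id=f"synth-{i}")
        )
    return reads
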