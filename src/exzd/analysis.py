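"""Experiment layer: value histograms, spike scoring, compression benchmarks.

Compression ratio is defined throughout as uncompressed size / compressed
size, with the uncompressed size fixed at 2 bytes per sample (the native
int16 representation of raw signal).

The spike score quantifies the converter artifact visible in raw-value
frequency distributions: for each interior ADC value v with occupied
neighbours, the positive part of log2(c(v) / mean(c(v-1), c(v+1))) is
averaged. A perfectly smooth histogram scores 0; an isolated doubled bin
contributes 1 at that bin. The metric is deliberately one-sided so dips do
not cancel spikes.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyarrow as pa

from .primitives import round_low_bits_array, zigzag_encode_array
from .record import exzd_encode
from .svb import svb_encode

_zstd = pa.Codec("zstd")

BASELINE_METHODS = (
    "raw",
    "zlib",
    "zstd",
    "zlib_svb_zd",
    "zstd_svb_zd",
    "exzd",
    "exzd_zstd",
)
#: the slow5tools default lossless method, the reference for relative sizes
DEFAULT_METHOD = "zlib_svb_zd"


@dataclass(frozen=True)
class SignalHistogram:
    """Exact frequency counts over the full ADC value range [0, 2^bits)."""

    counts: np.ndarray
    adc_bits: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def value_histogram(reads, adc_bits: int = 11) -> SignalHistogram:
    """Count occurrences of each ADC value across all reads.

    Samples outside [0, 2^adc_bits) are clamped into range with a warning.
    """
    size = 1 << adc_bits
    counts = np.zeros(size, dtype=np.int64)
    for read in reads:
        s = read.samples if hasattr(read, "samples") else np.asarray(read)
        s = s.astype(np.int64)
        if s.size and (s.min() < 0 or s.max() >= size):
            warnings.warn(
                f"samples outside the {adc_bits}-bit ADC range were clamped",
                UserWarning,
                stacklevel=2,
            )
            s = np.clip(s, 0, size - 1)
        counts += np.bincount(s, minlength=size)
    return SignalHistogram(counts=counts, adc_bits=adc_bits)


def spike_score(hist: SignalHistogram) -> float:
    """Mean positive log2 excess of each value over its neighbours' mean."""
    c = hist.counts.astype(np.float64)
    if np.count_nonzero(c) < 3:
        raise ValueError(
            "spike score needs a histogram with at least 3 occupied bins"
        )
    left, mid, right = c[:-2], c[1:-1], c[2:]
    neighbour_sum = left + right
    eligible = neighbour_sum > 0
    if not eligible.any():
        raise ValueError("degenerate histogram: no interior bin has neighbours")
    excess = np.zeros_like(mid)
    pos = eligible & (mid > 0)
    excess[pos] = np.log2(mid[pos] / (neighbour_sum[pos] / 2.0))
    np.maximum(excess, 0.0, out=excess)
    return float(excess[eligible].mean())


# ------------------------------------------------------------- compression


def _svb_zd_bytes(samples: np.ndarray) -> bytes:
    """Zig-zag delta transform then streamvbyte — the slow5 default's core."""
    chain = np.empty(samples.size, dtype=np.int64)
    chain[0] = samples[0]
    chain[1:] = np.diff(samples.astype(np.int64))
    return svb_encode(zigzag_encode_array(chain))


def _compressed_size(method: str, reads, n_bits: int) -> int:
    total = 0
    for read in reads:
        s = np.asarray(read.samples if hasattr(read, "samples") else read)
        if n_bits:
            s = round_low_bits_array(s, n_bits)
        if method == "raw":
            total += 2 * s.size
        elif method == "zlib":
            total += len(zlib.compress(s.astype("<i2").tobytes()))
        elif method == "zstd":
            total += len(_zstd.compress(s.astype("<i2").tobytes(), asbytes=True))
        elif method == "zlib_svb_zd":
            total += len(zlib.compress(_svb_zd_bytes(s)))
        elif method == "zstd_svb_zd":
            total += len(_zstd.compress(_svb_zd_bytes(s), asbytes=True))
        elif method == "exzd":
            total += len(exzd_encode(s, n_bits))
        elif method == "exzd_zstd":
            total += len(
                _zstd.compress(exzd_encode(s, n_bits), asbytes=True)
            )
        else:
            raise ValueError(f"unknown method label {method!r}")
    return total


def compression_report(
    reads,
    methods=BASELINE_METHODS,
    eliminate_bits_list=(0,),
) -> pd.DataFrame:
    """Benchmark table: one row per (method, eliminate_bits).

    Columns: method, eliminate_bits, uncompressed_bytes, compressed_bytes,
    ratio (= uncompressed/compressed) and pct_of_default (size relative to
    the lossless slow5 default, zlib_svb_zd at 0 bits eliminated).
    """
    reads = list(reads)
    if not reads:
        raise ValueError("compression_report needs at least one read")
    for m in methods:
        if m not in BASELINE_METHODS:
            raise ValueError(f"unknown method label {m!r}")
    uncompressed = sum(
        2 * np.asarray(r.samples if hasattr(r, "samples") else r).size
        for r in reads
    )
    default_size = _compressed_size(DEFAULT_METHOD, reads, 0)
    rows = []
    for n in eliminate_bits_list:
        for method in methods:
            size = _compressed_size(method, reads, int(n))
            rows.append(
                {
                    "method": method,
                    "eliminate_bits": int(n),
                    "uncompressed_bytes": uncompressed,
                    "compressed_bytes": size,
                    "ratio": uncompressed / size,
                    "pct_of_default": 100.0 * size / default_size,
                }
            )
    return pd.DataFrame(rows)


def per_bit_savings(
    reads, bits=(0, 1, 2, 3, 4), method: str = "exzd_zstd"
) -> pd.DataFrame:
    """Size of one method as bits are eliminated, with per-step savings.

    The savings_pct column is the percentage shrinkage relative to the
    previous row (one fewer bit eliminated). The default method is the
    zstd-wrapped record codec: the plain record stream stores every
    one-byte delta verbatim and so floors at one byte per sample, whereas
    file-level deployments pair the record codec with a general-purpose
    entropy coder, which is where the per-bit savings of bit elimination
    accumulate.
    """
    report = compression_report(reads, methods=(method,), eliminate_bits_list=bits)
    sizes = report["compressed_bytes"].to_numpy(dtype=np.float64)
    savings = np.full(sizes.size, np.nan)
    savings[1:] = 100.0 * (1.0 - sizes[1:] / sizes[:-1])
    report = report.copy()
    report["savings_pct"] = savings
    return report


# ------------------------------------------------------------------ plots


def plot_histogram(hists, labels=None, ax=None, log=True):
    """Overlay raw-value frequency distributions (one line per histogram)."""
    import matplotlib.pyplot as plt

    if isinstance(hists, SignalHistogram):
        hists = [hists]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for i, h in enumerate(hists):
        label = labels[i] if labels else None
        ax.plot(np.arange(h.counts.size), h.counts, lw=0.7, label=label)
    ax.set_xlabel("ADC value")
    ax.set_ylabel("frequency")
    if log:
        ax.set_yscale("log")
    if labels:
        ax.legend(frameon=False)
    return ax


def plot_relative_sizes(report: pd.DataFrame, ax=None):
    """Bar chart of compressed sizes relative to the lossless default."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    labels = [
        f"{m} (n={n})"
        for m, n in zip(report["method"], report["eliminate_bits"])
    ]
    ax.bar(labels, report["pct_of_default"])
    ax.set_ylabel(f"% of {DEFAULT_METHOD} size")
    ax.tick_params(axis="x", rotation=60)
    return ax
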