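"""Stateless integer transforms underlying the ex-zd record codec.

All operations are defined on two's-complement 16-bit samples (ONT raw ADC
counts are stored as signed 16-bit integers; PromethION data occupies the
11-bit range 0..2047, MinION 13-bit 0..8191, but the full int16 range is
accepted). Scalar Python-int variants carry the reference semantics; the
``*_array`` variants are vectorised numpy equivalents used on whole reads.
"""

from __future__ import annotations

import numpy as np

INT16_MIN = -(1 << 15)
INT16_MAX = (1 << 15) - 1

_ZZ_MAX_INPUT = (1 << 31) - 1  # zig-zag output must fit in uint32


def zigzag_encode(v: int) -> int:
    """Map a signed integer to a non-negative one.

    Positive integers are doubled; the absolute value of a negative integer
    is doubled then reduced by one, so small magnitudes get small codes:
    0, -1, 1, -2, 2, ... -> 0, 1, 2, 3, 4, ...
    """
    v = int(v)
    if abs(v) > _ZZ_MAX_INPUT:
        raise ValueError(f"zig-zag input magnitude {v} exceeds 2^31-1")
    return 2 * v if v >= 0 else 2 * (-v) - 1


def zigzag_decode(z: int) -> int:
    """Inverse of :func:`zigzag_encode`."""
    z = int(z)
    if z < 0:
        raise ValueError(f"zig-zag code must be non-negative, got {z}")
    return z // 2 if z % 2 == 0 else -((z + 1) // 2)


def zigzag_encode_array(v: np.ndarray) -> np.ndarray:
    """Vectorised zig-zag encode; int64 in, uint32-valued uint64 out."""
    v = np.asarray(v, dtype=np.int64)
    if v.size and np.abs(v).max() > _ZZ_MAX_INPUT:
        raise ValueError("zig-zag input magnitude exceeds 2^31-1")
    # (v << 1) ^ (v >> 63) is the branch-free form of the doubling rule
    return ((v << 1) ^ (v >> 63)).astype(np.uint64)


def zigzag_decode_array(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.uint64)
    return ((z >> np.uint64(1)).astype(np.int64)) ^ -(z & np.uint64(1)).astype(np.int64)


def delta_chain(samples) -> list[int]:
    """First sample followed by consecutive differences.

    ``[s0, s1, s2, ...] -> [s0, s1-s0, s2-s1, ...]``; the inverse is a
    prefix sum. Raises on empty input.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("delta_chain requires at least one sample")
    out = [int(samples[0])]
    out.extend(int(b) - int(a) for a, b in zip(samples, samples[1:]))
    return out


def prefix_sum(deltas) -> list[int]:
    """Inverse of :func:`delta_chain`."""
    deltas = list(deltas)
    if not deltas:
        raise ValueError("prefix_sum requires at least one delta")
    out = [int(deltas[0])]
    for d in deltas[1:]:
        out.append(out[-1] + int(d))
    return out


def trailing_zeros16(x: int) -> int:
    """Trailing-zero count of the two's-complement 16-bit pattern of x.

    Zero is defined to have 16 trailing zeros.
    """
    u = int(x) & 0xFFFF
    if u == 0:
        return 16
    return (u & -u).bit_length() - 1


def common_trailing_zeros(samples) -> int:
    """Smallest run of zero least-significant bits shared by all samples.

    This is the right-shift the record codec applies before delta encoding.
    Capped at 15 so the shift is always meaningful for 16-bit data (an
    all-zero read still round-trips).
    """
    samples = np.asarray(list(samples), dtype=np.int64)
    if samples.size == 0:
        raise ValueError("common_trailing_zeros requires at least one sample")
    u = (samples & 0xFFFF).astype(np.uint16)
    # trailing zeros of the OR of all patterns == min of per-sample counts
    acc = int(np.bitwise_or.reduce(u))
    return min(trailing_zeros16(acc), 15)


def round_low_bits(x: int, n: int) -> int:
    """Zero the n least-significant bits of x by rounding.

    Rounds to the nearest multiple of 2**n; a value exactly halfway (low
    bits equal to 2**(n-1)) rounds up, which is what the bit formula
    ``(x & ~(2^n - 1)) + 2^n * bit_{n-1}(x)`` computes. Operates on the
    two's-complement pattern, so negative samples also land on the nearest
    multiple. Saturates at the largest multiple of 2**n not above +32767.
    """
    _check_bits(n)
    x = int(x)
    if not INT16_MIN <= x <= INT16_MAX:
        raise ValueError(f"sample {x} outside int16 range")
    if n == 0:
        return x
    mask = (1 << n) - 1
    r = (x & ~mask) + ((1 << n) if (x >> (n - 1)) & 1 else 0)
    if r > INT16_MAX:
        r = INT16_MAX & ~mask
    return r


def round_low_bits_array(x: np.ndarray, n: int) -> np.ndarray:
    """Vectorised :func:`round_low_bits` over an int16-valued array."""
    _check_bits(n)
    x = np.asarray(x)
    if x.size and (x.min() < INT16_MIN or x.max() > INT16_MAX):
        raise ValueError("sample outside int16 range")
    x = x.astype(np.int64)
    if n == 0:
        return x.astype(np.int16)
    mask = (1 << n) - 1
    r = (x & ~mask) + ((x >> (n - 1)) & 1) * (1 << n)
    np.minimum(r, INT16_MAX & ~mask, out=r)
    return r.astype(np.int16)


def _check_bits(n: int) -> None:
    if not 0 <= int(n) <= 8:
        raise ValueError(f"bits to eliminate must be in 0..8, got {n}")
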