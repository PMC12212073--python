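"""The ex-zd record codec: one read's samples to/from the ex-zd byte layout.

Wire layout of one record (all multi-byte fields little-endian)::

    version        1 byte   (this dialect: 0)
    num_samples    8 bytes
    shift_bits     1 byte   right-shift applied before delta coding
    first_sample_zz 2 bytes  zig-zag of the (shifted) first sample
    num_exceptions 4 bytes  n_x
    [exception block]       absent when n_x == 0;
                            n_x == 1: position (4B) + value-256 (4B);
                            n_x  > 1: svb(positions') size (4B) + bytes,
                                      svb(values-256)  size (4B) + bytes,
                            where positions' = [p0, p1-p0-1, p2-p1-1, ...]
    one_byte_data           (num_samples-1) - n_x bytes, the zig-zag deltas
                            that fit in one byte, verbatim

The codec right-shifts every sample by the common count of zero
least-significant bits (>= the bits eliminated by any prior lossy
rounding), zig-zag encodes the first sample and the consecutive deltas,
and splits the deltas into one-byte values (<= 255) and exceptions
(> 255, stored minus 256 with their 0-based positions in the delta
sequence). Decoding inverts every step exactly.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .primitives import (
    INT16_MAX,
    INT16_MIN,
    _check_bits,
    common_trailing_zeros,
    zigzag_decode,
    zigzag_decode_array,
    zigzag_encode,
    zigzag_encode_array,
)
from .svb import svb_decode, svb_encode, svb_encoded_size

VERSION = 0
HEADER = struct.Struct("<BQBHI")  # version, num_samples, shift, first_zz, n_x
HEADER_SIZE = HEADER.size  # 16
_U32 = struct.Struct("<I")


class ExZdFormatError(ValueError):
    """Raised when a byte stream is not a well-formed ex-zd record."""


@dataclass(frozen=True)
class ExZdBlob:
    """Parsed view of one encoded record (introspection/debugging aid)."""

    version: int
    num_samples: int
    shift_bits: int
    first_sample_zz: int
    num_exceptions: int
    exception_block: bytes
    one_byte_data: bytes

    @property
    def size(self) -> int:
        return HEADER_SIZE + len(self.exception_block) + len(self.one_byte_data)


def _prepare(samples, eliminate_bits: int):
    _check_bits(eliminate_bits)
    s = np.asarray(samples, dtype=np.int64).ravel()
    if s.size == 0:
        raise ValueError("cannot encode an empty read")
    if s.min() < INT16_MIN or s.max() > INT16_MAX:
        raise ValueError("sample outside int16 range")
    shift = common_trailing_zeros(s)
    if shift < eliminate_bits:
        raise ValueError(
            f"samples are not rounded to multiples of 2^{eliminate_bits} "
            f"(common trailing zeros = {shift}); apply degrade_read first"
        )
    shifted = s >> shift
    first_zz = zigzag_encode(int(shifted[0]))
    if first_zz > 0xFFFF:
        raise ValueError(
            f"first sample {int(s[0])} does not fit the 2-byte zig-zag field"
        )
    zz = zigzag_encode_array(np.diff(shifted))
    exc_mask = zz > 255
    positions = np.flatnonzero(exc_mask).astype(np.uint64)
    exc_values = zz[exc_mask] - 256
    one_byte = zz[~exc_mask].astype(np.uint8)
    return s.size, shift, first_zz, positions, exc_values, one_byte


def _exception_block(positions: np.ndarray, exc_values: np.ndarray) -> bytes:
    n_x = positions.size
    if n_x == 0:
        return b""
    if n_x == 1:
        return _U32.pack(int(positions[0])) + _U32.pack(int(exc_values[0]))
    tpos = positions.copy()
    tpos[1:] = np.diff(positions) - 1  # first unchanged, rest delta minus 1
    pos_enc = svb_encode(tpos)
    val_enc = svb_encode(exc_values)
    return (
        _U32.pack(len(pos_enc)) + pos_enc + _U32.pack(len(val_enc)) + val_enc
    )


def exzd_encode(samples, eliminate_bits: int = 0) -> bytes:
    """Encode one read's samples into an ex-zd record.

    ``eliminate_bits`` documents how many low bits were zeroed by prior
    lossy rounding; the samples must already be multiples of 2**eliminate_bits
    (use :func:`exzd.degrade.degrade_and_encode` for the combined operation).
    """
    num, shift, first_zz, positions, exc_values, one_byte = _prepare(
        samples, eliminate_bits
    )
    header = HEADER.pack(VERSION, num, shift, first_zz, positions.size)
    return header + _exception_block(positions, exc_values) + one_byte.tobytes()


def exzd_encoded_size(samples, eliminate_bits: int = 0) -> int:
    """Closed-form record size in bytes; always equals len(exzd_encode(...))."""
    num, _shift, _fzz, positions, exc_values, _ob = _prepare(
        samples, eliminate_bits
    )
    n_x = positions.size
    if n_x == 0:
        exc = 0
    elif n_x == 1:
        exc = 8
    else:
        tpos = positions.copy()
        tpos[1:] = np.diff(positions) - 1
        exc = 8 + svb_encoded_size(tpos) + svb_encoded_size(exc_values)
    return HEADER_SIZE + exc + (num - 1 - n_x)


def decode_record(buf: bytes, offset: int = 0):
    """Decode one record starting at ``offset``.

    Returns ``(samples, end_offset)`` where ``end_offset`` is the first byte
    past the record — records are self-delimiting, so blobs can be unpacked
    from a concatenated stream.
    """
    if len(buf) - offset < HEADER_SIZE:
        raise ExZdFormatError(
            f"record truncated: {len(buf) - offset} bytes < {HEADER_SIZE}-byte header"
        )
    version, num, shift, first_zz, n_x = HEADER.unpack_from(buf, offset)
    pos = offset + HEADER_SIZE
    if version != VERSION:
        raise ExZdFormatError(f"unsupported ex-zd version {version}")
    if num == 0:
        raise ExZdFormatError("record declares zero samples")
    n_deltas = num - 1
    if n_x > n_deltas:
        raise ExZdFormatError(
            f"{n_x} exceptions exceed {n_deltas} delta slots"
        )

    if n_x == 0:
        positions = np.empty(0, dtype=np.int64)
        exc_values = np.empty(0, dtype=np.uint64)
    elif n_x == 1:
        if len(buf) - pos < 8:
            raise ExZdFormatError("record truncated in single-exception block")
        p, v = struct.unpack_from("<II", buf, pos)
        pos += 8
        positions = np.array([p], dtype=np.int64)
        exc_values = np.array([v], dtype=np.uint64)
    else:
        tpos, pos = _read_svb_block(buf, pos, n_x, "exception positions")
        exc_values, pos = _read_svb_block(buf, pos, n_x, "exception values")
        positions = np.empty(n_x, dtype=np.int64)
        positions[0] = int(tpos[0])
        positions[1:] = int(tpos[0]) + np.cumsum(tpos[1:].astype(np.int64) + 1)
        exc_values = exc_values.astype(np.uint64)

    if n_x and (positions[-1] >= n_deltas or positions[0] < 0):
        raise ExZdFormatError("exception position outside the delta sequence")
    if n_x > 1 and np.any(np.diff(positions) <= 0):
        raise ExZdFormatError("exception positions not strictly increasing")

    n_one = n_deltas - n_x
    if len(buf) - pos < n_one:
        raise ExZdFormatError(
            f"record truncated: one-byte data needs {n_one} bytes, "
            f"{len(buf) - pos} remain"
        )
    one_byte = np.frombuffer(buf, dtype=np.uint8, count=n_one, offset=pos)
    pos += n_one

    zz = np.empty(n_deltas, dtype=np.uint64)
    mask = np.zeros(n_deltas, dtype=bool)
    mask[positions] = True
    zz[mask] = exc_values + 256
    zz[~mask] = one_byte
    deltas = zigzag_decode_array(zz)
    first = zigzag_decode(first_zz)
    shifted = np.empty(num, dtype=np.int64)
    shifted[0] = first
    np.cumsum(deltas, out=shifted[1:])
    shifted[1:] += first
    samples = shifted << shift
    if samples.min() < INT16_MIN or samples.max() > INT16_MAX:
        raise ExZdFormatError("decoded sample outside int16 range")
    return samples.astype(np.int16), pos


def _read_svb_block(buf: bytes, pos: int, count: int, what: str):
    if len(buf) - pos < 4:
        raise ExZdFormatError(f"record truncated before {what} size field")
    (size,) = _U32.unpack_from(buf, pos)
    pos += 4
    if len(buf) - pos < size:
        raise ExZdFormatError(
            f"record truncated in {what}: need {size} bytes, {len(buf) - pos} remain"
        )
    values = svb_decode(buf[pos : pos + size], count)
    return values, pos + size


def exzd_decode(blob: bytes) -> np.ndarray:
    """Decode a single complete record; trailing bytes are an error."""
    samples, end = decode_record(blob, 0)
    if end != len(blob):
        raise ExZdFormatError(
            f"{len(blob) - end} trailing bytes after a {end}-byte record"
        )
    return samples


def parse_blob(blob: bytes) -> ExZdBlob:
    """Split a record into its named fields without decoding the samples."""
    version, num, shift, first_zz, n_x = HEADER.unpack_from(blob, 0)
    samples, end = decode_record(blob, 0)  # validates structure
    n_one = num - 1 - n_x
    return ExZdBlob(
        version=version,
        num_samples=num,
        shift_bits=shift,
        first_sample_zz=first_zz,
        num_exceptions=n_x,
        exception_block=bytes(blob[HEADER_SIZE : end - n_one]),
        one_byte_data=bytes(blob[end - n_one : end]),
    )
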