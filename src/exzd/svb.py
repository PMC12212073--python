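"""Stream variable-byte (svb) codec for unsigned 32-bit integers.

Scalar stream-vbyte layout: all 2-bit control codes come first, packed four
per control byte with the least-significant bit-pair describing the first
integer of the group, followed by the data bytes. Control code c means the
integer occupies c+1 little-endian data bytes (value 0 still takes one data
byte). This dialect is pinned by golden fixtures in the test suite; the
record container carries a codec identifier so a different dialect is
detectable rather than silently mis-decoded.
"""

from __future__ import annotations

import numpy as np

UINT32_MAX = (1 << 32) - 1

_BYTE_WEIGHTS = np.array([1, 1 << 8, 1 << 16, 1 << 24], dtype=np.uint64)


def svb_byte_length(value: int) -> int:
    """Minimal little-endian byte count (1..4) for one uint32."""
    if not 0 <= value <= UINT32_MAX:
        raise ValueError(f"svb value {value} outside uint32 range")
    if value < 1 << 8:
        return 1
    if value < 1 << 16:
        return 2
    if value < 1 << 24:
        return 3
    return 4


def svb_encoded_size(values) -> int:
    """ceil(k/4) control bytes plus the per-integer data bytes."""
    values = list(values)
    return (len(values) + 3) // 4 + sum(svb_byte_length(v) for v in values)


def svb_encode(values) -> bytes:
    """Encode a sequence of uint32 into the svb control+data byte stream."""
    v = np.asarray(list(values), dtype=np.uint64)
    if v.size == 0:
        return b""
    if v.max() > UINT32_MAX:
        raise ValueError("svb value outside uint32 range")
    lengths = np.ones(v.size, dtype=np.uint8)
    lengths += v >= (1 << 8)
    lengths += v >= (1 << 16)
    lengths += v >= (1 << 24)
    codes = lengths - 1

    pad = (-v.size) % 4
    codes_p = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)]).reshape(-1, 4)
    control = (
        codes_p[:, 0]
        | (codes_p[:, 1] << 2)
        | (codes_p[:, 2] << 4)
        | (codes_p[:, 3] << 6)
    ).astype(np.uint8)

    le_bytes = v.astype("<u4").view(np.uint8).reshape(-1, 4)
    keep = np.arange(4, dtype=np.uint8)[None, :] < lengths[:, None]
    data = le_bytes[keep]
    return control.tobytes() + data.tobytes()


def svb_decode(payload: bytes, count: int) -> np.ndarray:
    """Decode `count` uint32 values from an svb byte stream.

    Raises ValueError when the payload is shorter than the control bytes
    and data bytes imply.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        if payload:
            raise ValueError("non-empty svb payload for zero integers")
        return np.empty(0, dtype=np.uint32)
    n_control = (count + 3) // 4
    if len(payload) < n_control:
        raise ValueError(
            f"svb payload truncated: {len(payload)} bytes < {n_control} control bytes"
        )
    buf = np.frombuffer(payload, dtype=np.uint8)
    control = buf[:n_control]
    codes = np.empty(n_control * 4, dtype=np.uint8)
    codes[0::4] = control & 3
    codes[1::4] = (control >> 2) & 3
    codes[2::4] = (control >> 4) & 3
    codes[3::4] = (control >> 6) & 3
    lengths = codes[:count].astype(np.int64) + 1

    total = n_control + int(lengths.sum())
    if len(payload) < total:
        raise ValueError(
            f"svb payload truncated: {len(payload)} bytes, need {total}"
        )
    data = buf[n_control:total].astype(np.uint64)
    ends = np.cumsum(lengths)
    starts = ends - lengths
    # gather up to 4 bytes per value, masking positions beyond its length
    idx = starts[:, None] + np.arange(4)
    mask = np.arange(4)[None, :] < lengths[:, None]
    gathered = data[np.minimum(idx, len(data) - 1)] * mask
    values = (gathered * _BYTE_WEIGHTS[None, :]).sum(axis=1)
    return values.astype(np.uint32)
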