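"""The ex-zd record codec: wire-format goldens, round trips, size audit."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exzd.record import (
    ExZdFormatError,
    decode_record,
    exzd_decode,
    exzd_encode,
    exzd_encoded_size,
    parse_blob,
)


def test_golden_wire_format(golden):
    """Encodings are bit-exact against hand-derived fixtures, and decode back."""
    for entry in golden["records"]:
        samples = entry["samples"]
        blob = exzd_encode(samples, 0)
        assert blob.hex() == entry["hex"]
        assert list(exzd_decode(bytes.fromhex(entry["hex"]))) == samples
        assert exzd_encoded_size(samples, 0) == len(blob)


def test_hand_traced_blob_fields():
    """The 26-byte single-exception record: header fields as laid out."""
    blob = exzd_encode([100, 101, 99, 300], 0)
    assert len(blob) == 26
    parsed = parse_blob(blob)
    assert parsed.version == 0
    assert parsed.num_samples == 4
    assert parsed.shift_bits == 0
    assert parsed.first_sample_zz == 200
    assert parsed.num_exceptions == 1
    # position 2, value 402 - 256 = 146, both 4-byte little-endian
    assert parsed.exception_block == b"\x02\x00\x00\x00\x92\x00\x00\x00"
    assert parsed.one_byte_data == b"\x02\x03"


def test_degenerate_reads():
    assert list(exzd_decode(exzd_encode([5], 0))) == [5]
    assert len(exzd_encode([5], 0)) == 16
    constant = [1000] * 50
    blob = exzd_encode(constant, 0)
    parsed = parse_blob(blob)
    assert parsed.num_exceptions == 0
    assert set(parsed.one_byte_data) == {0}
    assert list(exzd_decode(blob)) == constant


def test_all_zero_read_uses_capped_shift():
    blob = exzd_encode([0, 0, 0], 0)
    assert parse_blob(blob).shift_bits == 15
    assert list(exzd_decode(blob)) == [0, 0, 0]


def test_encode_errors():
    with pytest.raises(ValueError, match="empty"):
        exzd_encode([], 0)
    with pytest.raises(ValueError, match="int16"):
        exzd_encode([70000], 0)
    with pytest.raises(ValueError, match="rounded"):
        exzd_encode([3, 5], 2)  # odd samples cannot claim 2 eliminated bits


def test_exhaustive_tiny_reads_lossless():
    """decode(encode(s)) = s for every read of length 1..3 over samples -4..4."""
    values = range(-4, 5)
    for length in (1, 2, 3):
        for samples in itertools.product(values, repeat=length):
            blob = exzd_encode(list(samples), 0)
            assert tuple(exzd_decode(blob)) == samples
            assert exzd_encoded_size(list(samples), 0) == len(blob)


def test_exception_partition_is_exact(rng):
    """Deltas > 255 after zig-zag appear only in the exception block; the
    one-byte stream holds exactly the remaining deltas."""
    from exzd.primitives import zigzag_encode_array

    s = rng.integers(-2000, 2000, size=500, dtype=np.int16)
    s[::7] = rng.integers(-32000, 32000, size=s[::7].size)  # force exceptions
    blob = exzd_encode(s, 0)
    parsed = parse_blob(blob)
    zz = zigzag_encode_array(np.diff(s.astype(np.int64)))
    assert parsed.num_exceptions == int((zz > 255).sum())
    assert parsed.one_byte_data == bytes(zz[zz <= 255].astype(np.uint8))
    assert np.array_equal(exzd_decode(blob), s)


def test_size_audit_random(rng):
    """Closed-form size equals actual encoded length on 10^3 random reads."""
    for _ in range(1000):
        n = int(rng.integers(1, 400))
        s = rng.integers(-32768, 32768, size=n, dtype=np.int16)
        assert exzd_encoded_size(s, 0) == len(exzd_encode(s, 0))


@given(
    st.lists(st.integers(min_value=-32768, max_value=32767), min_size=1, max_size=2000)
)
def test_roundtrip_property(samples):
    arr = np.array(samples, dtype=np.int16)
    assert np.array_equal(exzd_decode(exzd_encode(arr, 0)), arr)


def test_self_delimiting_stream(rng):
    """Concatenated records decode back one by one from their offsets."""
    reads = [
        rng.integers(-300, 300, size=int(rng.integers(1, 100)), dtype=np.int16)
        for _ in range(20)
    ]
    stream = b"".join(exzd_encode(r, 0) for r in reads)
    offset = 0
    for r in reads:
        decoded, offset = decode_record(stream, offset)
        assert np.array_equal(decoded, r)
    assert offset == len(stream)


@pytest.mark.parametrize(
    "mutate,match",
    [
        (lambda b: b"\x07" + b[1:], "version"),
        (lambda b: b[:10], "truncated"),
        (lambda b: b[:-1], "truncated"),
        (lambda b: b[:16] + b"\xff\xff\xff\xff" + b[20:], "position"),
    ],
)
def test_decode_named_errors(mutate, match):
    blob = exzd_encode([100, 101, 99, 300], 0)
    with pytest.raises(ExZdFormatError, match=match):
        exzd_decode(mutate(blob))


def test_exception_count_exceeding_slots_rejected():
    blob = bytearray(exzd_encode([100, 101, 99, 300], 0))
    blob[12:16] = (50).to_bytes(4, "little")  # n_x = 50 > 3 delta slots
    with pytest.raises(ExZdFormatError, match="exceed"):
        exzd_decode(bytes(blob))


def test_trailing_garbage_rejected():
    blob = exzd_encode([5], 0) + b"\x00"
    with pytest.raises(ExZdFormatError, match="trailing"):
        exzd_decode(blob)
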