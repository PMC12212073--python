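"""SLOW5-ASCII text I/O and the EZD binary container."""

import numpy as np
import pytest

from exzd import (
    CodecParams,
    SignalRead,
    pack_container,
    read_slow5_ascii,
    to_picoamperes,
    unpack_container,
    write_slow5_ascii,
)
from exzd.record import ExZdFormatError


def make_reads(rng, n=5):
    return [
        SignalRead(
            read_id=f"r{i}",
            digitisation=2048.0,
            offset=-243.0 + i,
            range=748.5801,
            sampling_rate=5000.0,
            samples=rng.integers(0, 2048, size=int(rng.integers(1, 400)), dtype=np.int16),
        )
        for i in range(n)
    ]


def test_fixture_file_parses_exactly(example_slow5_path):
    reads = read_slow5_ascii(example_slow5_path)
    assert len(reads) == 2
    first = reads[0]
    assert first.read_id == "read-0001"
    assert first.digitisation == 2048.0
    assert first.offset == -243.0
    assert list(first.samples) == [430, 432, 429, 700, 698, 702, 1105, 1103]
    assert first.extra == {"median_before": "219.2"}
    assert reads[1].samples.size == 5


def test_slow5_roundtrip_and_determinism(tmp_path, rng):
    reads = make_reads(rng)
    reads[0].extra["median_before"] = "12.5"
    p1, p2 = tmp_path / "a.slow5", tmp_path / "b.slow5"
    write_slow5_ascii(reads, p1)
    restored = read_slow5_ascii(p1)
    assert restored == reads
    write_slow5_ascii(restored, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_slow5_empty_data_section(tmp_path):
    p = tmp_path / "empty.slow5"
    p.write_text(
        "#read_id\tdigitisation\toffset\trange\tsampling_rate\t"
        "len_raw_signal\traw_signal\n"
    )
    assert read_slow5_ascii(p) == []


_HEADER = (
    "#read_id\tdigitisation\toffset\trange\tsampling_rate\t"
    "len_raw_signal\traw_signal\n"
)


@pytest.mark.parametrize(
    "row,match",
    [
        ("r1\t2048.0\t0.0\t748.6\t5000.0\t5\t1,2,3,4", "len_raw_signal=5"),
        ("r1\t2048.0\t0.0\t748.6\t5000.0\t3\t1,x,3", "non-integer"),
        ("r1\t2048.0\t0.0\t748.6\t5000.0\t3", "fields"),
    ],
)
def test_slow5_malformed_rows_cite_the_line(tmp_path, row, match):
    p = tmp_path / "bad.slow5"
    p.write_text(_HEADER + row + "\n")
    with pytest.raises(ValueError, match=match):
        read_slow5_ascii(p)


def test_slow5_missing_column(tmp_path):
    p = tmp_path / "bad.slow5"
    p.write_text("#read_id\toffset\n" "r1\t0.0\n")
    with pytest.raises(ValueError, match="digitisation"):
        read_slow5_ascii(p)


@pytest.mark.parametrize("zstd", [False, True])
def test_container_roundtrip(tmp_path, rng, zstd):
    reads = make_reads(rng)
    path = tmp_path / "out.ezd"
    size = pack_container(reads, CodecParams(0), path, zstd=zstd)
    assert size == path.stat().st_size
    restored, params = unpack_container(path)
    assert params.eliminate_bits == 0
    assert len(restored) == len(reads)
    for a, b in zip(reads, restored):
        assert a.read_id == b.read_id
        assert a.digitisation == b.digitisation
        assert np.array_equal(a.samples, b.samples)


def test_container_empty_read_list(tmp_path):
    path = tmp_path / "empty.ezd"
    pack_container([], CodecParams(0), path)
    reads, _ = unpack_container(path)
    assert reads == []


def test_container_named_errors(tmp_path, rng):
    path = tmp_path / "out.ezd"
    pack_container(make_reads(rng, 3), CodecParams(0), path)
    data = path.read_bytes()

    bad_magic = tmp_path / "bad_magic.ezd"
    bad_magic.write_bytes(b"XXXX" + data[4:])
    with pytest.raises(ExZdFormatError, match="magic"):
        unpack_container(bad_magic)

    bad_codec = tmp_path / "bad_codec.ezd"
    bad_codec.write_bytes(data[:4] + b"\x09" + data[5:])
    with pytest.raises(ExZdFormatError, match="codec_id"):
        unpack_container(bad_codec)

    truncated = tmp_path / "trunc.ezd"
    truncated.write_bytes(data[: len(data) // 2])
    with pytest.raises(ExZdFormatError, match="truncated"):
        unpack_container(truncated)


def test_picoampere_conversion():
    read = SignalRead(
        read_id="r",
        digitisation=2048.0,
        offset=10.0,
        range=1200.0,
        sampling_rate=5000.0,
        samples=np.array([100, 0], dtype=np.int16),
    )
    pa = to_picoamperes(read)
    assert pa[0] == pytest.approx(110 * 1200 / 2048)  # 64.453125
    assert pa[1] == pytest.approx(10 * 1200 / 2048)


def test_lossy_perturbation_in_picoamperes(rng):
    """n-bit rounding moves the calibrated current by <= 2^(n-1)*range/digitisation."""
    from exzd import degrade_read

    read = SignalRead(
        read_id="r",
        digitisation=2048.0,
        offset=-243.0,
        range=748.5801,
        sampling_rate=5000.0,
        samples=rng.integers(0, 2048, size=2000, dtype=np.int16),
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        degraded = SignalRead(
            read_id="r",
            digitisation=read.digitisation,
            offset=read.offset,
            range=read.range,
            sampling_rate=read.sampling_rate,
            samples=degrade_read(read.samples, CodecParams(3)),
        )
    delta = np.abs(to_picoamperes(read) - to_picoamperes(degraded)).max()
    assert delta <= 4 * read.range / read.digitisation + 1e-9
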