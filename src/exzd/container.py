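"""Signal-read I/O: SLOW5-ASCII text files and a minimal binary record container.

The text side speaks a minimal SLOW5-ASCII dialect — tab-separated data rows
under '#'-prefixed header lines, the last of which names the columns;
raw_signal is a comma-separated integer list. Unknown extra columns are
carried through round-trips as opaque strings.

The binary side is deliberately NOT BLOW5 (that format's read groups and
indices are out of scope): a magic tag "EZD0", a codec identifier, then
self-delimiting records of (read_id, calibration, ex-zd blob). It exists so
whole-file compression experiments have a well-defined file size. codec_id 1
additionally wraps each blob with zstd.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pyarrow as pa

from .degrade import CodecParams
from .record import ExZdFormatError, decode_record, exzd_encode

MAGIC = b"EZD0"
CODEC_PLAIN = 0
CODEC_ZSTD = 1

REQUIRED_COLUMNS = (
    "read_id",
    "digitisation",
    "offset",
    "range",
    "sampling_rate",
    "len_raw_signal",
    "raw_signal",
)

_zstd = pa.Codec("zstd")


@dataclass
class SignalRead:
    """One nanopore read: raw ADC samples plus per-read calibration.

    Current in picoamperes is recovered as (raw + offset) * range / digitisation.
    """

    read_id: str
    digitisation: float
    offset: float
    range: float
    sampling_rate: float
    samples: np.ndarray
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples)
        if arr.size < 1:
            raise ValueError(f"read {self.read_id!r} has no samples")
        if arr.dtype != np.int16:
            wide = arr.astype(np.int64)
            if wide.min() < -(1 << 15) or wide.max() > (1 << 15) - 1:
                raise ValueError(
                    f"read {self.read_id!r}: sample outside int16 range"
                )
            arr = wide.astype(np.int16)
        self.samples = arr
        if self.digitisation <= 0:
            raise ValueError(f"read {self.read_id!r}: digitisation must be > 0")
        if self.sampling_rate <= 0:
            raise ValueError(f"read {self.read_id!r}: sampling_rate must be > 0")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SignalRead)
            and self.read_id == other.read_id
            and self.digitisation == other.digitisation
            and self.offset == other.offset
            and self.range == other.range
            and self.sampling_rate == other.sampling_rate
            and np.array_equal(self.samples, other.samples)
            and self.extra == other.extra
        )


def to_picoamperes(read: SignalRead) -> np.ndarray:
    """Standard ONT linear calibration: pA = (raw + offset) * range / digitisation."""
    return (
        (read.samples.astype(np.float64) + read.offset)
        * read.range
        / read.digitisation
    )


# ---------------------------------------------------------------- SLOW5 text


def read_slow5_ascii(path) -> list[SignalRead]:
    """Parse a SLOW5-ASCII file into SignalRead objects."""
    path = Path(path)
    columns: list[str] | None = None
    reads: list[SignalRead] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                columns = line.lstrip("#").split("\t")
                continue
            if line.startswith("@"):  # attribute lines of the full format
                continue
            if columns is None:
                raise ValueError(
                    f"{path}:{lineno}: data row before any '#' column header"
                )
            missing = [c for c in REQUIRED_COLUMNS if c not in columns]
            if missing:
                raise ValueError(
                    f"{path}: column header lacks required columns {missing}"
                )
            fields = line.split("\t")
            if len(fields) != len(columns):
                raise ValueError(
                    f"{path}:{lineno}: {len(fields)} fields for "
                    f"{len(columns)} columns"
                )
            row = dict(zip(columns, fields))
            try:
                samples = np.array(
                    [int(tok) for tok in row["raw_signal"].split(",")],
                    dtype=np.int64,
                )
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer raw_signal value ({exc})"
                ) from None
            declared = int(row["len_raw_signal"])
            if declared != samples.size:
                raise ValueError(
                    f"{path}:{lineno}: len_raw_signal={declared} but "
                    f"{samples.size} samples present"
                )
            extra = {
                k: v
                for k, v in row.items()
                if k not in REQUIRED_COLUMNS and v != ""
            }
            reads.append(
                SignalRead(
                    read_id=row["read_id"],
                    digitisation=float(row["digitisation"]),
                    offset=float(row["offset"]),
                    range=float(row["range"]),
                    sampling_rate=float(row["sampling_rate"]),
                    samples=samples,
                    extra=extra,
                )
            )
    return reads


def write_slow5_ascii(reads, path) -> None:
    """Write reads as SLOW5-ASCII; byte-deterministic for fixed input."""
    reads = list(reads)
    extra_cols: list[str] = []
    for r in reads:
        for k in r.extra:
            if k not in extra_cols:
                extra_cols.append(k)
    columns = list(REQUIRED_COLUMNS) + extra_cols
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("#" + "\t".join(columns) + "\n")
        for r in reads:
            row = [
                r.read_id,
                repr(float(r.digitisation)),
                repr(float(r.offset)),
                repr(float(r.range)),
                repr(float(r.sampling_rate)),
                str(r.samples.size),
                ",".join(str(int(v)) for v in r.samples),
            ]
            row.extend(r.extra.get(k, "") for k in extra_cols)
            fh.write("\t".join(row) + "\n")


# ------------------------------------------------------------ binary container

_FILE_HEADER = struct.Struct("<4sBBBQ")  # magic, codec_id, elim_bits, native, n
_REC_FIXED = struct.Struct("<H4dQQ")  # id_len, 4 calib doubles, raw_len, stored


def pack_container(reads, params: CodecParams, path, *, zstd: bool = False) -> int:
    """Degrade (if params say so), ex-zd encode and write all reads.

    Returns the total file size in bytes.
    """
    from .degrade import degrade_read

    reads = list(reads)
    codec_id = CODEC_ZSTD if zstd else CODEC_PLAIN
    path = Path(path)
    with path.open("wb") as fh:
        fh.write(
            _FILE_HEADER.pack(
                MAGIC,
                codec_id,
                params.eliminate_bits,
                params.instrument_native_bits,
                len(reads),
            )
        )
        for r in reads:
            samples = degrade_read(r.samples, params)
            blob = exzd_encode(samples, params.eliminate_bits)
            payload = (
                _zstd.compress(blob, asbytes=True) if zstd else blob
            )
            rid = r.read_id.encode("utf-8")
            fh.write(
                _REC_FIXED.pack(
                    len(rid),
                    r.digitisation,
                    r.offset,
                    r.range,
                    r.sampling_rate,
                    len(blob),
                    len(payload),
                )
            )
            fh.write(rid)
            fh.write(payload)
        return fh.tell()


def unpack_container(path) -> tuple[list[SignalRead], CodecParams]:
    """Inverse of :func:`pack_container` (exact when eliminate_bits was 0)."""
    buf = Path(path).read_bytes()
    if len(buf) < _FILE_HEADER.size:
        raise ExZdFormatError("container shorter than its header")
    magic, codec_id, elim, native, n_reads = _FILE_HEADER.unpack_from(buf, 0)
    if magic != MAGIC:
        raise ExZdFormatError(f"bad magic {magic!r}; not an EZD0 container")
    if codec_id not in (CODEC_PLAIN, CODEC_ZSTD):
        raise ExZdFormatError(f"unknown codec_id {codec_id}")
    pos = _FILE_HEADER.size
    reads: list[SignalRead] = []
    for i in range(n_reads):
        if len(buf) - pos < _REC_FIXED.size:
            raise ExZdFormatError(f"container truncated at record {i}")
        id_len, dig, off, rng, rate, raw_len, stored_len = _REC_FIXED.unpack_from(
            buf, pos
        )
        pos += _REC_FIXED.size
        if len(buf) - pos < id_len + stored_len:
            raise ExZdFormatError(f"container truncated at record {i}")
        rid = buf[pos : pos + id_len].decode("utf-8")
        pos += id_len
        payload = buf[pos : pos + stored_len]
        pos += stored_len
        blob = (
            _zstd.decompress(payload, raw_len, asbytes=True)
            if codec_id == CODEC_ZSTD
            else payload
        )
        samples, end = decode_record(blob, 0)
        if end != raw_len:
            raise ExZdFormatError(
                f"record {i}: blob length {raw_len} but record ends at {end}"
            )
        reads.append(
            SignalRead(
                read_id=rid,
                digitisation=dig,
                offset=off,
                range=rng,
                sampling_rate=rate,
                samples=samples,
            )
        )
    if pos != len(buf):
        raise ExZdFormatError(f"{len(buf) - pos} trailing bytes after last record")
    return reads, CodecParams(eliminate_bits=elim, instrument_native_bits=native)
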