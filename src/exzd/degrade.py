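"""Lossy bit elimination: round away the n least-significant bits, then encode.

PromethION signal is natively 11-bit, MinION 13-bit; validation in the
wider ecosystem supports removing up to 3 bits with no measurable impact on
basecalling or modified-base detection, so callers are warned above that.
The operation is irreversible: decoded samples differ from the originals by
at most 2**(n-1) ADC counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .primitives import _check_bits, round_low_bits_array
from .record import exzd_encode

#: bits removed without measurable downstream impact on DNA/RNA analyses
VALIDATED_MAX_BITS = 3


@dataclass(frozen=True)
class CodecParams:
    """Lossy codec settings.

    eliminate_bits: number n of least-significant bits to zero (0 = lossless).
    instrument_native_bits: informational ADC depth (11 PromethION, 13 MinION).
    """

    eliminate_bits: int = 0
    instrument_native_bits: int = 11

    def __post_init__(self) -> None:
        _check_bits(self.eliminate_bits)
        if self.eliminate_bits > VALIDATED_MAX_BITS:
            warnings.warn(
                f"eliminating {self.eliminate_bits} bits exceeds the "
                f"{VALIDATED_MAX_BITS}-bit envelope validated against "
                "basecalling and modified-base detection; proceed with care",
                UserWarning,
                stacklevel=2,
            )


def degrade_read(samples, params: CodecParams) -> np.ndarray:
    """Round every sample to the nearest multiple of 2**n (ties up).

    Idempotent; never touches calibration metadata. Returns int16.
    """
    return round_low_bits_array(np.asarray(samples), params.eliminate_bits)


def degrade_and_encode(samples, params: CodecParams) -> bytes:
    """Apply lossy rounding then ex-zd lossless encoding in one step."""
    return exzd_encode(degrade_read(samples, params), params.eliminate_bits)
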