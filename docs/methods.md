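# Methods

## The record codec

One nanopore read is a chain of signed 16-bit ADC counts. The codec
exploits two properties of that chain: consecutive samples are close in
value (so deltas are small), and lossy bit elimination leaves guaranteed
trailing zero bits (so a right shift is free).

Encoding pipeline, per read:

1. **Shift.** Compute the minimum, over all samples, of the trailing-zero
   count of the two's-complement 16-bit pattern (the count for the value 0
   is defined as 16 and the result is capped at 15 so an all-zero read
   still has a meaningful one-byte shift). Arithmetic-right-shift every
   sample by that amount and store it in the header. The decoder
   left-shifts by the same amount. Storing the *actual* common shift —
   which is always ≥ the number of lossily eliminated bits — rather than
   the requested elimination count is what makes the round trip exact when
   data happens to have extra natural trailing zeros.
2. **Zig-zag deltas.** The first (shifted) sample and the consecutive
   differences are mapped to unsigned integers: `2v` for `v ≥ 0`,
   `2|v| − 1` for `v < 0`. The first sample's code is stored in a 2-byte
   header field (any int16 first sample fits: the largest code is 65535).
3. **Partition.** Delta codes ≤ 255 are the *one-byte data*, written
   verbatim at the end of the record. Codes > 255 are *exceptions*: each
   is stored minus 256 (256 being the smallest possible exception),
   together with its 0-based position in the delta sequence.
4. **Exception block.** Zero exceptions: nothing. Exactly one: position
   and value, 4 bytes each. More than one: positions are transformed
   (first kept, the rest delta-encoded minus 1 — strictly increasing
   positions make every transformed value non-negative), then positions
   and values are each streamvbyte-encoded and written as a 4-byte size
   followed by the bytes.

All multi-byte fields are little-endian. Records are self-delimiting —
every block length is derivable from header fields — so a container can
concatenate them without an index. The wire dialect (version byte 0,
control-bytes-first scalar streamvbyte with little-endian minimal-length
data bytes) is pinned by hand-derived golden fixtures in
`tests/data/golden_records.json`.

Worst case: adversarial full-range int16 input can produce zig-zag deltas
up to 131070. These are still representable (exceptions are uint32 in the
streamvbyte block); only the *first sample* field is hard-limited to 2
bytes, and that limit cannot be exceeded by int16 input. The bare record
stream stores each one-byte delta verbatim, so its size floors at one byte
per sample plus the 16-byte header: the asymptotic ratio of the bare codec
on clean data is ~2. File-level deployments therefore pair the record
codec with a general-purpose entropy coder; this package exposes a
zstd-wrapped variant (via pyarrow's zstd codec), and the per-bit savings of
bit elimination are measured on that wrapped form, where they accumulate
(~12–18% per bit on the synthetic defaults) instead of saturating at the
one-byte floor.

## Lossy bit elimination

To eliminate `n ∈ 0..8` bits, each sample is rounded to a multiple of
`2^n` with the bit operation `(x & ~(2^n − 1)) + 2^n · bit_{n−1}(x)`:
bit `n−1` is set exactly when the low `n` bits are ≥ `2^(n−1)`, so this is
"nearest multiple, ties up". Three numerical choices:

- **Ties round up**, as the formula computes (a prose description of
  "whichever is closer" does not determine the halfway case).
- **Negative samples** are rounded on their two's-complement pattern, which
  still lands on the nearest multiple of `2^n` (ties toward +∞); ONT
  stores signal as signed int16 and values can be negative.
- **Saturation**: when rounding up would exceed +32767 the result clamps
  to the largest representable multiple of `2^n`. The per-sample error
  bound of `2^(n−1)` holds everywhere except those top
  `2^(n−1) − 1` input values (where the error is still `< 2^n`); real ADC
  values live in 0..8191 and never approach the boundary. Tests assert the
  strict bound exhaustively over the 13-bit range and the clamp behaviour
  at the boundary.

The operator is idempotent and never touches calibration metadata, so the
picoampere conversion `pA = (raw + offset) × range / digitisation` is
perturbed by at most `2^(n−1) × range / digitisation` (≈ 1.5 pA at n = 3
with typical PromethION calibration). `eliminate_bits ≤ 3` is the
validated envelope (no measurable impact on basecalling or modified-base
detection in the ecosystem's published evaluations); the API accepts up to
8 and warns above 3.

## Synthetic signal model

`SyntheticModel` emulates only the statistics a codec sees:

| parameter | default | meaning |
|---|---|---|
| `adc_bits` | 11 | ADC depth (11 PromethION, 13 MinION); clamp range `[0, 2^bits − 1]` |
| `level_means` | 35% and 65% of range | two-component Gaussian mixture of segment levels (ADC counts) |
| `level_sds` | 6% of range each | mixture spreads |
| `level_weight` | 0.5 | weight of the first component |
| `dwell_mean` | 10 | geometric mean samples per constant-level segment |
| `noise_sd` | 1.5% of range (≈31 counts) | additive Gaussian sample noise |
| `spike_rate` | 0 | probability a sample with low bits 11₂ is displaced +1 |

Reads are piecewise-constant level sequences with geometric dwells, plus
noise, rounded and clamped; generated reads carry PromethION-typical
calibration (digitisation 2048, range ≈748.58 pA, 5 kHz). The spike
injector is a phenomenological stand-in for the converter artifact seen in
real data (excess frequency where the two low bits roll over 11₂→00₂): it
lives entirely in the two lowest bits, so 2-bit degradation must erase it —
the property the analysis experiments assert.

What the model does *not* capture: k-mer-dependent level structure (the
real spike artifact is unrelated to the sample's k-mer profile, and codec
behaviour depends only on level/dwell/noise statistics), RNA-specific
signal, adapter/stall segments, and long-range drift. Consequently the
absolute compression ratios measured on synthetic data (≈1.70 bare, ≈1.83
zstd-wrapped at the defaults) characterise the synthetic noise level, not
any particular real dataset; published whole-dataset ratios on real
PromethION data are higher (≈2.35) because real signal is less noisy than
the deliberately conservative defaults here. The *relative* claims the
tests assert — exact losslessness, the error bound, ≥10% savings per
eliminated bit, spike flattening — transfer, the absolute ratios do not.

## The spike score

The artifact metric is this package's own (the phenomenon is usually shown,
not quantified): over interior histogram bins `v` whose neighbours are
occupied (`c(v−1) + c(v+1) > 0`), average `max(0, log2(c(v) / mean(c(v−1),
c(v+1))))`. A flat histogram scores 0; one doubled bin over a flat
background contributes exactly 1 at that bin. The positive part is taken so
dips do not cancel spikes. Two consequences worth knowing: Poisson counting
noise gives even a smooth histogram a small positive score (≈0.08–0.09 at
10⁶ samples over 2048 bins), and a 2-bit-degraded histogram — computed at
native scale, so only multiples of 4 are occupied — scores exactly 0
because every eligible interior bin is empty. Spike-flattening assertions
are therefore one-sided: the degraded score must drop to at most the
spike-free baseline plus a small tolerance.

## Containers and formats

SLOW5-ASCII support is the minimal dialect needed to exchange fixtures:
'#'-prefixed header lines (the last names the columns), tab-separated rows,
comma-separated `raw_signal`, required columns `read_id, digitisation,
offset, range, sampling_rate, len_raw_signal, raw_signal`; unknown columns
round-trip as opaque strings (empty values are dropped on read). The binary
container ("EZD0" magic) is deliberately not BLOW5 — no read groups, no
index — just enough structure that file sizes in benchmarks are
well-defined; a codec-id byte distinguishes plain from zstd-wrapped records
so foreign dialects fail loudly.

The benchmark set is a deliberate 7-method subset — raw, zlib, zstd, the
zigzag-delta+streamvbyte transform under zlib or zstd (the ecosystem's
default file method), and the record codec plain or zstd-wrapped — enough
to rank the codec locally without reimplementing dozens of transform
chains. Compression ratio is always uncompressed/compressed with the
uncompressed size fixed at 2 bytes per sample.

## Problem sizes

Desk-scale defaults keep every check fast while staying statistically
decisive: exhaustive enumerations where feasible (all reads of length ≤3
over samples −4..4; all 65536 int16 values for the rounding operator; the
full 13-bit ADC range for the reconstruction bound), 10⁴ random reads for
round-trip and oracle-equivalence properties, 100 reads × 5000 samples for
compression tables, and 10⁶ samples for histogram assertions.

## Known limitations

- The streamvbyte dialect is the scalar control-bytes-first layout; if an
  external implementation uses a permuted ("0124") layout, records are not
  interchangeable — the version/codec-id bytes make that detectable.
- Whether external ex-zd writers keep placeholders in the one-byte stream
  at exception positions is not publicly specified; this codec excludes
  exceptions from the one-byte stream (consistent with the separate-blocks
  layout and strictly smaller output), and the golden fixtures pin that
  choice.
- No BLOW5/POD5/FAST5 parsing, no SIMD, no multi-threading.
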