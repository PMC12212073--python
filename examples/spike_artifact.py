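"""The ADC spike artifact and how 2-bit degradation erases it.

Real nanopore value histograms show excess counts where the two lowest bits
roll over 11 -> 00. The generator injects that artifact; the spike score
quantifies it; rounding away 2 bits removes it entirely because it lives in
the two least-significant bits.
"""

import warnings

from exzd import (
    CodecParams,
    SyntheticModel,
    degrade_read,
    simulate_dataset,
    spike_score,
    value_histogram,
)

warnings.simplefilter("ignore", UserWarning)

spiked = simulate_dataset(SyntheticModel(spike_rate=0.3), 10, 100_000, seed=5)
clean = simulate_dataset(SyntheticModel(spike_rate=0.0), 10, 100_000, seed=5)
degraded = [degrade_read(r.samples, CodecParams(2)) for r in spiked]

for label, data in [("spiked, native", spiked), ("spike-free, native", clean),
                    ("spiked, 2-bit degraded", degraded)]:
    print(f"{label:>24s}: spike score {spike_score(value_histogram(data, 11)):.4f}")
# The spiked histogram scores well above the spike-free baseline; after
# 2-bit degradation the score drops to 0 — the artifact is gone, mirroring
# the flattening seen when real data is re-encoded with fewer bits.
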