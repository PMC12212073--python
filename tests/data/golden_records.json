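{
  "_comment": "Hand-derived ex-zd record fixtures pinning the wire dialect. Each entry: input samples (eliminate_bits=0) and the expected encoding as hex. Derivations: single exception (zig-zag deltas 2,3,402 -> exception 402-256=146 at position 2); single-sample degenerate; common right-shift of 2 (all samples multiples of 4, deltas +-75 zig-zag to 150/149); three exceptions exercising the svb position transform [p0, p1-p0-1, p2-p1-1] = [0,0,0] and svb values [2,1486,1743].",
  "records": [
    {
      "samples": [100, 101, 99, 300],
      "hex": "00040000000000000000c8000100000002000000920000000203"
    },
    {
      "samples": [5],
      "hex": "000100000000000000000a0000000000"
    },
    {
      "samples": [0, 300, 0, 300, 0],
      "hex": "0005000000000000000200000000000096959695"
    },
    {
      "samples": [0, 129, 1000, 0],
      "hex": "000400000000000000000000030000000400000000000000060000001402ce05cf06"
    }
  ],
  "svb": [
    { "values": [], "hex": "" },
    { "values": [0], "hex": "0000" },
    { "values": [256], "hex": "010001" },
    { "values": [1, 2, 3, 4, 5], "hex": "00000102030405" },
    { "values": [4294967295], "hex": "03ffffffff" },
    { "values": [1, 256, 65536, 16777216], "hex": "e401000100000100000001" }
  ]
}
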