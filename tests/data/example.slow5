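#read_id	digitisation	offset	range	sampling_rate	len_raw_signal	raw_signal	median_before
read-0001	2048.0	-243.0	748.5801	5000.0	8	430,432,429,700,698,702,1105,1103	219.2
read-0002	2048.0	-219.5	748.5801	5000.0	5	512,516,508,504,520	184.5
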