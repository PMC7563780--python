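target_size_mb: 1.3
genome_size_mb: 3101.79
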