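Package data directory; referenced by the $DATA shorthand in configuration files.
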