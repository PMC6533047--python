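url	label
https://example.org/aa/home	AA
https://example.org/aa/meeting-finder	AA
https://example.org/aa/meeting-directory	AA
https://example.org/aa/twelve-steps	AA
https://example.org/aa/contact	AA
https://example.org/na/home	NA
https://example.org/na/meeting-search	NA
https://example.org/na/contact	NA
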