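chr15	39500	48000	1.9520	1000	+
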