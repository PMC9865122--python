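# Store-operated calcium entry (SOCE) seed genes for prioritization demos
SURF4
STIM1
ORAI1
CRACR2A
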