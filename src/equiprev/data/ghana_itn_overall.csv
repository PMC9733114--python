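setting,year,mu
Ghana,2011,32.6
Ghana,2017,49.7
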