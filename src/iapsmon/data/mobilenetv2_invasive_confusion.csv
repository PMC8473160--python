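observed,Invasive,Non-invasive
Invasive,755,390
Non-invasive,289,706
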