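load_g,reading_raw16
200,21440
500,36480
1000,44480
1500,46880
2000,48000
3000,50400
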