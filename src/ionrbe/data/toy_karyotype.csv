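# Two-chromosome toy karyotype for fast tests and worked examples.
name,length_mbp,centromere_mbp,copies
A,100.0,40.0,1
B,80.0,30.0,1
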