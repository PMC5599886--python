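chr1	9000
chr2	5000
chr3	2000
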