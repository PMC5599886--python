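chr2L	23011544
chr2R	21146708
chr3L	24543557
chr3R	27905053
chr4	1351857
chrX	22422827
chrM	19517
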