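m,k_max
3,22
4,77
5,280
6,777
7,1730
8,2847
9,3763
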