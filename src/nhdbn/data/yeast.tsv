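CBF1	GAL4
GAL4	SWI5
SWI5	CBF1
SWI5	GAL80
SWI5	ASH1
GAL80	SWI5
GAL80	GAL4
ASH1	CBF1
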