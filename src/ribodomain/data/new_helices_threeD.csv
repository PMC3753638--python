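helix_name,ranges
25a,562-578
26a,1262-1270;2010-2017
49a,1611-1620
49b,1309-1313;1603-1605
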