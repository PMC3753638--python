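label,ranges
0,562-586;1251-1270;1648-1678;1990-2057;2611-2625
I,1-561;2895-2904
II,587-1250
III,1271-1647
IV,1679-1989
V,2058-2610
VI,2626-2894
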