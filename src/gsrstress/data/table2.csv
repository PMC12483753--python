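Person 1,Person 2,Person 3,Person 4,Person 5,Person 6,Person 7,Person 8,Person 9,Person 10,Person 11,Person 12,Person 13,Person 14,Person 15,Person 16
432,378,254,189,493,335,285,155,458,369,254,149,501,387,280,175
487,362,273,176,486,370,268,172,480,357,288,160,482,348,290,199
410,395,289,190,501,321,222,144,490,323,275,198,495,363,267,145
478,319,215,145,452,366,295,189,493,358,262,130,490,330,240,181
465,342,278,160,415,354,211,139,477,316,251,142,485,374,228,150
499,389,260,192,488,306,272,181,481,376,265,160,478,309,265,135
421,331,290,175,460,384,283,160,498,310,242,155,468,399,245,160
439,350,223,182,473,350,263,174,485,332,225,171,479,322,271,138
480,372,299,198,420,399,295,177,472,335,250,148,481,340,254,182
446,313,202,140,497,333,261,168,486,356,239,180,490,377,290,155
455,388,267,174,488,356,216,135,494,373,267,165,495,365,229,172
472,359,276,185,475,380,234,192,497,389,293,133,479,350,271,160
429,347,241,159,466,353,299,150,470,349,276,190,480,310,285,145
485,365,280,191,,,,,,,,,,,,
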