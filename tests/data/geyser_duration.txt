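4.0166667
2.15
4
4
4
2
4.3833333
4.2833333
2.0333333
4.8333333
1.8333333
5.45
1.6166667
4.8666667
4.3833333
1.7666667
4.6666667
2
4.7333333
4.2166667
1.9
4.9666667
2
4
2
4
2.8333333
4.5
4.0666667
3.7166667
3.5166667
4.4666667
2.2166667
4.8833333
2.6
4.15
2.2
4.7666667
1.8333333
4.6
2.2666667
4.1333333
2
4
2
4
1.8833333
4.2666667
2.0833333
4.4666667
2.5
4
1.7666667
4.3333333
2.1833333
4.4833333
3.8833333
3.3333333
3.7333333
4
1.95
5.2666667
2
4
2
4
2
4
3.5333333
2.1666667
4.5
2.0166667
4.15
4.2
4.3333333
1.9333333
4.65
3.8166667
4.0333333
4.1666667
4.6666667
1.8166667
4
3
4
2
4.45
2.05
4.25
1.9166667
4.6666667
1.7333333
4.3833333
1.7666667
4.6
1.8666667
4.45
1.6333333
5.0333333
1.8166667
5.1
1.6333333
4.2833333
2
4
2
4.5333333
2
4
2.9333333
4.7333333
3.9
1.95
4.1166667
1.8
4.6666667
1.8333333
4.7
2.1166667
4.7833333
1.8166667
4.1
4.65
4
2
4
4
4.2166667
4.1333333
3.9333333
3.75
4.4166667
2.4666667
4.1666667
3.8
4.3166667
3.8666667
4.6833333
1.7
4.9666667
4.2666667
4.5833333
4
4
4
4
1.9833333
4.6
0.8333333
4.9166667
1.7333333
4.5833333
1.7
4.75
1.8333333
4.5
1.8666667
4.45
4.45
4
4.8
4
4
2
4
1.9333333
4.5833333
2
3.7
2.8666667
4.8333333
3.45
4.3833333
1.8
4.4
2.4833333
4.5166667
2.1
4.35
4.3666667
1.7833333
4.9166667
1.8166667
4
4
4
3.8666667
1.85
4.7
2.0166667
4.4666667
1.8666667
4.1666667
1.9
4.25
3.25
4.2166667
1.8833333
4.9833333
1.85
4
1.9666667
4.7666667
4
2
4
4
2.3833333
4.4166667
4.2166667
4.3666667
2
4.45
1.75
4.5
1.6166667
4.7
2.5666667
3.7
4.2333333
1.9333333
4.35
4
4
4
4.2166667
4
4.1333333
1.8833333
4.4666667
1.95
4.2166667
1.7166667
4.45
4.25
3.9666667
4.3833333
1.9666667
4.45
4.2666667
1.9166667
4.4166667
3
4
2
4
3.2833333
1.8333333
4.6166667
1.8333333
4.6166667
4.6
4.25
1.9333333
4.9833333
1.9666667
4.3
4.2
4.5333333
4.4
4.6166667
2
4
4
3.9166667
2
4.5
1.8
4
2.75
4.7333333
3.9666667
1.95
4.9666667
1.85
4.8
4
4
4
4
4
4
4
2
4
1.9333333
4.3333333
1.6666667
4.7666667
1.95
4.6833333
1.9333333
4.4166667
2.1333333
4.0833333
2.0666667
4
4
2
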