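26
relaxed neutral G2S2 dendrimer conformation, centred on the COM; Rg=2.0486
m 0.19408402 -0.22012265 -0.40292376
m -0.63762171 -0.38332011 -0.94274020
m -0.01047778 -0.84014197 0.36665329
m -0.01784344 -1.74605666 0.64673678
m 0.98544246 0.25232199 -0.69043223
m 1.68695112 0.77934070 -1.01997015
m -0.12877120 0.37538655 -1.36514230
m 0.21332147 1.25341857 -1.14256874
m -1.41122225 -0.96804522 -0.94022696
m -1.48198275 -0.82128813 0.02446470
m 0.13451880 -2.65110326 0.76191801
m -0.31290281 -3.29989377 1.28839789
m 0.25857587 -1.27824636 1.39433629
m 0.18147326 -0.40041898 1.79889096
m 2.16384455 1.52185425 -0.67863547
m 1.86683283 2.05634734 0.05231781
m 1.93014154 0.27439764 -0.19782122
m 1.71589131 0.51979833 0.65342266
m 0.41034161 1.38569028 -0.14767041
m 0.85853118 2.16204497 0.32584769
m -0.65739107 1.35106856 -0.89682495
m -0.77975132 2.22316331 -0.56906072
m -2.15833601 -1.29233009 0.60740792
m -1.76693839 -0.99867598 1.44154202
m -1.93306876 0.03354323 -0.26770829
m -1.30364254 0.71126746 -0.10021064
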