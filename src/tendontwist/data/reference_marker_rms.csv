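# RMS error (mm) between predicted and recorded marker positions for ten
# cadaver Achilles tendons calibrated at five fascicle-twist angles,
# transcribed from the published per-subject table of the cadaver
# calibration study this pipeline's synthetic cohort emulates.
# Rows 1-10: subjects; Average/SD: the study's printed summary rows.
subject,deg0,deg15,deg30,deg45,deg60
1,0.268,0.276,0.319,0.316,0.280
2,0.234,0.265,0.289,0.265,0.341
3,0.283,0.301,0.303,0.305,0.274
4,0.269,0.275,0.278,0.277,0.259
5,0.405,0.402,0.404,0.404,0.399
6,0.317,0.321,0.326,0.323,0.284
7,0.356,0.361,0.371,0.360,0.371
8,0.556,0.566,0.569,0.567,0.548
9,0.256,0.258,0.262,0.259,0.250
10,0.314,0.312,0.312,0.312,0.313
Average,0.326,0.334,0.343,0.339,0.332
SD,0.096,0.093,0.090,0.091,0.090
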