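# Optimized material coefficients (C1, C3 in MPa; C4 dimensionless) for ten
# cadaver Achilles tendons at five fascicle-twist angles, transcribed from
# the published per-subject table of the cadaver calibration study.
# NOTE: the study's printed Average row does not equal the mean of its own
# printed per-subject values; per-subject values are authoritative here and
# are used only to set optimizer bounds, never as calibration targets.
subject,c1_deg0,c1_deg15,c1_deg30,c1_deg45,c1_deg60,c3_deg0,c3_deg15,c3_deg30,c3_deg45,c3_deg60,c4_deg0,c4_deg15,c4_deg30,c4_deg45,c4_deg60
1,38.07,38.18,46.00,75.39,78.00,11.57,12.92,13.00,3.41,9.10,30.65,30.67,24.00,1.12,9.00
2,22.74,23.24,34.16,29.34,89.54,13.23,21.95,5.97,6.03,9.75,42.03,33.82,64.28,69.02,5.92
3,43.13,30.15,27.34,29.82,29.81,2.21,6.28,1.64,2.91,3.08,97.37,70.23,124.02,99.77,99.79
4,49.92,46.37,55.02,46.39,46.33,14.05,11.71,9.20,11.86,12.20,42.19,53.45,56.27,53.53,53.68
5,164.18,146.57,148.07,146.52,143.10,31.73,36.18,37.29,34.98,37.37,2.95,2.68,2.40,2.81,2.91
6,46.52,42.62,39.07,41.84,21.76,15.29,3.34,5.76,3.79,14.37,26.80,62.70,50.43,60.17,39.57
7,40.20,14.28,40.06,14.65,31.62,4.98,4.06,5.82,4.82,1.79,83.34,127.14,80.12,117.72,155.45
8,35.73,12.79,14.54,11.27,6.92,6.22,3.09,2.92,3.33,4.25,73.12,100.00,99.83,100.00,100.00
9,25.38,24.68,21.97,23.40,21.61,7.90,1.68,2.76,2.50,3.77,14.59,83.82,70.14,74.02,64.76
10,98.95,142.59,142.78,140.35,143.10,27.06,35.88,35.62,33.70,35.49,26.15,3.55,3.53,4.11,3.65
Average,70.03,53.70,56.90,53.73,59.31,16.40,13.80,12.00,11.55,13.56,41.04,59.71,57.50,64.57,58.41
SD,54.19,52.74,39.72,52.11,52.84,15.17,14.06,11.04,13.23,13.67,36.20,41.81,36.78,40.37,52.57
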