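# Approximate complex refractive index of crystalline silicon, 400-800 nm,
# interpolated from literature-typical room-temperature values.
wavelength_nm,n,k
400,5.570,0.387
420,5.010,0.269
440,4.790,0.183
460,4.580,0.131
480,4.430,0.096
500,4.300,0.073
520,4.200,0.057
540,4.120,0.044
560,4.050,0.036
580,3.990,0.030
600,3.940,0.025
620,3.900,0.021
640,3.860,0.018
660,3.830,0.016
680,3.800,0.013
700,3.780,0.011
720,3.760,0.010
740,3.740,0.009
760,3.720,0.008
780,3.700,0.007
800,3.690,0.006
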