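t_ms,dx_counts,dy_counts,x_counts,y_counts,x_mm,y_mm
0,0,3,0,3,0.000000,0.047625
8,0,-1,0,2,0.000000,0.031750
16,0,2,0,4,0.000000,0.063500
24,0,0,0,4,0.000000,0.063500
32,0,-4,0,0,0.000000,0.000000
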