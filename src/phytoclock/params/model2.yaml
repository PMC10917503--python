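variant: MODEL2
K1: 0.3
K10: 1.9
K11: 4.15
K2: 1.1
K4: 8.0
K5: 0.3
K6: 8.5
K7: 1.0
K8: 1.0
d1: 0.4
d2D_p7: 0.5
d2D_p9: 0.5
d2L_p7: 0.29
d2L_p9: 0.29
d3D: 0.3
d3L: 0.32
d4D: 1.21
d4L: 0.38
k1D: 0.1
k1L: 0.36
k2_p7: 0.5
k2_p9: 0.5
k3: 0.36
k4: 0.6
p1: 0.76
p1L: 0.42
p2_p7: 1.01
p2_p9: 1.01
p3: 0.64
p4: 1.01
pP: 0.3
v1: 4.58
v1L: 3.0
v2A_p7: 0.635
v2A_p9: 0.635
v2L_p7: 2.5
v2L_p9: 2.5
v3: 31.0
v4: 2.5
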