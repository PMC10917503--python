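# Base compact clock model: rate constants (1/h or conc/h) and Hill half-max
# constants (model concentration units).  Hill exponent is 2 throughout.
#
# Roles:
#   v1/v1L     CL transcription (basal / acute light induction via P)
#   k1L,k1D    CL mRNA decay (light / dark); p1,p1L translation; d1 protein decay
#   v2A/v2L    P97 transcription (basal / acute light via P); k2,p2,d2D,d2L likewise
#   v3         P51 maximal transcription (CL-activated, EL-repressed)
#   v4         EL transcription (CL-repressed, self-repressed)
#   K1  P97p -| CLm      K2  P51p -| CLm
#   K4  P51p -| P9/P7m   K5  ELp  -| P9/P7m     (K11 = mean(K4, K5), derived)
#   K6  CLp  -> P51m (activation)   K7  ELp -| P51m
#   K8  CLp  -| ELm      K10 ELp -| ELm (autorepression)
#   pP         dark accumulation rate of P (light degradation rate fixed at 1)
variant: BASE
v1: 4.58
v1L: 3.0
k1L: 0.36
k1D: 0.10
p1: 0.76
p1L: 0.42
d1: 0.40
v2A: 1.27
v2L: 5.0
k2: 0.5
p2: 1.01
d2D: 0.50
d2L: 0.29
v3: 31.0
k3: 0.36
p3: 0.64
d3D: 0.30
d3L: 0.32
v4: 2.5
k4: 0.6
p4: 1.01
d4D: 1.21
d4L: 0.38
K1: 0.30
K2: 1.10
K4: 8.0
K5: 0.30
K6: 8.5
K7: 1.0
K8: 1.0
K10: 1.9
pP: 0.3
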