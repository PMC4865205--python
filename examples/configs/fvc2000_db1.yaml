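# Trained sensor parameters for FVC2000 DB1 (C, gamma, t); the remaining
# parameters are the fixed operating point (n=20, L=16, s=9, b=6,
# omega_L=0.3, omega_H=1.0, pad=15).
C: 0.06
gamma: 4
t: 5
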