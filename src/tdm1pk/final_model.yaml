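theta1: -0.3915622029391729
theta2: 1.1400740784757042
theta3: 0.42787870294506447
theta4: -0.4155154439616658
theta5: 0.596
theta6: 0.49
theta7: 0.035
theta8: -0.423
theta9: 0.052
theta10: -0.002
theta11: 0.071
omega_cl: 0.1911
omega_vc: 0.1166
omega_q: 1.808
omega_vp: 0.745
omega_cl_vc: 0.011
sigma_prop: 0.3156
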