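# Per-pH water (Pf) and solute (Ps) permeability coefficients of beetroot
# tonoplast obtained with the WS model, with per-record Pf/Ps ratio means
# and steady relative volumes. Units: Pf, Ps in cm/s; ratio and vf_v0
# dimensionless; SEMs on the same scale; n = number of vacuoles.
ph,pf_mean,pf_sem,ps_mean,ps_sem,ratio_mean,ratio_sem,vf_v0_mean,vf_v0_sem,n
6.6,0.0004,0.0003,0.0020,0.0016,1.12,0.44,1.002,0.002,6
6.8,0.007,0.003,0.0014,0.0009,8.19,1.22,1.023,0.004,10
7.0,0.027,0.005,0.0021,0.0004,14.04,0.91,1.040,0.004,14
7.6,0.009,0.002,0.00035,0.00007,27.68,2.62,1.073,0.008,14
8.6,0.021,0.005,0.00077,0.00010,33.85,5.69,1.085,0.012,6
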