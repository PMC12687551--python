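name,K,eps_ref,eps1
PCL_a,6468.8,-0.51,0.03
PCL_po,2101.2,-0.33,0.03
MCL_a,2388.1,0.07,0.03
MCL_c,3355.4,0.06,0.03
MCL_po,3595.5,0.06,0.03
opMCL,2700.0,-0.01,0.03
dMCL_a,3000.0,-0.09,0.03
dMCL_po,4000.0,0.02,0.03
LCL_a,1209.1,0.12,0.03
LCL_s,3274.7,0.07,0.03
LCL_po,3273.9,0.11,0.03
OPL_pr,917.3,0.10,0.03
OPL_d,871.0,0.11,0.03
APL,2071.9,0.07,0.03
PCAP_l,5264.3,0.06,0.03
PCAP_m,5069.7,0.06,0.03
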