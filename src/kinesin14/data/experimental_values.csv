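construct,quantity,value,uncertainty,units,source
KlpA,gliding_velocity,309,35,nm/s,gliding_assay
KlpA-dtail,gliding_velocity,287,10,nm/s,gliding_assay
GiKIN14a-dtail,atpase_rate,10.0,0.7,1/s,bulk_atpase_assay
KlpA-3xGS,kappa_delta,0.78,0,pN,single_mt_velocity_fit
KlpA,kappa_delta,2.92,0,pN,single_mt_velocity_fit
KlpA-3xGS,kappa,0.39,0,pN/nm,single_mt_velocity_fit
KlpA,kappa,1.46,0,pN/nm,single_mt_velocity_fit
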