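name,mw_g_per_mol,dissociation_degree
glucose,180,1.0
sucrose,342,1.0
maltodextrin,800,1.0
ethanol,46.5,1.0
xylitol,152,1.0
nacl,58.4,2.0
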