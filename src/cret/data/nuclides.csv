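name,half_life_h,atomic_number,mode,fraction,energy_mev
F-18,1.83,9,beta_plus,0.97,0.635
Cu-64,12.7,29,beta_plus,0.19,0.655
Cu-64,12.7,29,beta_minus,0.39,0.578
Tc-99m,6.0,43,gamma,0.89,0.140
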