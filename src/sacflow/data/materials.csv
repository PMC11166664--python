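name,cp,k,mu,rho
blood,3746,0.52,0.003,1063
gold,129,310,0.00464,19300
silver,2354,429,0.005,10500
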