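# Reported line-graph extremes of velocity (m/s) and pressure (Pa) at four
# output times in the 3D rupture simulation.  Interpretation caveats: the
# "minimum velocity" cannot be a domain minimum (no-slip walls force zero),
# so it is read as a minimum over the reporting line; the flow rate, particle
# loadings and sac dimensions behind these numbers are not stated, so this
# table is a comparison surface (signed deviations), not an equality target.
t,v_max,v_min,p_max,p_min
0.4,0.082,0.063,13120,13000
0.8,0.085,0.080,13075,13000
1.2,0.087,0.083,13060,12990
2.4,0.094,0.082,13040,13000
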