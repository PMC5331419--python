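complex_id,dE_ele,dE_vdw,dG_p,dG_np,dE_MM,dG_sol,dE_bind,minus_TdS,dG_bind
Compound 4,-29.58,-58.93,44.95,-6.74,-88.50,38.22,-50.28,27.59,-22.69
CID_70128824,-3.32,-70.56,24.14,-7.25,-73.88,16.89,-56.99,25.13,-31.86
CID_70127147,-16.79,-71.34,33.50,-7.80,-88.13,25.69,-62.44,29.38,-33.06
CID_70126881,-10.01,-69.32,25.14,-8.85,-79.33,16.29,-63.05,21.43,-41.62
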