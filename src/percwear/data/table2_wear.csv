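tool_id,tool_type,grain_size,macro_wear,depressions,pitting,crushing,flake_detachment,residue,n_discrete_use_wear,n_active_planes
CGG23,hammerstone,medium,yes,yes,yes,no,yes,yes,3,2
CQQ34-18,hammerstone,coarse,yes,yes,yes,yes,no,no,1,2
CTD1,hammerstone,coarse,yes,yes,yes,yes,no,yes,6,2
M Granite Hammer,hammerstone,very coarse,yes,yes,yes,yes,no,no,1,2
PPGd,hammerstone,medium,yes,no,no,no,yes,yes,1,2
PGQ18,hammerstone,coarse,yes,yes,yes,yes,no,yes,1,1
PPQ1003,hammerstone,coarse,yes,yes,yes,yes,no,no,2,2
PWS5,hammerstone,medium,yes,no,no,no,yes,yes,2,2
PWS7,hammerstone,medium,yes,yes,no,yes,yes,yes,0,2
PrGG1017,hammerstone,very coarse,yes,yes,yes,yes,no,no,2,2
PrPrQ_3015,hammerstone,fine,no,no,no,no,no,no,0,indeterminate
PGG3005-Ex,anvil,very coarse,yes,yes,yes,yes,no,no,1,1
PGQ18-A,anvil,very coarse,yes,yes,yes,yes,no,no,1,1
PGQ18-B,anvil,very coarse,yes,yes,yes,yes,no,no,13,1
PGU3012,anvil,very coarse,yes,yes,yes,yes,no,no,10,1
PGU3013,anvil,very coarse,yes,yes,yes,yes,no,no,43,1
PRGU3014,anvil,very coarse,yes,yes,yes,yes,no,no,9,1
SGdGd-A,anvil,medium,yes,yes,yes,no,no,no,5,1
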