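segment,right,left,balanced
rca_proximal,1,0,0.5
rca_mid,1,0,0.5
rca_distal,1,0,0.5
pda,1,na,0.5
left_main,5,6,5.5
lad_proximal,3.5,3.5,3.5
lad_mid,2.5,2.5,2.5
lad_distal,1,1,1
first_diagonal,1,1,1
second_diagonal,0.5,0.5,0.5
lcx_proximal,1.5,2.5,2
first_obtuse_marginal,1,1,1
lcx_distal,0.5,1.5,1
second_obtuse_marginal,1,1,1
pda_from_lca,na,1,na
pl_branch_from_lca,na,0.5,0.5
pl_branch_from_rca,0.5,na,na
intermediate_branch,1,1,1
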