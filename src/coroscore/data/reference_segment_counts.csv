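block,row,control,low,moderate,high
segment,rca_proximal,18,22,32,34
segment,rca_mid,17,14,24,26
segment,rca_distal,13,8,17,14
segment,pda,3,3,9,7
segment,left_main,12,8,18,24
segment,lad_proximal,37,32,38,48
segment,lad_mid,25,15,22,27
segment,lad_distal,1,0,2,2
segment,first_diagonal,7,8,18,21
segment,second_diagonal,1,0,6,3
segment,lcx_proximal,16,15,27,26
segment,first_obtuse_marginal,5,3,9,13
segment,lcx_distal,3,2,5,6
segment,second_obtuse_marginal,0,0,2,2
segment,pda_from_lca,0,0,0,0
segment,pl_branch_from_lca,0,2,5,5
segment,pl_branch_from_rca,1,0,1,4
segment,intermediate_branch,0,0,0,0
severity,obstructive,21,29,107,124
severity,non_obstructive,138,103,128,138
composition,non_calcified_or_mixed,139,128,214,234
composition,calcified,20,4,21,28
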