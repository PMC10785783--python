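compound_id,method,role,model_type,parent_id,log_K1,se_K1,log_K2,se_K2
malonic_acid,nmr,parent,,,5.22,0.01,2.700,0.008
succinic_acid,nmr,parent,,,5.18,0.02,3.98,0.03
maleic_acid,nmr,parent,,,5.777,0.004,1.79,0.02
fumaric_acid,nmr,parent,,,4.08,0.03,2.93,0.03
catechol,nmr,parent,,,13.26,0.01,9.396,0.005
resorcinol,nmr,parent,,,11.09,0.01,9.28,0.01
chlororesorcinol_2,nmr,parent,,,10.150,0.007,7.950,0.006
hydroquinone,nmr,parent,,,11.83,0.03,10.06,0.02
propanedithiol_13,nmr,parent,,,10.98,0.03,9.71,0.03
butanedithiol_14,nmr,parent,,,11.0,0.2,10.0,0.1
benzenedithiol_14,nmr,parent,,,7.42,0.02,5.75,0.02
monomethyl_malonate,nmr,model,O_methyl,malonic_acid,3.197,0.005,,
malonamic_acid,nmr,model,amide,malonic_acid,3.530,0.005,,
monomethyl_succinate,nmr,model,O_methyl,succinic_acid,4.38,0.01,,
succinamic_acid,nmr,model,amide,succinic_acid,4.45,0.01,,
monomethyl_maleate,nmr,model,O_methyl,maleic_acid,2.790,0.002,,
maleamic_acid,nmr,model,amide,maleic_acid,3.556,0.005,,
monomethyl_fumarate,nmr,model,O_methyl,fumaric_acid,3.178,0.009,,
guaiacol,nmr,model,O_methyl,catechol,9.913,0.005,,
methoxyphenol_3,nmr,model,O_methyl,resorcinol,9.599,0.009,,
chloro_2_methoxyphenol_3,nmr,model,O_methyl,chlororesorcinol_2,8.15,0.02,,
methoxyphenol_4,nmr,model,O_methyl,hydroquinone,10.200,0.002,,
smethyl_propanedithiol_13,nmr,model,S_methyl,propanedithiol_13,10.53,0.03,,
smethyl_butanedithiol_14,nmr,model,S_methyl,butanedithiol_14,10.41,0.04,,
smethyl_benzenedithiol_14,nmr,model,S_methyl,benzenedithiol_14,6.23,0.01,,
oxalic_acid,potentiometric,parent,,,4.27,0.01,1.28,0.01
malonic_acid,potentiometric,parent,,,5.33,0.02,2.82,0.02
succinic_acid,potentiometric,parent,,,5.28,0.02,4.07,0.01
maleic_acid,potentiometric,parent,,,5.87,0.01,1.93,0.03
fumaric_acid,potentiometric,parent,,,4.18,0.02,2.95,0.05
resorcinol,potentiometric,parent,,,11.11,0.02,9.27,0.02
chlororesorcinol_2,potentiometric,parent,,,10.13,0.02,7.95,0.01
hydroquinone,potentiometric,parent,,,11.52,0.04,9.90,0.02
monomethyl_oxalate,potentiometric,model,O_methyl,oxalic_acid,1.64,0.04,,
oxamic_acid,potentiometric,model,amide,oxalic_acid,2.05,0.03,,
monomethyl_malonate,potentiometric,model,O_methyl,malonic_acid,3.29,0.01,,
malonamic_acid,potentiometric,model,amide,malonic_acid,3.58,0.03,,
monomethyl_succinate,potentiometric,model,O_methyl,succinic_acid,4.43,0.02,,
succinamic_acid,potentiometric,model,amide,succinic_acid,4.47,0.01,,
monomethyl_maleate,potentiometric,model,O_methyl,maleic_acid,2.72,0.04,,
maleamic_acid,potentiometric,model,amide,maleic_acid,3.60,0.02,,
monomethyl_fumarate,potentiometric,model,O_methyl,fumaric_acid,3.23,0.04,,
methoxyphenol_3,potentiometric,model,O_methyl,resorcinol,9.51,0.03,,
chloro_2_methoxyphenol_3,potentiometric,model,O_methyl,chlororesorcinol_2,8.13,0.03,,
methoxyphenol_4,potentiometric,model,O_methyl,hydroquinone,10.12,0.04,,
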