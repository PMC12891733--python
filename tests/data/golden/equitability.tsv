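subject_id	condition	n_clonotypes	total_reads	equitability
S01	baseline	148	20000	0.232355533342
S01	vehicle_only	162	20000	0.238944619713
S01	control_peptide	164	20000	0.239622330182
S01	G12V	162	20000	0.220478370587
S01	G12A	165	20000	0.225886213041
S01	G12R	161	20000	0.223655830699
S01	G12C	163	20000	0.225035218682
S01	G12D	164	20000	0.229067703099
S01	G13D	157	20000	0.222256812698
S01	tumor_tissue	142	20000	0.209820117022
S02	baseline	144	20000	0.236323020936
S02	vehicle_only	164	20000	0.246617368762
S02	control_peptide	165	20000	0.250665800767
S02	G12V	166	20000	0.235740520837
S02	G12A	164	20000	0.225173470737
S02	G12R	162	20000	0.230820227489
S02	G12C	161	20000	0.234255388204
S02	G12D	163	20000	0.236032151483
S02	G13D	167	20000	0.237127890589
S02	tumor_tissue	147	20000	0.222482416313
S03	baseline	144	20000	0.241419232827
S03	vehicle_only	168	20000	0.254491745398
S03	control_peptide	169	20000	0.254648585228
S03	G12V	167	20000	0.235822792782
S03	G12A	169	20000	0.241930347062
S03	G12R	165	20000	0.240939982797
S03	G12C	164	20000	0.23355032525
S03	G12D	162	20000	0.238792778151
S03	G13D	166	20000	0.241448731412
S03	tumor_tissue	146	20000	0.22228342391
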