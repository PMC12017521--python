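subject	sex	mass_kg	truncated_foot_length_mm	static_nnht	max_arch_displacement_nnht	k_hc_kn_per_mm	k_pc_kn_per_mm	k_po_kn_per_mm
1	F	52	188.7	0.164	0.106	0.073	0.0081	0.028
2	F	58	184.1	0.161	0.090	0.124	0.0074	0.038
3	F	61	179.6	0.156	0.095	0.127	0.0067	0.029
4	M	56	204.1	0.175	0.072	0.121	0.0065	0.038
5	M	57	194.3	0.165	0.081	0.079	0.0071	0.059
6	M	72	197.9	0.162	0.092	0.130	0.0061	0.041
7	M	69	177.0	0.169	0.072	0.166	0.0066	0.053
8	M	84	206.3	0.155	0.071	0.149	0.0072	0.051
9	M	75	212.6	0.158	0.072	0.181	0.0066	0.043
10	M	82	214.8	0.154	0.071	0.133	0.0065	0.035
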