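superclass	pct
Lipids and lipid-like molecules	30.2
Organoheterocyclic compounds	19.5
Organic acids and derivatives	15.1
Benzenoids	9.9
Phenylpropanoids and polyketides	7.6
Organic oxygen compounds	6.5
Organic nitrogen compounds	4.0
Alkaloids and derivatives	1.7
Lignans, neolignans and related compounds	0.6
Hydrocarbon derivatives	0.4
Organic 1,3-dipolar compounds	0.2
Hydrocarbons	0.2
Organosulfur compounds	0.2
None	3.8
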