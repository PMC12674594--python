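label,formula,klass,pa_exp_kcal
1,HCOO-,carboxylate,345.2
2,CH3COO-,carboxylate,348.5
3,CH3CH2COO-,carboxylate,347.5
4,CH3(CH2)2COO-,carboxylate,346.6
5,CH3(CH2)3COO-,carboxylate,346.1
6,CH3COCOO-,carboxylate,333.5
7,CH2FCOO-,carboxylate,339.2
8,CHF2COO-,carboxylate,330.2
9,CF3COO-,carboxylate,322.6
10,ClCH2COO-,carboxylate,336.2
11,Cl(CH2)2COO-,carboxylate,340.8
12,NH3,amine,204.1
13,CH3NH2,amine,214.9
14,CH3CH2NH2,amine,217.9
15,CH3(CH2)2NH2,amine,219.3
16,(CH3)2NH,amine,222.1
17,(CH3)3N,amine,226.9
18,C6H5NH2,aromatic,211.0
19,C6H5O-,aromatic,351.4
20,C6H5COO-,aromatic,340.1
21,NO2-,inorganic,340.1
22,CN-,inorganic,353.1
23,HS-,inorganic,353.1
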