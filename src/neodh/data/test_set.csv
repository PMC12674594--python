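label,formula,klass,pa_exp_kcal
1',CH3CH2O-,alcohol,378.2
2',(CH3)2CHO-,alcohol,375.7
3',o-C6H4ClO-,phenol,343.4
4',m-C6H4ClO-,phenol,342.1
5',p-CH3C6H4O-,phenol,350.7
6',p-C6H4NO3-,phenol,327.8
7',(CH3)2CHCH2NH2,amine,220.8
8',C3H4N2,N-heterocycle,225.3
9',(CH2)4NH,N-heterocycle,226.6
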