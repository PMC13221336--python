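id,name,cas,smiles
1,[(E)-2-nitroethenyl]benzene,102-96-5,C1=CC=C(C=C1)C=C[N+](=O)[O-]
2,2-nitroethylbenzene,6125-24-2,C1=CC=C(C=C1)CC[N+](=O)[O-]
3,1-nitro-2-[(E)-2-nitroethenyl]benzene,3156-39-6,C1=CC=C(C(=C1)C=C[N+](=O)[O-])[N+](=O)[O-]
4,styrene,100-42-5,C=CC1=CC=CC=C1
5,2-phenylethanamine,64-04-0,C1=CC=C(C=C1)CCN
6,nitrobenzene,98-95-3,C1=CC=C(C=C1)[N+](=O)[O-]
7,(E)-3-phenylprop-2-enoic acid,140-10-3,C1=CC=C(C=C1)C=CC(=O)O
8,"5-[(E)-2-nitroethenyl]-1,3-benzodioxole",22568-48-5,C1OC2=C(O1)C=C(C=C2)C=C[N+](=O)[O-]
9,2-methoxy-5-[(E)-2-nitroethenyl]phenol,39816-35-8,COC1=C(C=C(C=C1)C=C[N+](=O)[O-])O
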