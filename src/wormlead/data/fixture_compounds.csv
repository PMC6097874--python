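id,name,smiles,logs,has_dione_ring,has_lactam_ring,note
cpd1,ethosuximide,CCC1(C)CC(=O)NC1=O,-0.93,1,1,
cpd2,succinimide,O=C1CCC(=O)N1,-0.09,1,1,
cpd3,phenytoin,O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1,-2.85,0,0,hydantoin core
cpd4,trimethadione,CN1C(=O)OC(C)(C)C1=O,-0.96,0,0,oxazolidinedione core
cpd5,thalidomide,O=C1CCC(N2C(=O)c3ccccc3C2=O)C(=O)N1,-1.66,0,0,dione ring fused to benzene (aromatic carbons)
cpd6,phthalimide,O=C1NC(=O)c2ccccc21,-1.52,0,0,dione ring fused to benzene (aromatic carbons)
cpd7,2-pyrrolidinone,O=C1CCCN1,-0.30,0,1,ambiguous source name '2-pyrrolidine'; transcribed as 2-pyrrolidinone
cpd8,N-phenylphthalimide,O=C1N(c2ccccc2)C(=O)c2ccccc21,-3.25,0,0,dione ring fused to benzene (aromatic carbons)
cpd9,alpha-methyl-alpha-phenylsuccinimide,CC1(c2ccccc2)CC(=O)NC1=O,-1.89,1,1,MPS
cpd10,1-benzylpyrrolidine-2-5-dione,O=C1CCC(=O)N1Cc1ccccc1,-2.04,1,1,
cpd11,alpha-methyl-alpha-propylsuccinimide,CCCC1(C)CC(=O)NC1=O,-1.20,1,1,
cpd12,3-3-diethylpyrrolidine-2-5-dione,CCC1(CC)CC(=O)NC1=O,-1.20,1,1,
cpd13,4-ethyl-4-methylpyrrolidin-2-one,CCC1(C)CNC(=O)C1,-1.14,0,1,
cpd14,alpha-alpha-dimethyl-beta-methylsuccinimide,CC1C(=O)NC(=O)C1(C)C,-0.91,1,1,
cpd15,3-3-diethylpyrrolidin-2-one,CCC1(CC)CCNC1=O,-1.41,0,1,
cpd16,methsuximide,CC1(c2ccccc2)CC(=O)N(C)C1=O,-2.17,1,1,
cpd17,phensuximide,CN1C(=O)CC(c2ccccc2)C1=O,-1.99,1,1,
cpd18,N-methyl-ethosuximide,CCC1(C)CC(=O)N(C)C1=O,-1.23,1,1,synthesised in-house
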