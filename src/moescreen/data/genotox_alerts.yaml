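# Structural alerts for genotoxic carcinogenicity / bacterial mutagenicity.
# A documented subset of the classic alert catalogues, expressed as named
# SMARTS patterns. A chemical is flagged when any pattern matches.
# version is echoed into run reports so alert-table changes are traceable.
version: "2024.1"
alerts:
  - name: aromatic nitro
    smarts: "c[$([NX3](=[OX1])=[OX1]),$([NX3+](=[OX1])[O-])]"
  - name: aromatic amine
    # primary/secondary exocyclic amine on an aromatic carbon; amides excluded
    smarts: "[NX3;H2,H1;!$([NX3][CX3]=[OX1,SX1,NX2]);!$([NX3][#7,#8,#16])]c"
  - name: N-nitroso
    smarts: "[NX3][NX2]=[OX1]"
  - name: epoxide
    smarts: "[CX4]1[OX2][CX4]1"
  - name: aziridine
    smarts: "[CX4]1[NX3][CX4]1"
  - name: aromatic azo
    smarts: "c[NX2]=[NX2]c"
  - name: hydrazine
    # N-N single bond, neither nitrogen acylated or part of an azo/nitroso group
    smarts: "[NX3;!$([NX3][CX3]=[OX1])][NX3;!$([NX3][CX3]=[OX1])]"
  - name: activated alkyl halide
    # allylic, benzylic or alpha-carbonyl halide on sp3 carbon
    smarts: "[Cl,Br,I][CX4;$([CX4][CX3]=[CX3]),$([CX4]c),$([CX4][CX3]=[OX1])]"
  - name: alpha,beta-unsaturated carbonyl
    smarts: "[CX3]=[CX3][CX3]=[OX1]"
  - name: aromatic N-oxide
    smarts: "[$([nX3+][O-]),$([nX3]=[OX1])]"
  - name: alkyl sulfonate or phosphonate ester
    smarts: "[$([#6][SX4](=[OX1])(=[OX1])[OX2][CX4]),$([#6][PX4](=[OX1])([OX2][CX4])[OX2][CX4])]"
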