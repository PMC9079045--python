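# Bundled substructure pattern set for count/presence fingerprints.
# Format: <feature_name> <SMARTS>, '#' starts a comment.
# Covers the functional-group classes that dominate the Gini ranking of the
# substructure-count model (phenol, amine, aromatic, carboxylic acid
# derivative, ether, tautomerizable motifs, rotatable bonds), plus common
# drug-like groups. Native graph descriptors with no SMARTS expression are
# registered under "@builtin:" names.
Phenol [OX2H]c
Catechol [OX2H]c1ccccc1[OX2H]
Hydroxyl [OX2H]
AliphaticAlcohol [OX2H][CX4]
PrimaryAmine [NX3;H2;!$(NC=O);!$(N=*)]
SecondaryAmine [NX3;H1;!$(NC=O);!$(N=*);!$([nH])]
TertiaryAliphaticAmine [NX3;H0;!$(NC=O);!$(N=*);!$(n)]([CX4])([CX4])[CX4]
Amine [NX3;!$(NC=O);!$(N=*);!$(n)]
AromaticNitrogen n
HeteroNNonbasic [nX2,$([nX3+])]
CarboxylicAcid [CX3](=O)[OX2H1]
CarboxylicAcidDerivative [CX3](=[OX1])[#7,#8X2H0,#16]
Ester [CX3](=O)[OX2H0][#6]
Amide [CX3](=O)[NX3]
Ketone [#6][CX3](=O)[#6]
Aldehyde [CX3H1](=O)[#6]
Ether [OD2]([#6])[#6]
AlkylArylEther [OX2](c)[CX4]
DiarylEther c[OX2]c
Thiol [SX2H]
Thioether [SX2]([#6])[#6]
Sulfonamide [SX4](=O)(=O)[NX3]
Sulfone [SX4](=O)(=O)([#6])[#6]
Halogen [F,Cl,Br,I]
Fluorine F
Chlorine Cl
Nitro [$([NX3](=O)=O),$([NX3+](=O)[O-])]
Nitrile [CX2]#[NX1]
BenzeneRing c1ccccc1
AromaticAtom a
CONSBond [#6]~[#7,#8,#16]
ConjugatedDoubleBond C=CC=C
VinylogousEster [OX2][CX3]=[CX3]
Imine [CX3]=[NX2]
Urea [NX3][CX3](=O)[NX3]
Carbamate [NX3][CX3](=O)[OX2]
MethylGroup [CX4H3]
SecondaryCarbon [CX4H2]([#6])[#6]
TertiaryCarbon [CX4H1]([#6])([#6])[#6]
QuaternaryCarbon [CX4]([#6])([#6])([#6])[#6]
Tautomerizable13 [CX4;!H0][CX3]=[OX1]
Tautomerizable15 [CX4;!H0][CX3]=[CX3][CX3]=[OX1]
RotatableBondSmarts [!$(*#*)&!D1]-!@[!$(*#*)&!D1]
ChiralCenterSpecified @builtin:chiral_centers
RotatableBondCount @builtin:rotatable_bonds
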