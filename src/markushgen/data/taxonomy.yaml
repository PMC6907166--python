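# Default common-group taxonomy: 28 named groups with SMARTS definitions and
# patent text terms. "defined" groups denote one fixed structure (hydroxy,
# cyano, halo...); "general" groups denote structure classes (alkyl, aryl,
# heteroaryl...). This set is a reconstruction chosen to name the package's
# reference R-group tables; it is user-editable, so a different curated set
# can be substituted wholesale.
#
# Fields per group:
#   name    unique identifier, also the default category label
#   smarts  detection pattern
#   kind    defined | general
#   term    text term used in claims
#   prefix  combining form used when the group is distal in a composite term
#   exact   fragment SMILES -> term, for fragments that ARE the group
#   sizes   carbon count -> -yl name, for chain-length-specific naming
#   compose false to exclude umbrella groups from composite term building
groups:
  - name: hydrogen
    smarts: "[#1]"
    kind: defined
    term: hydrogen
    exact:
      "*[H]": hydrogen
  - name: hydroxy
    smarts: "[OX2H1]"
    kind: defined
    term: hydroxy
    exact:
      "*O": hydroxy
  - name: cyano
    smarts: "C#N"
    kind: defined
    term: cyano
    exact:
      "*C#N": cyano
  - name: nitro
    smarts: "[$([NX3](=O)=O),$([NX3+](=O)[O-])]"
    kind: defined
    term: nitro
    exact:
      "*[N+](=O)[O-]": nitro
  - name: amino
    smarts: "[NX3;H2,H1;!$(N=O);!$(NC=O);!$(NS(=O)=O)]"
    kind: defined
    term: amino
    exact:
      "*N": amino
  - name: carboxy
    smarts: "C(=O)[OX2H1]"
    kind: defined
    term: carboxy
    exact:
      "*C(=O)O": carboxy
  - name: carbamoyl
    smarts: "C(=O)[NX3H2]"
    kind: defined
    term: carbamoyl
    exact:
      "*C(N)=O": carbamoyl
  - name: sulfamoyl
    smarts: "S(=O)(=O)[NX3H2]"
    kind: defined
    term: sulfamoyl
    exact:
      "*S(=O)(=O)N": sulfamoyl
  - name: sulfonyl
    smarts: "[$([SX4](=O)(=O))]"
    kind: defined
    term: sulfonyl
  - name: thio
    smarts: "[SX2]"
    kind: defined
    term: thio
    exact:
      "*S": mercapto
  - name: oxo
    smarts: "[CX3]=[OX1]"
    kind: defined
    term: oxo
  - name: halo
    smarts: "[F,Cl,Br,I]"
    kind: defined
    term: halo
    exact:
      "*F": fluoro
      "*Cl": chloro
      "*Br": bromo
      "*I": iodo
  - name: trifluoromethyl
    smarts: "C(F)(F)F"
    kind: defined
    term: trifluoromethyl
    exact:
      "*C(F)(F)F": trifluoromethyl
  - name: alkoxy
    smarts: "[OX2;!$([OX2H])][CX4]"
    kind: general
    term: alkoxy
    prefix: alkoxy
    exact:
      "*OC": methoxy
      "*OCC": ethoxy
      "*OCCC": propoxy
      "*OC(C)C": isopropoxy
  - name: acyl
    smarts: "[CX3](=O)[#6]"
    kind: general
    term: acyl
    exact:
      "*C(C)=O": acetyl
  - name: ester
    smarts: "[CX3](=O)[OX2][#6]"
    kind: general
    term: alkoxycarbonyl
    compose: false
  - name: amido
    smarts: "[CX3](=O)[NX3]"
    kind: general
    term: amido
    compose: false
  - name: alkyl
    smarts: "[CX4;!R]"
    kind: general
    term: alkyl
    sizes:
      1: methyl
      2: ethyl
      3: propyl
      4: butyl
      5: pentyl
      6: hexyl
    exact:
      "*C": methyl
      "*CC": ethyl
      "*CCC": propyl
      "*C(C)C": isopropyl
      "*CCCC": butyl
      "*C(C)(C)C": tert-butyl
  - name: alkenyl
    smarts: "[CX3]=[CX3]"
    kind: general
    term: alkenyl
    exact:
      "*C=C": vinyl
  - name: alkynyl
    smarts: "C#C"
    kind: general
    term: alkynyl
    exact:
      "*C#C": ethynyl
  - name: cycloalkyl
    smarts: "[CX4;R]"
    kind: general
    term: cycloalkyl
    exact:
      "*C1CC1": cyclopropyl
      "*C1CCC1": cyclobutyl
      "*C1CCCC1": cyclopentyl
      "*C1CCCCC1": cyclohexyl
  - name: aryl
    smarts: "c1ccccc1"
    kind: general
    term: aryl
    prefix: phenyl
    exact:
      "*c1ccccc1": phenyl
  - name: heteroaryl
    smarts: "[a;!#6]"
    kind: general
    term: heteroaryl
    prefix: heteroaryl
  - name: heterocyclyl
    smarts: "[A;R;!#6;!#1]"
    kind: general
    term: heterocyclyl
    prefix: heterocyclyl
  - name: arylalkyl
    smarts: "[CX4;!R][c]"
    kind: general
    term: arylalkyl
    compose: false
  - name: aminoalkyl
    smarts: "[NX3][CX4]"
    kind: general
    term: aminoalkyl
    compose: false
  - name: ether
    smarts: "[#6][OX2][#6]"
    kind: general
    term: ether
    compose: false
  - name: hydroxyalkyl
    smarts: "[OX2H1][CX4]"
    kind: general
    term: hydroxyalkyl
    compose: false
    exact:
      "*CO": hydroxymethyl
      "*CCO": hydroxyethyl
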