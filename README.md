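# markushgen

Markush structures and patent-claim drafting from analog series.

The first claim of a pharmaceutical composition patent is usually written
around a *Markush structure*: a fixed core bearing variable positions
R1..Rn, each allowed to take a set of substituents, so that one claim covers
a whole family of compounds. Deriving that structure from a pile of analog
compounds — and deciding which extra substituents are worth claiming — is
manual attorney work. `markushgen` automates the structural part for
medicinal chemists and patent professionals:

- **Core extraction.** The invariant core of a series is its maximum common
  connected substructure (MCS), computed with patent-sensible matching
  rules: atoms by element, bonds by order (aromatic ≠ single), ring atoms
  only against ring atoms, and no partial rings. Core atoms where at least
  one member extends beyond the core become the attachment positions
  R1..Rn.
- **R-group decomposition.** Each compound is cut around the core; every
  connected piece outside it becomes a substituent fragment written with a
  `*` attachment atom (`*C`, `*OC`, `*[H]` for unsubstituted positions).
  Identity everywhere is the stereo-stripped canonical SMILES, so optical
  isomers collapse.
- **Naming.** A configurable taxonomy of 28 common groups (SMARTS +
  text term) names each fragment. Composite fragments are named from the
  group most distant from the attachment point inward (`*CCc1ccccc1` →
  "phenylethyl"); sets collapsing under one family emit a class term
  ({`*F`,`*Cl`} → "halo").
- **Library building and expansion.** From (compounds, scaffolds) pairs the
  package harvests fragments, deduplicates, applies the deuterium /
  phosphorus / long-aliphatic-chain (>6 C) filters with audited ledger
  arithmetic, and records *substituent contexts* — which substituents
  co-occur on which bare ring system or carbon chain. A claim position
  sitting on a matching main structure can then be broadened with the
  context's remaining substituents, each addition carrying a provenance
  note.
- **Output.** Numbered claim clauses ("R1 is selected from the group
  consisting of ...") rendered to `.docx`, Markdown and JSON, with an SVG
  scheme of the core labeled R1..Rn.

## Worked example

Draft claims from the shipped 4-compound benzhydryl ether-amine series
(para-halo × N-alkyl variation):

```
$ markushgen draft tests/data/etheramine_series.sdf --format json --format md --out claims
INFO:markushgen:series of 4 compounds: core CN(CCOC(c1ccccc1)c1cc[cH:2]cc1)[CH3:1], 2 positions, 4 explicit + 0 expanded R groups
wrote claims.json, claims.md
```

The mapped core SMILES marks the two variable positions. `claims.md` holds
the claim text exactly as rendered:

```
1. A compound of formula (I):
   [Formula (I)]
   wherein
   R1 is selected from the group consisting of hydrogen and methyl;
   R2 is selected from the group consisting of halo,
   or a pharmaceutically acceptable salt thereof.
```

R2 collects `*Br` and `*Cl` (the para-halogens of the series), which the
taxonomy collapses to the single family term "halo". R1 captures the
N-methyl vs N-ethyl variation: the common N-methyl folds into the core and
the remaining carbon is hydrogen-or-methyl.

Building a library from the 20-compound fixture and inspecting it:

```
$ markushgen build-library tests/data/library_compounds.sdf tests/data/library_scaffolds.sdf --out lib.json
harvested 20 fragments; removed 11 duplicates; dropped 0 deuterium, 0 phosphorus, 1 long-chain; kept 8 R groups
$ markushgen stats lib.json --top 3
key  count  percent
 *C      4     23.5
...
top-3 share: 58.8%
```

The ledger line is the audited accounting identity: kept = harvested −
duplicates − drops. Percentages are occurrence-weighted over entries seen
at least twice.

## Scope

The package works on MDL SD files (V2000) and assumes the input series
genuinely shares a core. It does not attempt IUPAC nomenclature, legal
validity checking, prior-art search, nested R-group hierarchies, or
disconnected/fuzzy MCS. See `docs/methods.md` for the model, parameter and
design details.
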