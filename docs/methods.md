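# Methods

## Problem and model

A Markush claim is modeled as a pair (core, position specs): the core is a
connected molecular graph; each attachment position names one core atom and
carries a set of allowed substituent fragments plus the text terms used in
the claim language. A compound is *covered* when some choice of one allowed
fragment per position reassembles (stereochemistry ignored) into that
compound. The pipeline's central assumption is that an analog series is
generated exactly this way — fixed core, independent substituent choices —
which is the assumption patent claims themselves encode.

## Core finding

The core is the maximum common connected substructure of the series,
computed with RDKit's MCS search under these matching rules:

- atoms compare by element; formal charge and isotope are carried into the
  extracted core but do not constrain matching;
- bonds compare by order, with aromatic distinct from single;
- ring atoms and ring bonds may only match ring atoms and ring bonds;
- rings may not be matched partially (`completeRingsOnly`);
- atom count is maximized (not bond count), with a floor of
  `min_core_atoms = 3` below which the series is rejected as sharing no
  core, and a search timeout of 60 s.

Rationale: a claimed core with half a ring, or with an aromatic ring
matched onto an aliphatic one, is chemically meaningless in a patent. The
defaults live in `McsParams` and are part of the package contract; they are
verified against a brute-force connected-common-subgraph enumeration (an
independent oracle in the test suite, written on networkx) on molecule
pairs small enough to enumerate.

The MCS query is materialized into a concrete molecule by copying the
matched atoms and bonds out of the series member with the canonically
smallest SMILES, which makes core construction independent of input order.
Attachment positions are the core atoms where any member extends beyond the
core; they are labeled R1..Rn in canonical-atom-rank order of the core so
labeling is reproducible across runs and input permutations.

## Decomposition

Cutting a compound around the core severs every bond between a matched core
atom and the rest; each connected remainder becomes a fragment with one
`*` pseudo-atom per severed bond (the molecule is kekulized before cutting
so no fragment is left with orphan aromatic flags). Unsubstituted positions
receive `*[H]`.

Degenerate inputs are handled explicitly rather than rejected:

- **Symmetric cores** (benzene, etc.) admit several embeddings; the one
  minimizing the lexicographically sorted multiset of fragment canonical
  keys is chosen — determinism over chemistry, since the alternatives are
  automorphic images of each other.
- **Bridging fragments** bonded to two or more core atoms (e.g. the
  four-carbon remainder of naphthalene over a benzene core) are kept as
  divalent linkers under a combined position label ("R1/R2") with a
  warning; dropping them would break the reassembly invariant that core +
  fragments always rebuilds the input.
- **Gem-disubstitution** of a single core atom merges the two pieces into
  one multi-part fragment so a position always maps to one object.

Identity throughout is the stereo-stripped canonical SMILES: duplicates
"including optical isomers" must collapse, so stereocenters and double-bond
geometry are erased before canonicalization everywhere (decomposition,
dedup, coverage checking).

## Library construction

Scaffolds for library building are Murcko frameworks (ring systems plus
inter-ring linkers, with atoms double-bonded directly to those retained).
Each compound is cut around its largest matching scaffold (ties by
canonical key). The harvested fragment pool is deduplicated on fragment
keys and filtered in a fixed order — deuterium-containing, then
phosphorus-containing, then fragments whose longest aliphatic carbon chain
exceeds six atoms — first match wins, so ledger counts are disjoint and
`kept = harvested − duplicates − drops` holds identically. Chain length is
counted in atoms along the longest simple path over non-ring, non-aromatic
carbons; heteroatoms break the chain, so a cyclohexyl or methoxy fragment
scores 0 and the filter really only sees open-chain alkyl spans.

For every fragment the *substituent context* is recorded: the bare ring
system or maximal acyclic carbon chain of the scaffold carrying the
attachment (canonicalized with substituents removed), together with all
sibling substituents observed on that same main structure. Contexts are
merged across compounds by (main structure, kind).

The drug-set preparation filter keeps the heaviest connected component of
each record (salt stripping; equal-weight ties broken by canonical key),
then drops molecules with MW > 800 Da, MW < 100 Da, or fewer than 6 carbon
atoms, and deduplicates. The tiny-molecule criteria are applied as a union
(either one drops), reading the thresholds as independent cutoffs.

Occurrence statistics are restricted to entries seen at least twice and are
occurrence-weighted: an entry's percentage is its count over the total
count of all such duplicate entries. The alternative (group-weighted)
reading was rejected because only occurrence weighting makes the packaged
reference table's top-10 percentages an exact partition of its own top-10
share.

## Taxonomy and term generation

The default taxonomy ships 28 common groups, each a (name, SMARTS, kind,
term) record: "defined" groups denote one structure (hydroxy, cyano,
sulfamoyl, the halo family with per-halogen terms...), "general" groups
denote classes (alkyl, aryl, heteroaryl, alkoxy...). The published curated
set this reconstructs is not available in machine-readable form, so the
configuration is explicitly user-replaceable YAML; the shipped set was
chosen to name every entry of the packaged reference tables and is a
reconstruction, not the original.

Term generation: a fragment that *is* a known group takes its term directly
(`*OC` → methoxy). Otherwise the detected groups are reduced to a greedy
cover of the fragment's heavy atoms and concatenated by decreasing
bond-path distance from the attachment point (ties alphabetical), the
proximal group contributing its -yl form with chain-length-specific names
(methyl/ethyl/...) where applicable: `*CCc1ccccc1` → "phenylethyl".
Category labels follow the same detections: one covering general group
names the category; otherwise general groups are joined proximal→distal
("alkyl-aryl") with defined groups present as modifiers prefixed
("haloalkyl" for `*C(F)(F)F`). Unmatched fragments are labeled "other" and
fall back to their SMILES in claim text, so nothing is ever silently
dropped.

## Claim assembly, expansion, coverage

Per position, the explicit set is the union of fragment keys over the
series. Expansion applies the context rule: if the position's bare main
structure (ring system or chain, within the core) exactly matches a
library context and any explicit fragment appears among that context's
substituents, the remaining substituents are added — exact key matching
only, no fuzzy context similarity, because speculative breadth in a patent
draft must be auditable. Every machine-added fragment carries a provenance
note rendered in the document's notes section. The optional basic-set
switch (default off) additionally adds the library's top-10 duplicate
fragments everywhere; it is a recommendation layer, not a default, since it
broadens claims unconditionally.

Coverage checking embeds the core query in the candidate, cuts side chains
per embedding, and accepts when every fragment key falls in its position's
allowed set and all atoms are accounted for. Term generalization emits a
single family term when one group fully covers every fragment of a
position, hydrogen always listed first.

## Synthetic series generator

`fixtures.generate_series` assembles compounds from a mapped core SMILES
(`[*:1]`..`[*:k]`) and per-position candidate fragment lists, sampling
combinations without replacement from a seeded RNG (mixed-radix decoding of
sampled indices, so byte-identical SDF output per seed). It emulates the
one thing the pipeline assumes about real analog series — independent
substituent choice on a shared core — and deliberately not the rest of real
patent data: no stereochemistry, no salts, no tautomers, no reaction
byproducts, no multi-core chemotypes. Passing round-trip tests therefore
demonstrate correctness of the extraction machinery under the model's own
assumptions, not robustness to noisy real-world SD files.

The validation battery (`fixtures.validation_specs`) draws cores of 6–20
atoms with 1–4 positions and 2–6 candidates per position from a substituent
pool with pairwise-distinct first atoms, resampling until every position
actually varies within the sampled members. Both constraints exist to make
the intended core provably the MCS of the sample (a constant position, or
two substituents sharing their first atom in all members, would extend the
true common substructure beyond the intended core); recovery is then
required to be exact, with position labels compared up to core
automorphism. Problem sizes (50 specs for recovery, 14 molecule pairs for
the brute-force MCS cross-check, full enumeration on ≤ 3-position claims)
are chosen so the oracles stay exhaustive; all complete in seconds.

## Document output

The `.docx` writer emits a minimal OOXML package (content types, package
relationships, `word/document.xml`, plus the scheme PNG when RDKit's Cairo
renderer is present) directly over the standard-library zip module. Clause
text is the only tested surface: the docx and Markdown renderings must
carry byte-identical clause strings, and the SVG scheme must contain each
position label as a real `<text>` element (labels are overlaid at the
attachment-atom draw coordinates, since glyph outlines are not
searchable). Image pixels are never asserted on.

## Known limitations

- MCS is exponential in the worst case; the 60 s timeout can truncate the
  search on large, decoy-rich series, in which case the core may be
  suboptimal (RDKit reports, and the package propagates, a valid common
  substructure regardless).
- Multi-attachment fragments have no taxonomy terms; claims list their
  structures explicitly.
- Contexts match by exact bare-structure key; a methyl-decorated ring and
  its unsubstituted parent are different main structures by design.
- V3000 SD files, 2D-coordinate fidelity, InChI, and nested R-group
  hierarchies are out of scope.
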