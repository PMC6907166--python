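"""Core extraction and R-group decomposition.

The invariant core of an analog series is the maximum common connected
substructure (MCS) of its members, computed with chemistry-conscious
matching rules: atoms compare by element, bonds by order (aromatic is not
single), ring atoms only match ring atoms, and rings may not be matched
partially — a patent core with half a ring is meaningless. Atoms of the
core where at least one series member extends beyond it become the labeled
attachment positions R1..Rn of the Markush structure.

Decomposition cuts one compound around the core: every connected piece
outside the core becomes a Fragment carrying a ``*`` attachment pseudo-atom
per severed bond. Positions the compound does not substitute receive the
hydrogen fragment ``*[H]``. Symmetric cores admit several embeddings; the
one minimizing the sorted multiset of fragment canonical keys is chosen so
results are reproducible regardless of atom numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import rdFMCS
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chemio import CanonicalKey, canonical_key
from .errors import (
    BridgingFragmentWarning,
    CoreMismatch,
    InputTooSmall,
    NoCommonCore,
)

_MAX_EMBEDDINGS = 256


@dataclass(frozen=True)
class McsParams:
    """Matching rules for core finding.

    ``timeout`` bounds the (exponential worst-case) MCS search in seconds;
    ``min_core_atoms`` rejects trivially small cores that would claim
    nothing recognizable.
    """

    timeout: int = 60
    min_core_atoms: int = 3


@dataclass(frozen=True)
class Fragment:
    """A substituent graph with one or more ``*`` attachment pseudo-atoms.

    ``graph`` keeps an atom-map number (core atom index + 1) on each
    attachment dummy so the fragment can be bonded back onto its core atom;
    ``key`` is the stereo-stripped canonical SMILES with map numbers
    cleared, used for all identity comparisons.
    """

    graph: Chem.Mol
    key: CanonicalKey
    heavy_atom_count: int
    attachments: tuple[int, ...]  # core atom indices

    @property
    def smiles(self) -> str:
        return self.key.key

    @property
    def is_hydrogen(self) -> bool:
        return self.key.key in ("*[H]", "[H]*")


@dataclass(frozen=True)
class AttachmentPosition:
    label: str  # "R1".."Rn"
    core_atom: int
    context: str  # "ring" | "chain"
    main_key: str  # canonical SMILES of the bare ring system / carbon chain


@dataclass
class ScaffoldCore:
    """Invariant core plus its ordered attachment positions.

    ``query`` is the ring-constrained query used for embedding the core in
    compounds; its atom numbering coincides with ``core``'s.
    """

    core: Chem.Mol
    query: Chem.Mol
    positions: list[AttachmentPosition] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.positions]

    def position(self, label: str) -> AttachmentPosition:
        for p in self.positions:
            if p.label == label:
                return p
        raise KeyError(label)

    @property
    def smiles(self) -> str:
        """Core SMILES with atom-map numbers marking R positions (R1 -> map 1)."""
        work = Chem.Mol(self.core)
        for i, pos in enumerate(self.positions, start=1):
            work.GetAtomWithIdx(pos.core_atom).SetAtomMapNum(i)
        return Chem.MolToSmiles(work)


@dataclass
class Decomposition:
    compound: Chem.Mol
    assignments: dict[str, Fragment]


def hydrogen_fragment(core_atom: int = -1) -> Fragment:
    """The ``*[H]`` fragment assigned to unsubstituted positions."""
    graph = Chem.MolFromSmiles("*[H]")
    if core_atom >= 0:
        for atom in graph.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetAtomMapNum(core_atom + 1)
    return Fragment(
        graph=graph,
        key=CanonicalKey("*[H]"),
        heavy_atom_count=0,
        attachments=(core_atom,) if core_atom >= 0 else (),
    )


# ---------------------------------------------------------------------------
# core finding


def find_core(mols: list[Chem.Mol], params: McsParams | None = None) -> ScaffoldCore:
    """Maximum common connected substructure of a series, with R positions.

    Raises :class:`InputTooSmall` for fewer than two molecules and
    :class:`NoCommonCore` when the MCS falls below ``min_core_atoms``.
    Permuting the input order yields an isomorphic core with identical
    position labeling (labels follow canonical atom ranks of the core).
    """
    params = params or McsParams()
    if len(mols) < 2:
        raise InputTooSmall(
            "core finding needs more than one compound sharing a core structure"
        )
    result = rdFMCS.FindMCS(
        list(mols),
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrder,
        ringMatchesRingOnly=True,
        completeRingsOnly=True,
        maximizeBonds=False,
        timeout=params.timeout,
    )
    if result.numAtoms < params.min_core_atoms:
        raise NoCommonCore(
            f"common substructure has {result.numAtoms} atoms "
            f"(< {params.min_core_atoms})"
        )
    query = Chem.MolFromSmarts(result.smartsString)
    # Materialize the core as a real molecule, atom-for-atom aligned with the
    # query, by copying the matched atoms/bonds out of a reference member.
    # Use the member with the canonically smallest SMILES as reference so the
    # construction is independent of input order.
    ref = min(mols, key=lambda m: canonical_key(m).key)
    match = ref.GetSubstructMatch(query)
    if not match:  # pragma: no cover - FindMCS guarantees a match
        raise NoCommonCore("MCS query failed to embed in reference molecule")
    core_mol = _copy_matched_subgraph(ref, query, match)
    core = ScaffoldCore(core=core_mol, query=query)

    # Attachment positions: core atoms where any member extends beyond the
    # core, each under that member's preferred (key-minimal) embedding.
    attach_atoms: set[int] = set()
    for mol in mols:
        _, frags = _best_embedding(mol, core)
        for frag in frags:
            attach_atoms.update(frag.attachments)
            if len(frag.attachments) > 1:
                warnings.warn(
                    f"fragment {frag.smiles} bridges core atoms "
                    f"{frag.attachments}; rendered as a divalent linker",
                    BridgingFragmentWarning,
                    stacklevel=2,
                )
    core.positions = _label_positions(core_mol, sorted(attach_atoms))
    return core


def _copy_matched_subgraph(
    ref: Chem.Mol, query: Chem.Mol, match: tuple[int, ...]
) -> Chem.Mol:
    rw = Chem.RWMol()
    for qi in range(query.GetNumAtoms()):
        src = ref.GetAtomWithIdx(match[qi])
        atom = Chem.Atom(src.GetAtomicNum())
        atom.SetFormalCharge(src.GetFormalCharge())
        atom.SetIsotope(src.GetIsotope())
        rw.AddAtom(atom)
    for qbond in query.GetBonds():
        i, j = qbond.GetBeginAtomIdx(), qbond.GetEndAtomIdx()
        src_bond = ref.GetBondBetweenAtoms(match[i], match[j])
        rw.AddBond(i, j, src_bond.GetBondType())
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _label_positions(core_mol: Chem.Mol, attach_atoms: list[int]) -> list[AttachmentPosition]:
    """R1..Rn in canonical-atom-rank order, with ring/chain context."""
    ranks = list(Chem.CanonicalRankAtoms(core_mol, breakTies=True))
    ordered = sorted(attach_atoms, key=lambda a: ranks[a])
    structures = main_structures(core_mol)
    positions = []
    for n, atom_idx in enumerate(ordered, start=1):
        kind, main_key = _structure_of_atom(core_mol, structures, atom_idx)
        positions.append(
            AttachmentPosition(
                label=f"R{n}", core_atom=atom_idx, context=kind, main_key=main_key
            )
        )
    return positions


# ---------------------------------------------------------------------------
# main structures (ring systems / carbon chains) — shared with the library


def main_structures(mol: Chem.Mol) -> list[tuple[str, frozenset[int]]]:
    """Partition a scaffold into fused-ring systems and acyclic carbon chains.

    Returns ``(kind, atom_index_set)`` pairs; atoms that are neither ring
    members nor acyclic carbons (e.g. a lone ether oxygen linker) belong to
    no main structure.
    """
    ring_info = mol.GetRingInfo()
    systems: list[set[int]] = []
    for ring in ring_info.AtomRings():
        ring_set = set(ring)
        merged = [s for s in systems if s & ring_set]
        for s in merged:
            ring_set |= s
            systems.remove(s)
        systems.append(ring_set)
    out: list[tuple[str, frozenset[int]]] = [("ring", frozenset(s)) for s in systems]

    chain_atoms = {
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and not a.IsInRing() and not a.GetIsAromatic()
    }
    seen: set[int] = set()
    for start in sorted(chain_atoms):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nbr in mol.GetAtomWithIdx(cur).GetNeighbors():
                j = nbr.GetIdx()
                if j in chain_atoms and j not in comp:
                    comp.add(j)
                    stack.append(j)
        seen |= comp
        out.append(("chain", frozenset(comp)))
    return out


def structure_key(mol: Chem.Mol, atoms: frozenset[int]) -> str:
    """Canonical SMILES of the bare induced subgraph on ``atoms``."""
    rw = Chem.RWMol()
    index = {}
    for a in sorted(atoms):
        src = mol.GetAtomWithIdx(a)
        atom = Chem.Atom(src.GetAtomicNum())
        atom.SetFormalCharge(src.GetFormalCharge())
        index[a] = rw.AddAtom(atom)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in atoms and j in atoms:
            rw.AddBond(index[i], index[j], bond.GetBondType())
    sub = rw.GetMol()
    try:
        Chem.SanitizeMol(sub)
    except Exception:
        # e.g. an aromatic ring whose exocyclic partner was stripped; fall
        # back to an unsanitized (still canonical-per-input) notation
        sub.UpdatePropertyCache(strict=False)
    return Chem.MolToSmiles(sub)


def _structure_of_atom(
    mol: Chem.Mol, structures: list[tuple[str, frozenset[int]]], atom_idx: int
) -> tuple[str, str]:
    for kind, atoms in structures:
        if atom_idx in atoms:
            return kind, structure_key(mol, atoms)
    # isolated heteroatom linker: classify by ring flag with its own key
    kind = "ring" if mol.GetAtomWithIdx(atom_idx).IsInRing() else "chain"
    return kind, structure_key(mol, frozenset({atom_idx}))


# ---------------------------------------------------------------------------
# decomposition


def decompose(mol: Chem.Mol, core: ScaffoldCore) -> Decomposition:
    """Cut ``mol`` around ``core`` into per-position fragments.

    Every core position receives exactly one fragment (``*[H]`` when the
    compound carries nothing there). A fragment bonded to two or more core
    atoms is retained as a divalent linker under a combined label
    ("R1/R2") with a :class:`BridgingFragmentWarning`.
    """
    allowed = {p.core_atom for p in core.positions}
    choice = _best_embedding(mol, core, allowed=allowed)
    if choice is None:
        raise CoreMismatch("core embeds nowhere with substituents confined to R positions")
    _, frags = choice
    label_of = {p.core_atom: p.label for p in core.positions}
    assignments: dict[str, Fragment] = {}
    for frag in frags:
        if len(frag.attachments) == 1:
            label = label_of[frag.attachments[0]]
        else:
            label = "/".join(label_of[a] for a in frag.attachments)
            warnings.warn(
                f"fragment {frag.smiles} spans positions {label}",
                BridgingFragmentWarning,
                stacklevel=2,
            )
        if label in assignments:
            # gem-disubstitution on one core atom: merge into one multi-part
            # fragment so the position still maps to a single object
            assignments[label] = _merge_fragments(assignments[label], frag)
        else:
            assignments[label] = frag
    for pos in core.positions:
        covered = any(pos.core_atom in f.attachments for f in assignments.values())
        if not covered:
            assignments[pos.label] = hydrogen_fragment(pos.core_atom)
    return Decomposition(compound=mol, assignments=assignments)


def _merge_fragments(a: Fragment, b: Fragment) -> Fragment:
    graph = Chem.CombineMols(a.graph, b.graph)
    stripped = Chem.Mol(graph)
    for atom in stripped.GetAtoms():
        atom.SetAtomMapNum(0)
    return Fragment(
        graph=graph,
        key=canonical_key(stripped),
        heavy_atom_count=a.heavy_atom_count + b.heavy_atom_count,
        attachments=tuple(sorted(set(a.attachments + b.attachments))),
    )


def _best_embedding(
    mol: Chem.Mol, core: ScaffoldCore, allowed: set[int] | None = None
) -> tuple[tuple[int, ...], list[Fragment]] | None:
    """Embedding of the core minimizing the sorted fragment-key multiset.

    ``allowed`` restricts which core atoms may carry substituents; embeddings
    violating the restriction are discarded. Returns ``None`` when no
    admissible embedding exists; raises :class:`CoreMismatch` when the core
    does not embed at all.
    """
    matches = mol.GetSubstructMatches(core.query, uniquify=False, maxMatches=_MAX_EMBEDDINGS)
    if not matches:
        raise CoreMismatch("core is not a substructure of the compound")
    best = None
    for match in matches:
        frags = _sidechains(mol, match)
        if allowed is not None and any(
            a not in allowed for f in frags for a in f.attachments
        ):
            continue
        sig = tuple(sorted(f.key.key for f in frags))
        if best is None or sig < best[0]:
            best = (sig, match, frags)
    if best is None:
        return None
    return best[1], best[2]


def _sidechains(mol: Chem.Mol, match: tuple[int, ...]) -> list[Fragment]:
    """Connected fragments of ``mol`` outside the matched core atoms.

    Each severed bond is replaced by a ``*`` dummy whose atom-map number is
    the core atom index + 1 and whose bond keeps the original order.
    """
    matched = {m: c for c, m in enumerate(match)}
    rw = Chem.RWMol(mol)
    # kekulize first: severing bonds of an aromatic ring may otherwise leave
    # fragments with non-ring atoms still flagged aromatic
    Chem.Kekulize(rw, clearAromaticFlags=True)
    severed = [
        (matched[bond.GetBeginAtomIdx()]
         if bond.GetBeginAtomIdx() in matched
         else matched[bond.GetEndAtomIdx()],
         bond.GetEndAtomIdx() if bond.GetBeginAtomIdx() in matched
         else bond.GetBeginAtomIdx(),
         bond.GetBondType())
        for bond in rw.GetBonds()
        if (bond.GetBeginAtomIdx() in matched) != (bond.GetEndAtomIdx() in matched)
    ]
    for ci, other, btype in severed:
        dummy = Chem.Atom(0)
        dummy.SetAtomMapNum(ci + 1)
        didx = rw.AddAtom(dummy)
        rw.AddBond(didx, other, btype)
    for mi in sorted(matched, reverse=True):
        rw.RemoveAtom(mi)
    rest = rw.GetMol()
    if rest.GetNumAtoms() == 0:
        return []
    rest.UpdatePropertyCache(strict=False)
    try:
        Chem.SanitizeMol(rest)
    except Exception:
        pass
    fragments = []
    for piece in Chem.GetMolFrags(rest, asMols=True, sanitizeFrags=False):
        attachments = tuple(
            sorted(
                a.GetAtomMapNum() - 1
                for a in piece.GetAtoms()
                if a.GetAtomicNum() == 0 and a.GetAtomMapNum() > 0
            )
        )
        if not attachments:  # disconnected junk (e.g. counterion) — keep out
            continue
        stripped = Chem.Mol(piece)
        for atom in stripped.GetAtoms():
            atom.SetAtomMapNum(0)
        heavy = sum(
            1 for a in piece.GetAtoms() if a.GetAtomicNum() > 1
        )
        fragments.append(
            Fragment(
                graph=piece,
                key=canonical_key(stripped),
                heavy_atom_count=heavy,
                attachments=attachments,
            )
        )
    return fragments


def reassemble(core: ScaffoldCore, assignments: dict[str, Fragment]) -> Chem.Mol:
    """Bond every fragment back onto its core atoms; inverse of decompose.

    Used by tests to verify the decomposition invariant and by coverage
    checking to enumerate claim instantiations.
    """
    combo = Chem.RWMol(core.core)
    n_core = core.core.GetNumAtoms()
    offset = n_core
    pending: list[tuple[int, int, Chem.BondType]] = []  # (frag_atom, core_atom, order)
    dummies: list[int] = []
    for frag in assignments.values():
        if frag.is_hydrogen:
            continue
        gmol = frag.graph
        for atom in gmol.GetAtoms():
            combo.AddAtom(Chem.Atom(atom))
        for bond in gmol.GetBonds():
            combo.AddBond(
                bond.GetBeginAtomIdx() + offset,
                bond.GetEndAtomIdx() + offset,
                bond.GetBondType(),
            )
        for atom in gmol.GetAtoms():
            if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() > 0:
                didx = atom.GetIdx() + offset
                core_atom = atom.GetAtomMapNum() - 1
                nbr_bond = gmol.GetAtomWithIdx(atom.GetIdx()).GetBonds()[0]
                nbr = nbr_bond.GetOtherAtomIdx(atom.GetIdx()) + offset
                pending.append((nbr, core_atom, nbr_bond.GetBondType()))
                dummies.append(didx)
        offset += gmol.GetNumAtoms()
    for nbr, core_atom, order in pending:
        combo.AddBond(nbr, core_atom, order)
    for didx in sorted(dummies, reverse=True):
        combo.RemoveAtom(didx)
    mol = combo.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.SanitizeMol(mol)
    return mol


# ---------------------------------------------------------------------------
# Murcko scaffolds and library harvesting


def murcko_scaffold(mol: Chem.Mol) -> Chem.Mol | None:
    """Ring systems plus inter-ring linkers; ``None`` for acyclic molecules.

    Terminal side-chain atoms are pruned iteratively; atoms double-bonded
    directly to a ring or linker atom (e.g. a benzophenone carbonyl oxygen)
    survive the pruning.
    """
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return None
    return scaffold


def harvest_fragments(mol: Chem.Mol, scaffold: Chem.Mol) -> list[Fragment]:
    """Side chains of ``mol`` after removing ``scaffold``.

    Every connected component outside the scaffold becomes a Fragment with
    attachment pseudo-atoms at the severed bonds. Raises
    :class:`CoreMismatch` when the scaffold does not embed.
    """
    matches = mol.GetSubstructMatches(scaffold, uniquify=True, maxMatches=_MAX_EMBEDDINGS)
    if not matches:
        raise CoreMismatch("scaffold is not a substructure of the compound")
    # prefer embeddings where ring membership agrees atom-for-atom, so a
    # chain linker in the scaffold never eats a ring atom of the compound
    def ring_consistent(match: tuple[int, ...]) -> bool:
        return all(
            scaffold.GetAtomWithIdx(si).IsInRing() == mol.GetAtomWithIdx(mi).IsInRing()
            for si, mi in enumerate(match)
        )

    candidates = [m for m in matches if ring_consistent(m)] or list(matches)
    best = None
    for match in candidates:
        frags = _sidechains(mol, match)
        sig = tuple(sorted(f.key.key for f in frags))
        if best is None or sig < best[0]:
            best = (sig, frags)
    return best[1]
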