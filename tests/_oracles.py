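"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own code paths (and RDKit's MCS /
scaffold machinery): graphs are handled through networkx and plain
enumeration, so agreement with the implementation is a genuine
cross-check, not a tautology.
"""

from __future__ import annotations

import itertools

import networkx as nx
from networkx.algorithms.isomorphism import GraphMatcher
from rdkit import Chem


def mol_to_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(
            atom.GetIdx(),
            element=atom.GetAtomicNum(),
            ring=atom.IsInRing(),
            charge=atom.GetFormalCharge(),
            isotope=atom.GetIsotope(),
        )
    for bond in mol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(),
            bond.GetEndAtomIdx(),
            order=str(bond.GetBondType()),
            ring=bond.IsInRing(),
        )
    return g


def _node_match(a: dict, b: dict) -> bool:
    return a["element"] == b["element"] and a["ring"] == b["ring"]


def _edge_match(a: dict, b: dict) -> bool:
    return a["order"] == b["order"] and a["ring"] == b["ring"]


def _rings_complete(mol: Chem.Mol, atoms: frozenset[int]) -> bool:
    """Every ring atom of the subset lies on some ring wholly inside it."""
    ring_info = mol.GetRingInfo()
    rings = [frozenset(r) for r in ring_info.AtomRings()]
    for a in atoms:
        if mol.GetAtomWithIdx(a).IsInRing():
            if not any(a in ring and ring <= atoms for ring in rings):
                return False
    return True


def _connected_subsets(g: nx.Graph, max_size: int):
    """All connected node subsets, grown breadth-wise without repeats."""
    seen: set[frozenset] = set()
    frontier = [frozenset({n}) for n in g.nodes]
    seen.update(frontier)
    while frontier:
        yield from frontier
        nxt = []
        for subset in frontier:
            if len(subset) >= max_size:
                continue
            boundary = {
                nbr for n in subset for nbr in g.neighbors(n) if nbr not in subset
            }
            for nbr in boundary:
                grown = subset | {nbr}
                if grown not in seen:
                    seen.add(grown)
                    nxt.append(grown)
        frontier = nxt


def exhaustive_mcs_atoms(mol_a: Chem.Mol, mol_b: Chem.Mol) -> int:
    """Atom count of the maximum common connected substructure.

    Matching rules mirror the implementation's contract: elements must
    agree, ring atoms/bonds only match ring atoms/bonds, bond orders match
    exactly (aromatic is not single), and rings may not be left partial on
    either side. Pure enumeration over connected induced subgraphs of the
    smaller molecule.
    """
    if mol_a.GetNumAtoms() > mol_b.GetNumAtoms():
        mol_a, mol_b = mol_b, mol_a
    g_small, g_big = mol_to_graph(mol_a), mol_to_graph(mol_b)
    best = 0
    for subset in _connected_subsets(g_small, g_small.number_of_nodes()):
        if len(subset) <= best:
            continue
        if not _rings_complete(mol_a, subset):
            continue
        pattern = g_small.subgraph(subset)
        matcher = GraphMatcher(
            g_big, pattern, node_match=_node_match, edge_match=_edge_match
        )
        for mapping in matcher.subgraph_monomorphisms_iter():
            image = frozenset(mapping.keys())
            if _rings_complete(mol_b, image):
                best = len(subset)
                break
    return best


def murcko_prune(mol: Chem.Mol) -> Chem.Mol | None:
    """Scaffold by definition: ring atoms, inter-ring linkers, and atoms
    multiply-bonded directly to those; everything else pruned."""
    ring_atoms = {a.GetIdx() for a in mol.GetAtoms() if a.IsInRing()}
    if not ring_atoms:
        return None
    g = mol_to_graph(mol)
    keep = set(ring_atoms)
    for a, b in itertools.combinations(sorted(ring_atoms), 2):
        for path in nx.all_shortest_paths(g, a, b):
            keep.update(path)
    for bond in mol.GetBonds():
        if bond.GetBondTypeAsDouble() > 1.5 and not bond.GetIsAromatic():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i in keep or j in keep:
                keep.update((i, j))
    rw = Chem.RWMol(mol)
    for idx in sorted((a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in keep),
                      reverse=True):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def isomorphism_dedup(mols: list[Chem.Mol]) -> int:
    """Number of pairwise-nonisomorphic graphs (element/charge/isotope,
    bond order), computed by direct graph-isomorphism testing."""
    def full_node_match(a, b):
        return (
            a["element"] == b["element"]
            and a["charge"] == b["charge"]
            and a["isotope"] == b["isotope"]
        )

    def full_edge_match(a, b):
        return a["order"] == b["order"]

    graphs = [mol_to_graph(m) for m in mols]
    representatives: list[nx.Graph] = []
    for g in graphs:
        if not any(
            GraphMatcher(
                r, g, node_match=full_node_match, edge_match=full_edge_match
            ).is_isomorphic()
            for r in representatives
        ):
            representatives.append(g)
    return len(representatives)
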