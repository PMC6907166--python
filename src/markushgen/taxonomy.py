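"""Common-group detection, categorization and text-term generation.

A *common group* is a named functional-group class with a SMARTS definition
and a patent text term. "Defined" groups denote one fixed structure
(hydroxy, cyano, halo...); "general" groups denote structure classes
(alkyl, aryl, heteroaryl...). The default configuration ships 28 groups in
``data/taxonomy.yaml`` and is user-replaceable.

Term generation follows the distance-ordering rule: when an R group
comprises several common groups, the text term is assembled from the group
most distant from the attachment point moving inward, so ``*CCc1ccccc1``
reads "phenylethyl" (aryl distal, two-carbon alkyl proximal). Fragments
that *are* a known group use its term directly ("*OC" -> "methoxy").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml
from rdkit import Chem

from .chemio import canonical_key
from .errors import ParseError, Unsupported
from .scaffolding import Fragment

_SIZE_PREFIX = {
    1: "methyl", 2: "ethyl", 3: "propyl", 4: "butyl", 5: "pentyl", 6: "hexyl",
}


@dataclass(frozen=True)
class CommonGroup:
    name: str
    smarts: str
    kind: str  # "defined" | "general"
    term: str
    prefix: str | None = None
    sizes: dict[int, str] = field(default_factory=dict)
    compose: bool = True

    def __post_init__(self):
        if self.kind not in ("defined", "general"):
            raise ParseError(f"group {self.name}: bad kind {self.kind!r}")
        if Chem.MolFromSmarts(self.smarts) is None:
            raise ParseError(f"group {self.name}: SMARTS does not compile")

    @property
    def pattern(self) -> Chem.Mol:
        return Chem.MolFromSmarts(self.smarts)


@dataclass(frozen=True)
class GroupMatch:
    group: CommonGroup
    atoms: frozenset[int]
    distance: int  # min bond-path distance from attachment to a matched atom


class Taxonomy:
    """A loaded common-group configuration with an exact-term lookup."""

    def __init__(self, groups: list[CommonGroup], exact_terms: dict[str, str]):
        names = [g.name for g in groups]
        if len(set(names)) != len(names):
            raise ParseError("duplicate group names in taxonomy")
        self.groups = groups
        self._by_name = {g.name: g for g in groups}
        # canonical fragment key -> term, for fragments that are a group
        self.exact_terms = exact_terms

    def __len__(self) -> int:
        return len(self.groups)

    def group(self, name: str) -> CommonGroup:
        return self._by_name[name]

    @classmethod
    def from_config(cls, config: dict) -> "Taxonomy":
        groups: list[CommonGroup] = []
        exact: dict[str, str] = {}
        for raw in config["groups"]:
            group = CommonGroup(
                name=raw["name"],
                smarts=raw["smarts"],
                kind=raw["kind"],
                term=raw["term"],
                prefix=raw.get("prefix"),
                sizes={int(k): v for k, v in raw.get("sizes", {}).items()},
                compose=raw.get("compose", True),
            )
            groups.append(group)
            for smi, term in raw.get("exact", {}).items():
                exact[fragment_key(smi)] = term
        return cls(groups, exact)

    @classmethod
    def load(cls, path: str) -> "Taxonomy":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "Taxonomy":
        text = resources.files("markushgen.data").joinpath("taxonomy.yaml").read_text()
        return cls.from_config(yaml.safe_load(text))


def fragment_key(smiles: str) -> str:
    """Canonical stereo-stripped key for a fragment SMILES ('*H' tolerated)."""
    smiles = smiles.replace("*H", "*[H]") if smiles in ("*H", "H*") else smiles
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable fragment SMILES: {smiles!r}")
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return canonical_key(mol).key


def _as_mol(fragment: Fragment | str | Chem.Mol) -> Chem.Mol:
    if isinstance(fragment, Fragment):
        return fragment.graph
    if isinstance(fragment, Chem.Mol):
        return fragment
    smiles = fragment.replace("*H", "*[H]") if fragment in ("*H", "H*") else fragment
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable fragment SMILES: {fragment!r}")
    return mol


def _attachment_distances(mol: Chem.Mol) -> tuple[int, dict[int, int]]:
    """BFS distances from the single attachment dummy; its neighbor is 0."""
    dummies = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise Unsupported(
            f"term generation needs exactly one attachment point, found {len(dummies)}"
        )
    start = dummies[0]
    dist = {start: -1}
    frontier = [start]
    while frontier:
        nxt = []
        for idx in frontier:
            for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
                j = nbr.GetIdx()
                if j not in dist:
                    dist[j] = dist[idx] + 1
                    nxt.append(j)
        frontier = nxt
    return start, dist


def detect_groups(fragment: Fragment | str | Chem.Mol, tax: Taxonomy) -> list[GroupMatch]:
    """All common groups present in a single-attachment fragment.

    Each hit carries the union of its matched atoms and the minimum
    topological distance from the attachment point (the attachment's
    neighbor counts as distance 0).
    """
    mol = _as_mol(fragment)
    dummy, dist = _attachment_distances(mol)
    hits: list[GroupMatch] = []
    for group in tax.groups:
        matches = mol.GetSubstructMatches(group.pattern)
        atoms = {a for match in matches for a in match if a != dummy}
        if not atoms:
            continue
        hits.append(
            GroupMatch(
                group=group,
                atoms=frozenset(atoms),
                distance=min(dist.get(a, 0) for a in atoms),
            )
        )
    hits.sort(key=lambda h: (h.distance, h.group.name))
    return hits


def _heavy_atoms(mol: Chem.Mol) -> set[int]:
    return {a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1}


def categorize(fragment: Fragment | str | Chem.Mol, tax: Taxonomy) -> str:
    """Category label: one general group, a proximal->distal composite of
    general groups ("alkyl-aryl"), or a defined-modifier compound such as
    "haloalkyl"; "other" when nothing matches."""
    mol = _as_mol(fragment)
    hits = detect_groups(fragment, tax)
    if not hits:
        return "other"
    heavy = _heavy_atoms(mol)
    if not heavy:  # the hydrogen fragment
        return "hydrogen"
    full = [h for h in hits if heavy <= h.atoms]
    generals = [h for h in hits if h.group.kind == "general" and h.group.compose]
    # one general group explaining every heavy atom wins outright
    general_full = [h for h in full if h.group.kind == "general"]
    if general_full:
        preferred = [h for h in general_full if h.group.compose] or general_full
        return min(preferred, key=lambda h: (h.distance, h.group.name)).group.name
    if generals:
        base = "-".join(
            h.group.name
            for h in sorted(generals, key=lambda h: (h.distance, h.group.name))
        )
        covered = set().union(*(h.atoms for h in generals))
        modifiers = sorted(
            h.group.name
            for h in hits
            if h.group.kind == "defined" and not heavy <= h.atoms and (h.atoms - covered)
        )
        return "".join(modifiers) + base
    # defined groups only
    defined_full = [h for h in full if h.group.kind == "defined"]
    if defined_full:
        # the most specific (largest) defined structure names the category
        return max(defined_full, key=lambda h: (len(h.atoms), h.group.name)).group.name
    return "-".join(
        h.group.name for h in sorted(hits, key=lambda h: (h.distance, h.group.name))
    )


def _alkyl_part(group: CommonGroup, n_atoms: int) -> str:
    if group.sizes and n_atoms in group.sizes:
        return group.sizes[n_atoms]
    return group.prefix or group.term


def term_for(fragment: Fragment | str | Chem.Mol, tax: Taxonomy) -> str:
    """Patent text term for a single-attachment fragment.

    Exact-structure fragments use their group term directly; composite
    fragments concatenate group terms by decreasing distance to the
    attachment point (ties alphabetical), e.g. phenyl + ethyl ->
    "phenylethyl". Unrecognized fragments fall back to their SMILES.
    """
    mol = _as_mol(fragment)
    key = fragment.key.key if isinstance(fragment, Fragment) else fragment_key(
        Chem.MolToSmiles(mol)
    )
    if key in tax.exact_terms:
        return tax.exact_terms[key]
    hits = detect_groups(mol, tax)
    heavy = _heavy_atoms(mol)
    if not heavy:
        return "hydrogen"
    candidates = [h for h in hits if h.group.compose and h.group.name != "hydrogen"]
    if not candidates:
        return Chem.MolToSmiles(mol)
    # greedy cover of the heavy atoms, most-covering group first
    chosen: list[GroupMatch] = []
    uncovered = set(heavy)
    for hit in sorted(candidates, key=lambda h: (-len(h.atoms), h.distance, h.group.name)):
        if hit.atoms & uncovered:
            chosen.append(hit)
            uncovered -= hit.atoms
        if not uncovered:
            break
    chosen.sort(key=lambda h: (-h.distance, h.group.name))
    parts = []
    for i, hit in enumerate(chosen):
        proximal = i == len(chosen) - 1
        group = hit.group
        if proximal:
            parts.append(_alkyl_part(group, len(hit.atoms)) if group.sizes else group.term)
        else:
            parts.append(
                _alkyl_part(group, len(hit.atoms)) if group.sizes else (group.prefix or group.term)
            )
    return "".join(parts)


def common_term_for_set(keys: list[str], tax: Taxonomy) -> str | None:
    """One group term covering every fragment in ``keys`` entirely, or None.

    Used to collapse e.g. {*F, *Cl, *Br} to the single term "halo" in claim
    text. The hydrogen fragment is handled separately by the caller.
    """
    shared: set[str] | None = None
    for key in keys:
        mol = _as_mol(key)
        heavy = _heavy_atoms(mol)
        if not heavy:
            return None
        full = {
            h.group.name
            for h in detect_groups(mol, tax)
            if heavy <= h.atoms and h.group.name != "hydrogen"
        }
        shared = full if shared is None else shared & full
        if not shared:
            return None
    if not shared:
        return None
    # prefer defined families (halo) over catch-all generals
    ordered = sorted(shared, key=lambda n: (tax.group(n).kind != "defined", n))
    return tax.group(ordered[0]).term
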