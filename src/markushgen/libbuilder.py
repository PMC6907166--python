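"""R-group library construction and occurrence statistics.

The library is built from (compound set, scaffold set) pairs: every
compound is cut around its best-matching scaffold, the side-chain fragments
are pooled, deduplicated on stereo-stripped canonical keys (optical isomers
collapse), and passed through three exclusion filters applied in a fixed
order — deuterium-containing, phosphorus-containing, then fragments whose
longest aliphatic carbon chain exceeds six atoms. A FilterLedger records
the arithmetic so ``kept = harvested - duplicates - drops`` always holds.

For every harvested fragment the *substituent context* — the bare ring
system or acyclic carbon chain of the scaffold it hangs from, together with
its sibling substituents on that same main structure — is recorded; claim
expansion later uses these contexts to propose additional substituents.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem

from .chemio import canonical_key, carbon_count, largest_component, molecular_weight
from .errors import CoreMismatch, InvalidArgument, MissingInput
from .scaffolding import Fragment, harvest_fragments, main_structures, structure_key
from .taxonomy import Taxonomy, categorize

logger = logging.getLogger(__name__)

MAX_ALIPHATIC_CHAIN = 6  # fragments with a longer chain are dropped
DRUG_MW_MAX = 800.0
DRUG_MW_MIN = 100.0
DRUG_MIN_CARBONS = 6


@dataclass
class FilterLedger:
    """Bookkeeping for library construction; see the accounting identity."""

    harvested: int = 0
    duplicates_removed: int = 0
    dropped_deuterium: int = 0
    dropped_phosphorus: int = 0
    dropped_long_chain: int = 0

    @property
    def kept(self) -> int:
        return (
            self.harvested
            - self.duplicates_removed
            - self.dropped_deuterium
            - self.dropped_phosphorus
            - self.dropped_long_chain
        )


@dataclass
class SubstituentContext:
    main_key: str  # canonical SMILES of the bare ring system / carbon chain
    kind: str  # "ring" | "chain"
    substituents: set[str] = field(default_factory=set)  # fragment keys


@dataclass
class LibraryEntry:
    smiles: str  # stereo-stripped canonical fragment SMILES (the key)
    count: int
    categories: set[str] = field(default_factory=set)
    contexts: list[int] = field(default_factory=list)  # indices into library contexts
    percent: float | None = None  # populated for transcribed reference tables


@dataclass
class RGroupLibrary:
    entries: list[LibraryEntry] = field(default_factory=list)
    contexts: list[SubstituentContext] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def keys(self) -> set[str]:
        return {e.smiles for e in self.entries}

    def top_fragments(self, k: int) -> list[str]:
        """Keys of the k most frequent duplicate fragments (the 'basic set').

        Libraries transcribed from a printed occurrence table carry percents
        instead of raw counts and are ranked on those.
        """
        if self.entries and all(e.percent is not None for e in self.entries):
            ranked = sorted(self.entries, key=lambda e: (-e.percent, e.smiles))
            return [e.smiles for e in ranked[:k]]
        table = occurrence_stats(self.entries)
        return list(table["key"].head(k))

    def to_json(self, path: str) -> None:
        payload = {
            "entries": [
                {
                    "smiles": e.smiles,
                    "count": e.count,
                    "categories": sorted(e.categories),
                    "contexts": e.contexts,
                    **({"percent": e.percent} if e.percent is not None else {}),
                }
                for e in self.entries
            ],
            "contexts": [
                {
                    "main_smiles": c.main_key,
                    "kind": c.kind,
                    "substituent_smiles": sorted(c.substituents),
                }
                for c in self.contexts
            ],
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "RGroupLibrary":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            entries=[
                LibraryEntry(
                    smiles=e["smiles"],
                    count=e["count"],
                    categories=set(e.get("categories", [])),
                    contexts=list(e.get("contexts", [])),
                    percent=e.get("percent"),
                )
                for e in payload["entries"]
            ],
            contexts=[
                SubstituentContext(
                    main_key=c["main_smiles"],
                    kind=c["kind"],
                    substituents=set(c["substituent_smiles"]),
                )
                for c in payload.get("contexts", [])
            ],
            meta=payload.get("meta", {}),
        )


def longest_aliphatic_chain(fragment: Fragment | Chem.Mol | str) -> int:
    """Atom count of the longest simple path over acyclic aliphatic carbons.

    Aromatic and ring carbons are ineligible and heteroatoms break the
    chain, so a cyclohexyl fragment scores 0.
    """
    if isinstance(fragment, Fragment):
        mol = fragment.graph
    elif isinstance(fragment, str):
        mol = Chem.MolFromSmiles(fragment)
    else:
        mol = fragment
    eligible = {
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and not a.GetIsAromatic() and not a.IsInRing()
    }
    if not eligible:
        return 0
    adjacency = {
        i: [
            n.GetIdx()
            for n in mol.GetAtomWithIdx(i).GetNeighbors()
            if n.GetIdx() in eligible
        ]
        for i in eligible
    }

    best = 1

    def extend(node: int, seen: set[int]) -> None:
        nonlocal best
        best = max(best, len(seen))
        for nxt in adjacency[node]:
            if nxt not in seen:
                seen.add(nxt)
                extend(nxt, seen)
                seen.remove(nxt)

    for start in eligible:
        extend(start, {start})
    return best


def _has_deuterium(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 1 and a.GetIsotope() >= 2 for a in mol.GetAtoms())


def _has_phosphorus(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 15 for a in mol.GetAtoms())


def filter_category(fragment: Fragment) -> str | None:
    """First matching drop filter for a fragment, or None if it is kept.

    Order is fixed (deuterium, phosphorus, long chain) and first-match-wins
    so every dropped fragment lands in exactly one ledger column.
    """
    mol = fragment.graph
    if _has_deuterium(mol):
        return "deuterium"
    if _has_phosphorus(mol):
        return "phosphorus"
    if longest_aliphatic_chain(mol) > MAX_ALIPHATIC_CHAIN:
        return "long_chain"
    return None


def _pick_scaffold(compound: Chem.Mol, scaffolds: list[Chem.Mol]) -> Chem.Mol | None:
    """Largest matching scaffold; ties broken by canonical key."""
    matching = [s for s in scaffolds if compound.HasSubstructMatch(s)]
    if not matching:
        return None
    return min(matching, key=lambda s: (-s.GetNumAtoms(), canonical_key(s).key))


def build_library(
    compounds: list[Chem.Mol],
    scaffolds: list[Chem.Mol],
    tax: Taxonomy | None = None,
) -> tuple[RGroupLibrary, FilterLedger]:
    """Harvest, deduplicate, filter and count R groups.

    Compounds matched by no scaffold are logged and skipped. The returned
    library's entries are sorted by descending count then key, so output is
    independent of input compound order.
    """
    if not compounds or not scaffolds:
        raise MissingInput("build_library needs both compounds and scaffolds")
    tax = tax or Taxonomy.default()
    ledger = FilterLedger()
    pool: dict[str, list[Fragment]] = {}
    context_map: dict[tuple[str, str], SubstituentContext] = {}
    entry_contexts: dict[str, set[tuple[str, str]]] = {}

    for compound in compounds:
        scaffold = _pick_scaffold(compound, scaffolds)
        if scaffold is None:
            name = compound.GetProp("_Name") if compound.HasProp("_Name") else "?"
            logger.warning("compound %s matches no scaffold; skipped", name)
            continue
        try:
            frags = harvest_fragments(compound, scaffold)
        except CoreMismatch:  # pragma: no cover - _pick_scaffold guarantees a match
            continue
        ledger.harvested += len(frags)
        structures = main_structures(scaffold)
        by_structure: dict[tuple[str, str], set[str]] = {}
        for frag in frags:
            pool.setdefault(frag.key.key, []).append(frag)
            for attach_atom in frag.attachments:
                hit = _containing_structure(scaffold, structures, attach_atom)
                if hit is None:
                    continue
                kind, atoms = hit
                skey = structure_key(scaffold, atoms)
                by_structure.setdefault((skey, kind), set()).add(frag.key.key)
        for (skey, kind), subs in by_structure.items():
            ctx = context_map.setdefault(
                (skey, kind), SubstituentContext(main_key=skey, kind=kind)
            )
            ctx.substituents |= subs
            for key in subs:
                entry_contexts.setdefault(key, set()).add((skey, kind))

    unique = {key: frags[0] for key, frags in pool.items()}
    ledger.duplicates_removed = ledger.harvested - len(unique)

    contexts = sorted(context_map.values(), key=lambda c: (c.kind, c.main_key))
    context_index = {(c.main_key, c.kind): i for i, c in enumerate(contexts)}
    entries: list[LibraryEntry] = []
    for key, frag in unique.items():
        category = filter_category(frag)
        if category == "deuterium":
            ledger.dropped_deuterium += 1
            continue
        if category == "phosphorus":
            ledger.dropped_phosphorus += 1
            continue
        if category == "long_chain":
            ledger.dropped_long_chain += 1
            continue
        entries.append(
            LibraryEntry(
                smiles=key,
                count=len(pool[key]),
                categories={categorize(frag, tax)},
                contexts=sorted(
                    context_index[c] for c in entry_contexts.get(key, set())
                ),
            )
        )
    entries.sort(key=lambda e: (-e.count, e.smiles))
    library = RGroupLibrary(entries=entries, contexts=contexts)
    return library, ledger


def _containing_structure(mol, structures, atom_idx):
    for kind, atoms in structures:
        if atom_idx in atoms:
            return kind, atoms
    return None


def prepare_drug_set(mols: list[Chem.Mol]) -> list[Chem.Mol]:
    """Reduce to largest component, drop too-big/too-small molecules, dedup.

    Drop criteria: MW > 800 Da; MW < 100 Da; fewer than 6 carbon atoms.
    Duplicates (including optical isomers) keep their first occurrence.
    """
    kept: list[Chem.Mol] = []
    seen: set[str] = set()
    for mol in mols:
        mol = largest_component(mol)
        mw = molecular_weight(mol)
        if mw > DRUG_MW_MAX or mw < DRUG_MW_MIN or carbon_count(mol) < DRUG_MIN_CARBONS:
            continue
        key = canonical_key(mol).key
        if key in seen:
            continue
        seen.add(key)
        kept.append(mol)
    return kept


def occurrence_stats(entries: list[LibraryEntry]) -> pd.DataFrame:
    """Occurrence table of duplicate R groups (count >= 2).

    Percentages are occurrence-weighted: each entry's count over the total
    count of all duplicate entries, times 100. Sorted by descending
    percentage, ties by key.
    """
    dups = [e for e in entries if e.count >= 2]
    total = sum(e.count for e in dups)
    rows = [
        {"key": e.smiles, "count": e.count, "percent": 100.0 * e.count / total}
        for e in dups
    ]
    table = pd.DataFrame(rows, columns=["key", "count", "percent"])
    return table.sort_values(
        ["percent", "key"], ascending=[False, True], ignore_index=True
    )


def top_k_share(table: pd.DataFrame, k: int) -> float:
    """Summed percentage of the top-k rows of an occurrence table."""
    if k <= 0:
        raise InvalidArgument("k must be positive")
    if k > len(table):
        raise InvalidArgument(f"k={k} exceeds table length {len(table)}")
    return float(table["percent"].head(k).sum())


def cross_coverage(lib_a: RGroupLibrary | set[str], lib_b: RGroupLibrary | set[str]) -> float:
    """Percentage of lib_b's distinct fragment keys present in lib_a."""
    keys_a = lib_a.keys if isinstance(lib_a, RGroupLibrary) else set(lib_a)
    keys_b = lib_b.keys if isinstance(lib_b, RGroupLibrary) else set(lib_b)
    if not keys_b:
        raise InvalidArgument("reference library is empty")
    return 100.0 * len(keys_b & keys_a) / len(keys_b)


def top_list_overlap(table_a: pd.DataFrame, table_b: pd.DataFrame, k: int) -> int:
    """Number of fragment keys shared between the two top-k lists."""
    top_a = set(table_a["key"].head(k))
    top_b = set(table_b["key"].head(k))
    return len(top_a & top_b)
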