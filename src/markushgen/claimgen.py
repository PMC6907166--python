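"""Markush claim assembly, library expansion, and coverage checking.

A claim is the core plus, per attachment position, the set of substituents
observed in the input series (*explicit*), any substituents proposed from
the R-group library (*expanded*, each with a provenance note), and the
generalized text terms used in the claim language. Coverage of a compound
means some choice of one allowed substituent per position reassembles, up
to stereochemistry, into that compound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from .docgen import ClaimDocument
from .errors import CoreMismatch
from .libbuilder import RGroupLibrary
from .scaffolding import (
    Decomposition,
    ScaffoldCore,
    _sidechains,
)
from .taxonomy import Taxonomy, common_term_for_set, term_for

_H = "*[H]"
_MAX_EMBEDDINGS = 256


@dataclass
class PositionSpec:
    label: str
    explicit: set[str] = field(default_factory=set)  # fragment keys from inputs
    expanded: set[str] = field(default_factory=set)  # keys added by expansion
    terms: list[str] = field(default_factory=list)

    @property
    def allowed(self) -> set[str]:
        return self.explicit | self.expanded


@dataclass
class MarkushClaim:
    core: ScaffoldCore
    specs: list[PositionSpec] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)  # "label:key" -> note

    def spec(self, label: str) -> PositionSpec:
        for s in self.specs:
            if s.label == label:
                return s
        raise KeyError(label)


@dataclass
class ExpandOptions:
    basic_set: bool = False
    basic_set_size: int = 10


def build_claim(
    series: list[Chem.Mol],
    core: ScaffoldCore,
    decomps: list[Decomposition],
    tax: Taxonomy | None = None,
) -> MarkushClaim:
    """Union the per-position fragments of all decompositions into a claim.

    Positions keep the order R1..Rn; combined labels from bridging
    fragments ("R1/R2") are appended after the regular positions. Terms are
    generalized per position (e.g. {*F, *Cl} -> "halo").
    """
    tax = tax or Taxonomy.default()
    by_label: dict[str, set[str]] = {label: set() for label in core.labels}
    for decomp in decomps:
        for label, frag in decomp.assignments.items():
            by_label.setdefault(label, set()).add(frag.key.key)
    claim = MarkushClaim(core=core)
    ordered = core.labels + [l for l in by_label if l not in core.labels]
    for label in ordered:
        spec = PositionSpec(label=label, explicit=set(by_label[label]))
        claim.specs.append(generalize_terms(spec, tax))
    return claim


def generalize_terms(spec: PositionSpec, tax: Taxonomy) -> PositionSpec:
    """Fill ``spec.terms`` from its allowed fragments.

    When one common group covers every non-hydrogen fragment entirely, its
    single class term is emitted; otherwise fragments are named one by one.
    Hydrogen always leads; order of the rest follows the sorted fragment
    keys (first appearance), deduplicated.
    """
    keys = sorted(spec.explicit) + sorted(spec.expanded - spec.explicit)
    terms: list[str] = []
    if _H in keys:
        terms.append("hydrogen")
        keys = [k for k in keys if k != _H]
    if keys:
        shared = common_term_for_set(keys, tax) if len(keys) > 1 else None
        if shared is not None:
            terms.append(shared)
        else:
            for key in keys:
                term = term_for(key, tax)
                if term not in terms:
                    terms.append(term)
    spec.terms = terms
    return spec


def expand_claim(
    claim: MarkushClaim,
    lib: RGroupLibrary,
    options: ExpandOptions | None = None,
    tax: Taxonomy | None = None,
) -> MarkushClaim:
    """Broaden a claim with the library's substituent contexts.

    For each position sitting on a ring or carbon chain whose bare
    structure exactly matches a library context, if any explicit
    substituent of the position appears among that context's recorded
    substituents, the remaining recorded substituents are added. With
    ``basic_set`` on, the library's top duplicate fragments are added
    everywhere. Every added fragment carries a provenance note. The input
    claim is not modified.
    """
    options = options or ExpandOptions()
    tax = tax or Taxonomy.default()
    out = MarkushClaim(core=claim.core, provenance=dict(claim.provenance))
    basic = lib.top_fragments(options.basic_set_size) if options.basic_set else []
    for spec in claim.specs:
        new = PositionSpec(
            label=spec.label,
            explicit=set(spec.explicit),
            expanded=set(spec.expanded),
        )
        try:
            position = claim.core.position(spec.label)
        except KeyError:
            position = None  # combined bridging label: no single context
        if position is not None:
            for ctx in lib.contexts:
                if ctx.kind != position.context or ctx.main_key != position.main_key:
                    continue
                if new.explicit & ctx.substituents:
                    for key in ctx.substituents - new.allowed:
                        new.expanded.add(key)
                        out.provenance[f"{new.label}:{key}"] = (
                            f"shared context {ctx.kind} {ctx.main_key}"
                        )
        for key in basic:
            if key not in new.allowed:
                new.expanded.add(key)
                out.provenance[f"{new.label}:{key}"] = "library basic set"
        out.specs.append(generalize_terms(new, tax))
    return out


def claim_covers(claim: MarkushClaim, mol: Chem.Mol) -> bool:
    """True iff some per-position choice of allowed fragments yields ``mol``.

    Checked by embedding the core and comparing each side chain's canonical
    key against the position's allowed set; stereochemistry is ignored.
    """
    core = claim.core
    allowed = {s.label: s.allowed for s in claim.specs}
    label_of = {p.core_atom: p.label for p in core.positions}
    try:
        matches = mol.GetSubstructMatches(
            core.query, uniquify=False, maxMatches=_MAX_EMBEDDINGS
        )
    except Exception:
        return False
    if not matches:
        return False
    n_core = core.core.GetNumAtoms()
    for match in matches:
        frags = _sidechains(mol, match)
        outside = sum(f.heavy_atom_count for f in frags)
        if n_core + outside != mol.GetNumHeavyAtoms():
            continue  # a disconnected piece is unaccounted for
        assignment: dict[str, str] = {}
        ok = True
        for frag in frags:
            if any(a not in label_of for a in frag.attachments):
                ok = False
                break
            if len(frag.attachments) == 1:
                label = label_of[frag.attachments[0]]
            else:
                label = "/".join(label_of[a] for a in frag.attachments)
            if label in assignment:  # two substituents on one position
                ok = False
                break
            assignment[label] = frag.key.key
        if not ok:
            continue
        for label, keys in allowed.items():
            key = assignment.get(label, _H)
            if key not in keys:
                ok = False
                break
        if ok and all(label in allowed for label in assignment):
            return True
    return False


def _join_terms(terms: list[str]) -> str:
    if len(terms) == 1:
        return terms[0]
    if len(terms) == 2:
        return f"{terms[0]} and {terms[1]}"
    return ", ".join(terms[:-1]) + f", and {terms[-1]}"


def render_claim_text(claim: MarkushClaim, title: str = "Claims") -> ClaimDocument:
    """Number and phrase the claim clauses; deterministic for a fixed claim."""
    clauses: list[tuple[int, str]] = []
    if not claim.specs:
        smiles = Chem.MolToSmiles(claim.core.core)
        clauses.append((1, f"A compound of formula (I), being {smiles}."))
    else:
        lines = ["A compound of formula (I):", "[Formula (I)]", "wherein"]
        for i, spec in enumerate(claim.specs):
            terms = spec.terms or sorted(spec.allowed)
            sep = ";" if i < len(claim.specs) - 1 else ","
            lines.append(
                f"{spec.label} is selected from the group consisting of "
                f"{_join_terms(terms)}{sep}"
            )
        lines.append("or a pharmaceutically acceptable salt thereof.")
        clauses.append((1, "\n".join(lines)))
        number = 2
        for spec in claim.specs:
            if spec.expanded:
                extra = ", ".join(sorted(spec.expanded))
                clauses.append(
                    (
                        number,
                        f"The compound of claim 1, wherein {spec.label} is further "
                        f"selected from {extra}.",
                    )
                )
                number += 1
    notes = [
        f"{key}: {note}" for key, note in sorted(claim.provenance.items())
    ]
    return ClaimDocument(title=title, clauses=clauses, scheme=claim.core, notes=notes)
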